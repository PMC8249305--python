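"""Synthetic polyploid SSR + S-locus datasets with known ground truth.

The generator emulates the structure of a mixed blackthorn/damson panel:
accessions of ploidy 4/5/6, nine SSR loci with allele pools and Dirichlet
frequencies, an S-allele pool with functionality flags, planted clonal
duplicates, and interploidy hybrids formed by the union of one gamete from
each parent.  Dosage is simulated and then discarded — the observed call is
the *set* of distinct alleles drawn — so tests can quantify exactly what the
presence/absence coding loses.

Defaults mirror the published study panel: 17 accessions (10 tetraploid,
4 hexaploid of which one is a planted clone pair, 3 pentaploid hybrids of a
tetraploid seed parent and a hexaploid pollen parent), 9 SSR loci with the
panel's per-locus allele-pool sizes, and a 23-allele S pool with a single
non-functional member.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_io import Accession, PolyGenotype, SGenotype, write_genotype_table
from .mating import cross_compatibility, pollen_accepted

__all__ = [
    "LocusModel",
    "SimulationConfig",
    "TrueRecord",
    "SimulatedDataset",
    "default_loci",
    "default_s_pool",
    "simulate_accessions",
    "simulate_hybrid",
    "write_dataset",
]


@dataclass(frozen=True)
class LocusModel:
    """Allele pool for one simulated SSR locus."""

    name: str
    pool: tuple[int, ...]
    concentration: float = 1.0  # Dirichlet concentration for pool frequencies

    def __post_init__(self) -> None:
        if len(set(self.pool)) != len(self.pool):
            raise ValueError(f"locus {self.name}: duplicate pool sizes")
        if self.concentration <= 0:
            raise ValueError(f"locus {self.name}: concentration must be > 0")


def default_loci() -> tuple[LocusModel, ...]:
    """Nine SSR loci with the study panel's allele counts and size ranges."""
    spec = [
        ("BPPCT007", 122, 154, 17),
        ("BPPCT025", 132, 208, 24),
        ("BPPCT037", 100, 120, 5),
        ("BPPCT038", 110, 140, 6),
        ("BPPCT039", 122, 146, 7),
        ("BPPCT040", 120, 154, 12),
        ("CPDCT044", 162, 252, 24),
        ("CPSCT021", 124, 208, 26),
        ("EPDCU5100", 124, 144, 8),
    ]
    loci = []
    for name, lo, hi, k in spec:
        pool = tuple(int(round(x)) for x in np.linspace(lo, hi, k))
        loci.append(LocusModel(name=name, pool=pool))
    return tuple(loci)


def default_s_pool() -> tuple[tuple[str, ...], dict[str, bool]]:
    """23 S-allele labels, all functional except one (a pseudo-allele with a
    premature stop, mirroring the panel's non-functional member)."""
    labels = tuple(f"S_{c}" for c in string.ascii_uppercase[:23])
    functional = {lab: True for lab in labels}
    functional["S_J"] = False
    return labels, functional


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    ``n_accessions`` counts everything: base accessions plus ``clone_pairs``
    planted duplicates plus ``n_hybrids`` gamete-union offspring.  Base
    accessions draw their ploidy from ``ploidy_weights``; hybrids always
    join a tetraploid seed parent and a hexaploid pollen parent (2 + 3
    chromosome sets -> pentaploid).
    """

    n_accessions: int = 17
    ploidy_weights: Mapping[int, float] = field(
        default_factory=lambda: {4: 10 / 13, 6: 3 / 13}
    )
    loci: tuple[LocusModel, ...] = field(default_factory=default_loci)
    clone_pairs: int = 1
    n_hybrids: int = 3
    s_pool: tuple[str, ...] | None = None
    s_functional: Mapping[str, bool] | None = None
    s_concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.s_pool is None:
            pool, functional = default_s_pool()
            self.s_pool = pool
            if self.s_functional is None:
                self.s_functional = functional
        elif self.s_functional is None:
            self.s_functional = {lab: True for lab in self.s_pool}
        min_base = 2 if self.n_hybrids else 1
        if self.n_accessions < self.clone_pairs + self.n_hybrids + min_base:
            raise ValueError("n_accessions too small for requested clones/hybrids")
        if any(w < 0 for w in self.ploidy_weights.values()):
            raise ValueError("ploidy weights must be non-negative")
        if self.n_hybrids and not (
            any(p == 4 for p in self.ploidy_weights)
            and any(p == 6 for p in self.ploidy_weights)
        ):
            raise ValueError("hybrids require tetraploid and hexaploid parents")
        n_func = sum(
            1 for lab in self.s_pool if self.s_functional.get(lab, True)
        )
        max_ploidy = max(self.ploidy_weights, default=4)
        if n_func < max_ploidy:
            raise ValueError(
                "S-allele pool has fewer functional alleles than genome copies"
            )


@dataclass
class TrueRecord:
    """Full (dosage-aware) genotype of one simulated accession."""

    accession: Accession
    ssr_dosage: dict[str, tuple[int, ...]]  # locus -> ploidy-long draw
    s_dosage: tuple[str, ...]               # ploidy-long S-locus copies

    def observed(self) -> PolyGenotype:
        """Dosage lost: the observable call is the set of distinct alleles."""
        return PolyGenotype(
            accession_id=self.accession.id,
            calls={loc: frozenset(d) for loc, d in self.ssr_dosage.items()},
        )

    def observed_s(self) -> SGenotype:
        return SGenotype(
            accession_id=self.accession.id, alleles=tuple(set(self.s_dosage))
        )


@dataclass
class SimulatedDataset:
    accessions: list[Accession]
    records: dict[str, TrueRecord]
    genotypes: list[PolyGenotype]
    sgenotypes: list[SGenotype]
    functional: dict[str, bool]
    truth: dict


def _draw_s_dosage(
    rng: np.random.Generator,
    pool: Sequence[str],
    freqs: np.ndarray,
    functional: Mapping[str, bool],
    ploidy: int,
    max_tries: int = 1000,
) -> tuple[str, ...]:
    """Draw ``ploidy`` S-locus copies; functional alleles must be distinct
    (duplicates permitted only for non-functional alleles)."""
    for _ in range(max_tries):
        draw = tuple(rng.choice(len(pool), size=ploidy, p=freqs))
        labels = tuple(pool[i] for i in draw)
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        if all(
            k == 1 or not functional.get(lab, True) for lab, k in counts.items()
        ):
            return tuple(sorted(labels))
    raise RuntimeError("could not draw an S-genotype without functional duplicates")


def simulate_accessions(
    config: SimulationConfig, seed: int | np.random.Generator
) -> SimulatedDataset:
    """Simulate a panel under ``config``; the seed is mandatory.

    Returns the dataset (observed, dosage-unaware genotypes) together with a
    truth record: planted clone pairs, hybrid parentage, and the per-locus
    pool frequencies actually used.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    locus_freqs = {
        loc.name: rng.dirichlet([loc.concentration] * len(loc.pool))
        for loc in config.loci
    }
    s_freqs = rng.dirichlet([config.s_concentration] * len(config.s_pool))

    n_base = config.n_accessions - config.clone_pairs - config.n_hybrids
    ploidies = sorted(config.ploidy_weights)
    weights = np.array([config.ploidy_weights[p] for p in ploidies], dtype=float)
    weights = weights / weights.sum()
    base_ploidies = [
        int(rng.choice(ploidies, p=weights)) for _ in range(n_base)
    ]
    if config.n_hybrids:
        # guarantee at least one tetraploid and one hexaploid parent
        if 4 not in base_ploidies:
            base_ploidies[0] = 4
        if 6 not in base_ploidies:
            base_ploidies[-1] = 6

    records: dict[str, TrueRecord] = {}
    order: list[str] = []

    def species_for(ploidy: int) -> str:
        return {4: "P_spinosa", 6: "P_insititia"}.get(ploidy, "hybrid")

    for k, ploidy in enumerate(base_ploidies, start=1):
        acc = Accession(
            id=f"A{k:02d}", species=species_for(ploidy), ploidy=ploidy,
            origin="simulated",
        )
        ssr = {
            loc.name: tuple(
                sorted(
                    int(loc.pool[i])
                    for i in rng.choice(
                        len(loc.pool), size=ploidy, p=locus_freqs[loc.name]
                    )
                )
            )
            for loc in config.loci
        }
        s_dosage = _draw_s_dosage(
            rng, config.s_pool, s_freqs, config.s_functional, ploidy
        )
        records[acc.id] = TrueRecord(accession=acc, ssr_dosage=ssr, s_dosage=s_dosage)
        order.append(acc.id)

    clone_pairs = []
    base_ids = list(order)
    clone_sources = rng.choice(len(base_ids), size=config.clone_pairs, replace=False)
    for j, src_idx in enumerate(clone_sources, start=1):
        src = records[base_ids[int(src_idx)]]
        cid = f"C{j:02d}"
        acc = Accession(
            id=cid, species=src.accession.species, ploidy=src.accession.ploidy,
            origin=f"clone of {src.accession.id}",
        )
        records[cid] = TrueRecord(
            accession=acc, ssr_dosage=dict(src.ssr_dosage), s_dosage=src.s_dosage
        )
        order.append(cid)
        clone_pairs.append(tuple(sorted((src.accession.id, cid))))

    hybrids = {}
    tetra = [i for i in base_ids if records[i].accession.ploidy == 4]
    hexa = [i for i in base_ids if records[i].accession.ploidy == 6]
    # restrict to parent pairs with at least one acceptable pollen gamete
    compatible_pairs = [
        (a, b)
        for a in tetra
        for b in hexa
        if cross_compatibility(
            records[a].observed_s(), records[b].observed_s(),
            records[b].accession.ploidy, config.s_functional,
        ).compatible_fraction > 0
    ]
    if config.n_hybrids and not compatible_pairs:
        raise RuntimeError(
            "no compatible tetraploid x hexaploid parent pair in this draw"
        )
    for j in range(1, config.n_hybrids + 1):
        a, b = compatible_pairs[int(rng.integers(len(compatible_pairs)))]
        pa, pb = records[a], records[b]
        child = simulate_hybrid(
            pa, pb, rng, functional=config.s_functional, child_id=f"H{j:02d}"
        )
        records[child.accession.id] = child
        order.append(child.accession.id)
        hybrids[child.accession.id] = (pa.accession.id, pb.accession.id)

    accessions = [records[i].accession for i in order]
    dataset = SimulatedDataset(
        accessions=accessions,
        records=records,
        genotypes=[records[i].observed() for i in order],
        sgenotypes=[records[i].observed_s() for i in order],
        functional=dict(config.s_functional),
        truth={
            "clones": clone_pairs,
            "hybrids": hybrids,
            "locus_freqs": {
                name: {str(a): float(f) for a, f in zip(
                    [loc.pool for loc in config.loci if loc.name == name][0], freqs
                )}
                for name, freqs in locus_freqs.items()
            },
            "s_freqs": {
                lab: float(f) for lab, f in zip(config.s_pool, s_freqs)
            },
        },
    )
    return dataset


def simulate_hybrid(
    parent_a: TrueRecord,
    parent_b: TrueRecord,
    rng: np.random.Generator,
    functional: Mapping[str, bool] | None = None,
    child_id: str = "H01",
    max_tries: int = 1000,
) -> TrueRecord:
    """Offspring of two even-ploid parents by gamete union.

    ``parent_a`` is the seed parent, ``parent_b`` the pollen parent.  Each
    contributes a random half of its chromosome copies per locus; the
    pollen S-gamete must be accepted by the seed parent's pistil under the
    one-allele-match rule, so rejected gametes are resampled (gametophytic
    self-incompatibility acting during simulation).  A 4x × 6x cross yields
    a pentaploid (2 + 3 sets).
    """
    functional = dict(functional or {})
    pa, pb = parent_a.accession, parent_b.accession
    if pa.ploidy % 2 or pb.ploidy % 2:
        raise ValueError("hybrid parents must have even ploidy")
    ma, mb = pa.ploidy // 2, pb.ploidy // 2
    cross = cross_compatibility(
        parent_a.observed_s(), parent_b.observed_s(), pb.ploidy, functional
    )
    if cross.compatible_fraction == 0:
        raise ValueError(
            f"cross {pa.id} x {pb.id} is fully incompatible: no pollen gamete "
            "can be accepted"
        )
    ssr: dict[str, tuple[int, ...]] = {}
    for locus in parent_a.ssr_dosage:
        ga = rng.choice(parent_a.ssr_dosage[locus], size=ma, replace=False)
        gb = rng.choice(parent_b.ssr_dosage[locus], size=mb, replace=False)
        ssr[locus] = tuple(sorted(int(x) for x in np.concatenate([ga, gb])))
    seed_gamete = tuple(
        rng.choice(parent_a.s_dosage, size=ma, replace=False)
    )
    pistil = parent_a.observed_s()
    for _ in range(max_tries):
        pollen_gamete = tuple(rng.choice(parent_b.s_dosage, size=mb, replace=False))
        if pollen_accepted(pollen_gamete, pistil, functional):
            break
    else:  # pragma: no cover - guarded by the fraction check above
        raise RuntimeError("failed to sample a compatible pollen gamete")
    acc = Accession(
        id=child_id, species="hybrid", ploidy=ma + mb,
        origin=f"{pa.id} x {pb.id}",
    )
    return TrueRecord(
        accession=acc, ssr_dosage=ssr,
        s_dosage=tuple(sorted(seed_gamete + pollen_gamete)),
    )


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Write genotypes.csv / sgenotypes.csv / manifest.json / truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotype_table(dataset.genotypes, outdir / "genotypes.csv")
    with (outdir / "sgenotypes.csv").open("w") as fh:
        fh.write("accession,species,ploidy,origin,alleles\n")
        for acc, sg in zip(dataset.accessions, dataset.sgenotypes):
            fh.write(
                f'{acc.id},{acc.species},{acc.ploidy},"{acc.origin}",'
                + ";".join(sorted(sg.allele_set)) + "\n"
            )
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(
            {
                "accessions": [
                    {
                        "id": a.id, "species": a.species,
                        "ploidy": a.ploidy, "origin": a.origin,
                    }
                    for a in dataset.accessions
                ],
                "s_functional": dataset.functional,
            },
            fh, indent=2,
        )
    with (outdir / "truth.json").open("w") as fh:
        json.dump(dataset.truth, fh, indent=2)
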