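"""Polysomic gamete model and gametophytic self-incompatibility (GSI)
compatibility analysis for polyploid crosses.

Model: a 2m-ploid pollen parent undergoes meiosis with equal chance for all
possible chromosome pairings, so every m-subset of its 2m S-locus copies is
an equally likely pollen gamete (C(2m, m) subsets, aggregated over identical
allele multisets).  Pollen is rejected under the one-allele-match rule: a
gamete carrying at least one *functional* S-allele whose label matches a
functional S-RNase in the pistil genotype fails; non-functional alleles on
either side never cause rejection.  For a pollen parent with n distinct
functional alleles, s of them shared with the pistil, the compatible
fraction has the closed form C(n−s, m) / C(n, m).

Odd-ploidy (e.g. pentaploid) parents have no defined gamete model here and
are refused as pollen donors; they remain valid pistil parents.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import Accession, SGenotype

__all__ = [
    "GameteDistribution",
    "CrossResult",
    "OddPloidyError",
    "AmbiguousCopyNumberError",
    "enumerate_gametes",
    "pollen_accepted",
    "cross_compatibility",
    "closed_form_fraction",
    "incompatibility_groups",
    "predict_self_compatibility",
    "compatibility_panel",
]

_NULL_PREFIX = "∅"


class OddPloidyError(ValueError):
    """Raised for pollen-side gamete computation on an odd-ploidy parent."""


class AmbiguousCopyNumberError(ValueError):
    """Fewer alleles observed than genome copies, and the assignment of the
    unobserved copies to functional alleles is ambiguous."""


@dataclass(frozen=True)
class GameteDistribution:
    """Equally likely m-allele gametes of a 2m-ploid parent, aggregated by
    allele multiset.  Probabilities are exact rationals."""

    parent_id: str
    m: int
    gametes: tuple[tuple[tuple[str, ...], Fraction], ...]  # (sorted multiset, prob)

    def total_probability(self) -> float:
        return float(sum(p for _, p in self.gametes))


@dataclass(frozen=True)
class CrossResult:
    seed_parent: str
    pollen_parent: str
    compatible_fraction: float
    category: str  # fully_compatible | partially_compatible | incompatible
    fraction_interval: tuple[float, float] | None = None


def _categorize(fraction: float) -> str:
    if fraction == 0:
        return "incompatible"
    if fraction == 1:
        return "fully_compatible"
    return "partially_compatible"


def _chromosomes(
    genotype: SGenotype,
    ploidy: int,
    functional: Mapping[str, bool],
    fill: str,
) -> list[str]:
    """Resolve the genotype to exactly ``ploidy`` S-locus copies.

    Observed alleles occupy one copy each (duplicates in the genotype tuple
    occupy one per appearance).  Unobserved copies are filled by duplicating
    a non-functional allele when that choice is unambiguous, by inert
    placeholder 'null' labels when ``fill='null'``, and otherwise raise
    :class:`AmbiguousCopyNumberError`.
    """
    copies = list(genotype.alleles)
    deficit = ploidy - len(copies)
    if deficit < 0:
        raise ValueError(
            f"{genotype.accession_id}: {len(copies)} alleles exceed ploidy {ploidy}"
        )
    dup_functional = [
        lab for lab, k in Counter(copies).items() if k > 1 and functional.get(lab, True)
    ]
    if dup_functional:
        raise ValueError(
            f"{genotype.accession_id}: duplicated functional alleles {dup_functional} "
            "violate gametophytic self-incompatibility"
        )
    if deficit == 0:
        return copies
    if fill == "null":
        copies += [f"{_NULL_PREFIX}{genotype.accession_id}.{k}" for k in range(deficit)]
        return copies
    nonfunctional = sorted({lab for lab in copies if not functional.get(lab, True)})
    if len(nonfunctional) == 1:
        return copies + [nonfunctional[0]] * deficit
    raise AmbiguousCopyNumberError(
        f"{genotype.accession_id}: {deficit} genome copies unassigned and "
        f"{len(nonfunctional)} non-functional alleles to duplicate; supply the "
        "copy numbers explicitly or use fill='null' for a no-hidden-match "
        "point estimate"
    )


def enumerate_gametes(
    sgenotype: SGenotype,
    ploidy: int,
    functional: Mapping[str, bool] | None = None,
    fill: str = "error",
) -> GameteDistribution:
    """All equally likely pollen gametes of an even-ploid parent.

    Every C(ploidy, ploidy/2) subset of the parent's S-locus copies is one
    chromosome draw; draws with identical allele multisets are aggregated
    with summed probability.
    """
    if ploidy % 2:
        raise OddPloidyError(
            f"{sgenotype.accession_id}: ploidy {ploidy} is odd; the equal-chance "
            "chromosome-pairing gamete model is defined only for even ploidy, "
            "so this parent can serve as pistil parent only"
        )
    functional = functional or {}
    copies = _chromosomes(sgenotype, ploidy, functional, fill=fill)
    m = ploidy // 2
    n_subsets = comb(ploidy, m)
    agg: Counter = Counter()
    for subset in itertools.combinations(range(ploidy), m):
        agg[tuple(sorted(copies[i] for i in subset))] += 1
    gametes = tuple(
        (multiset, Fraction(count, n_subsets))
        for multiset, count in sorted(agg.items())
    )
    return GameteDistribution(parent_id=sgenotype.accession_id, m=m, gametes=gametes)


def pollen_accepted(
    gamete: Iterable[str],
    pistil_sgenotype: SGenotype | Iterable[str],
    functional: Mapping[str, bool] | None = None,
) -> bool:
    """One-allele-match rule: the gamete is rejected iff it carries at least
    one functional allele whose label matches a functional pistil S-RNase."""
    functional = functional or {}
    pistil = (
        pistil_sgenotype.allele_set
        if isinstance(pistil_sgenotype, SGenotype)
        else frozenset(pistil_sgenotype)
    )
    pistil_functional = {lab for lab in pistil if functional.get(lab, True)}
    for lab in gamete:
        if functional.get(lab, True) and lab in pistil_functional:
            return False
    return True


def _point_fraction(
    seed: SGenotype,
    pollen: SGenotype,
    pollen_ploidy: int,
    functional: Mapping[str, bool],
    fill: str,
) -> Fraction:
    dist = enumerate_gametes(pollen, pollen_ploidy, functional, fill=fill)
    return sum(
        (prob for gamete, prob in dist.gametes
         if pollen_accepted(gamete, seed, functional)),
        Fraction(0),
    )


def cross_compatibility(
    seed_parent: SGenotype,
    pollen_parent: SGenotype,
    pollen_ploidy: int,
    functional: Mapping[str, bool] | None = None,
    interval: bool = False,
) -> CrossResult:
    """Fraction of the pollen parent's gametes accepted by the seed parent.

    The point estimate fills unobserved genome copies (alleles < ploidy)
    with inert placeholders, i.e. assumes no hidden functional matches.
    With ``interval=True`` the result also carries [min, max] bounds over
    consistent completions: the pessimistic bound fills hidden pollen copies
    with distinct functional pistil alleles not already carried (maximally
    matching), the optimistic bound is the point estimate.
    """
    functional = dict(functional or {})
    fraction_exact = _point_fraction(
        seed_parent, pollen_parent, pollen_ploidy, functional, fill="null"
    )
    fraction = float(fraction_exact)
    bounds = None
    if interval:
        deficit = pollen_ploidy - len(pollen_parent.alleles)
        if deficit > 0:
            pistil_functional = sorted(
                lab for lab in seed_parent.allele_set
                if functional.get(lab, True) and lab not in pollen_parent.allele_set
            )
            hidden = pistil_functional[:deficit]
            hidden += [
                f"{_NULL_PREFIX}{pollen_parent.accession_id}.{k}"
                for k in range(deficit - len(hidden))
            ]
            pessimistic = SGenotype(
                accession_id=pollen_parent.accession_id,
                alleles=pollen_parent.alleles + tuple(hidden),
            )
            lo = float(_point_fraction(
                seed_parent, pessimistic, pollen_ploidy, functional, fill="null"
            ))
            bounds = (lo, fraction)
        else:
            bounds = (fraction, fraction)
    return CrossResult(
        seed_parent=seed_parent.accession_id,
        pollen_parent=pollen_parent.accession_id,
        compatible_fraction=fraction,
        category=_categorize(fraction_exact),
        fraction_interval=bounds,
    )


def closed_form_fraction(n: int, s: int, m: int) -> float:
    """Compatible-pollen fraction C(n−s, m)/C(n, m) for a pollen parent with
    n distinct functional alleles, s shared with the pistil, gametes of m."""
    if not 0 <= s <= n or m < 0 or m > n:
        raise ValueError("require 0 <= s <= n and 0 <= m <= n")
    return comb(n - s, m) / comb(n, m)


def incompatibility_groups(
    sgenotypes: Sequence[SGenotype],
    functional: Mapping[str, bool] | None = None,
) -> list[list[str]]:
    """Partition accessions by identical functional S-allele sets.

    Members of one group reject each other's pollen completely (compatible
    fraction 0 in both directions) and must not be co-planted as mutual
    pollinizers."""
    functional = functional or {}
    by_set: dict[frozenset, list[str]] = {}
    for sg in sgenotypes:
        key = frozenset(lab for lab in sg.allele_set if functional.get(lab, True))
        by_set.setdefault(key, []).append(sg.accession_id)
    return sorted((sorted(v) for v in by_set.values()), key=lambda g: g[0])


def predict_self_compatibility(
    sgenotype: SGenotype,
    ploidy: int,
    functional: Mapping[str, bool] | None = None,
) -> float:
    """Fraction of self-pollen accepted under the one-allele-match rule.

    0 for a fully functional genotype; > 0 only when gametes exist composed
    entirely of non-functional alleles (e.g. two non-functional haplotypes
    in a tetraploid give 1/6).
    """
    return cross_compatibility(
        sgenotype, sgenotype, ploidy, functional
    ).compatible_fraction


def compatibility_panel(
    sgenotypes: Sequence[SGenotype],
    accessions: Sequence[Accession],
    functional: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Seed-parent × pollen-parent matrix of compatible-pollen fractions.

    Odd-ploidy pollen parents yield NaN columns (no gamete model); the
    diagonal is the predicted self-compatibility.
    """
    ploidy_of = {a.id: a.ploidy for a in accessions}
    ids = [sg.accession_id for sg in sgenotypes]
    by_id = {sg.accession_id: sg for sg in sgenotypes}
    out = pd.DataFrame(index=ids, columns=ids, dtype=float)
    out.index.name = "seed_parent"
    for pollen_id in ids:
        if ploidy_of[pollen_id] % 2:
            out[pollen_id] = float("nan")
            continue
        for seed_id in ids:
            out.loc[seed_id, pollen_id] = cross_compatibility(
                by_id[seed_id], by_id[pollen_id], ploidy_of[pollen_id], functional
            ).compatible_fraction
    return out
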