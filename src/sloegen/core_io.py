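"""Domain types and table I/O for polyploid *Prunus* genotype data.

The central observability constraint of this package: in a polyploid,
capillary electrophoresis reveals which allele sizes are present at a
locus but not how many genome copies carry each.  A genotype is therefore
a *set* of allele sizes per locus ("dosage-unaware"), bounded above by the
accession's ploidy.

Canonical on-disk format is long CSV/TSV (one observed allele per row,
columns ``accession,locus,allele_bp``); a wide dialect with semicolon-joined
allele lists is accepted on read but never written.  A row with an empty
allele field records a failed amplification: a *missing* locus, which is
distinct from a locus with no shared alleles.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Accession",
    "SSRLocusMeta",
    "PolyGenotype",
    "SAllele",
    "SGenotype",
    "ParseError",
    "ValidationError",
    "read_genotype_table",
    "write_genotype_table",
    "read_sgenotype_table",
    "load_fixture",
    "FIXTURE_NAMES",
]

SPECIES = ("P_spinosa", "P_insititia", "hybrid")


class ParseError(ValueError):
    """Malformed input table (names the offending row)."""


class ValidationError(ValueError):
    """Input violates a biological invariant (e.g. alleles > ploidy)."""


@dataclass(frozen=True)
class Accession:
    """A plant accession (cultivar candidate) in the panel."""

    id: str
    species: str = "P_spinosa"
    ploidy: int = 4
    origin: str = ""

    def __post_init__(self) -> None:
        if self.ploidy < 2:
            raise ValidationError(f"accession {self.id}: ploidy must be >= 2")
        if self.species not in SPECIES:
            raise ValidationError(
                f"accession {self.id}: species must be one of {SPECIES}"
            )


@dataclass(frozen=True)
class SSRLocusMeta:
    """Descriptive metadata for one SSR marker locus."""

    name: str
    linkage_group: str = ""
    source_species: str = ""
    annealing_temp_C: float | None = None
    reported_size_range_bp: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        rng = self.reported_size_range_bp
        if rng is not None and rng[0] > rng[1]:
            raise ValidationError(f"locus {self.name}: size range min > max")


@dataclass
class PolyGenotype:
    """Dosage-unaware multilocus genotype of one accession.

    ``calls`` maps locus name -> frozenset of observed allele sizes (bp).
    Loci that failed to amplify are listed in ``missing`` and carry no entry
    in ``calls``; an empty set never appears.
    """

    accession_id: str
    calls: dict[str, frozenset] = field(default_factory=dict)
    missing: frozenset = frozenset()

    def alleles_at(self, locus: str):
        """Allele set at ``locus`` or ``None`` if the locus is missing/unscored."""
        if locus in self.missing:
            return None
        return self.calls.get(locus)

    def loci(self) -> set:
        return set(self.calls)

    def validate(self, ploidy: int | None = None) -> None:
        for locus, alleles in self.calls.items():
            if not alleles:
                raise ValidationError(
                    f"{self.accession_id}/{locus}: empty allele set "
                    "(use `missing` for amplification failure)"
                )
            if any(isinstance(a, int) and a <= 0 for a in alleles):
                raise ValidationError(
                    f"{self.accession_id}/{locus}: allele sizes must be positive"
                )
            if ploidy is not None and len(alleles) > ploidy:
                raise ValidationError(
                    f"{self.accession_id}/{locus}: {len(alleles)} alleles exceed "
                    f"ploidy {ploidy}"
                )


@dataclass(frozen=True)
class SAllele:
    """One S-RNase allele: label, second-intron fragment length, flags.

    ``approximate`` marks agarose-estimated lengths (printed with "~");
    ``functional`` is False for alleles carrying a lesion such as a premature
    stop codon; ``sequenced`` marks alleles confirmed by DNA sequencing.
    """

    label: str
    fragment_length_bp: int
    approximate: bool = False
    functional: bool = True
    sequenced: bool = False

    def __post_init__(self) -> None:
        if self.fragment_length_bp <= 0:
            raise ValidationError(f"S-allele {self.label}: fragment length must be > 0")


@dataclass
class SGenotype:
    """Set of S-RNase allele labels carried by one accession.

    Stored as a sorted tuple so that duplicated labels can be represented;
    under gametophytic self-incompatibility duplicated alleles can only be
    non-functional, which :meth:`validate` enforces when flags are known.
    """

    accession_id: str
    alleles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.alleles = tuple(sorted(self.alleles))

    @property
    def allele_set(self) -> frozenset:
        return frozenset(self.alleles)

    def validate(
        self,
        ploidy: int | None = None,
        functional: Mapping[str, bool] | None = None,
    ) -> None:
        if ploidy is not None and len(self.alleles) > ploidy:
            raise ValidationError(
                f"{self.accession_id}: {len(self.alleles)} S-alleles exceed "
                f"ploidy {ploidy}"
            )
        if functional is not None:
            seen: set[str] = set()
            for lab in self.alleles:
                if lab in seen and functional.get(lab, True):
                    raise ValidationError(
                        f"{self.accession_id}: duplicated functional allele {lab}"
                    )
                seen.add(lab)


# ---------------------------------------------------------------------------
# Long-format genotype tables


def _sniff_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _parse_allele(text: str, row_no: int, path) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(
            f"{path}, row {row_no}: allele size {text!r} is not an integer"
        ) from None


def read_genotype_table(
    path,
    ploidy: Mapping[str, int] | None = None,
) -> list[PolyGenotype]:
    """Read a long-format genotype CSV/TSV into :class:`PolyGenotype` records.

    One row per observed allele; a semicolon-joined ``allele_bp`` field is
    accepted as a wide dialect.  Rows with an empty allele field mark the
    locus as missing for that accession.  When a ``ploidy`` map is supplied,
    allele counts are validated against it.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    calls: dict[str, dict[str, set]] = {}
    missing: dict[str, set] = {}
    order: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        required = {"accession", "locus", "allele_bp"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(f"{path}: expected columns {sorted(required)}")
        for row_no, row in enumerate(reader, start=2):
            acc = row["accession"].strip()
            locus = row["locus"].strip()
            raw = (row["allele_bp"] or "").strip()
            if acc not in calls:
                calls[acc] = {}
                missing[acc] = set()
                order.append(acc)
            if not raw:
                missing[acc].add(locus)
                continue
            sizes = {_parse_allele(p.strip(), row_no, path) for p in raw.split(";")}
            calls[acc].setdefault(locus, set()).update(sizes)

    genotypes = []
    for acc in order:
        # a locus both scored and flagged missing: the scored rows win
        miss = frozenset(missing[acc] - set(calls[acc]))
        g = PolyGenotype(
            accession_id=acc,
            calls={loc: frozenset(s) for loc, s in calls[acc].items()},
            missing=miss,
        )
        g.validate(ploidy.get(acc) if ploidy else None)
        genotypes.append(g)
    return genotypes


def write_genotype_table(genotypes: Iterable[PolyGenotype], path) -> None:
    """Write genotypes in canonical long format (one allele per row)."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["accession", "locus", "allele_bp"])
        for g in sorted(genotypes, key=lambda g: g.accession_id):
            for locus in sorted(g.calls):
                for allele in sorted(g.calls[locus]):
                    writer.writerow([g.accession_id, locus, allele])
            for locus in sorted(g.missing):
                writer.writerow([g.accession_id, locus, ""])


def read_sgenotype_table(path) -> tuple[list[Accession], list[SGenotype]]:
    """Read an S-genotype CSV: ``accession,species,ploidy,origin,alleles``.

    ``alleles`` is a semicolon-joined list of S-allele labels.
    """
    path = Path(path)
    accessions, sgenotypes = [], []
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            acc = Accession(
                id=row["accession"].strip(),
                species=row.get("species", "P_spinosa").strip(),
                ploidy=int(row.get("ploidy", 4)),
                origin=row.get("origin", "").strip(),
            )
            labels = tuple(
                p.strip() for p in row["alleles"].split(";") if p.strip()
            )
            sg = SGenotype(accession_id=acc.id, alleles=labels)
            sg.validate(ploidy=acc.ploidy)
            accessions.append(acc)
            sgenotypes.append(sg)
    return accessions, sgenotypes


def read_manifest(path) -> list[Accession]:
    """Read a JSON dataset manifest listing accession metadata."""
    with Path(path).open() as fh:
        data = json.load(fh)
    return [Accession(**rec) for rec in data["accessions"]]


# ---------------------------------------------------------------------------
# Packaged fixtures (transcriptions of the published tables)

FIXTURE_NAMES = ("table1_sgenotypes", "table2_locus_stats", "table3_salleles")


def _fixture_path(name: str):
    return resources.files("sloegen.fixtures").joinpath(f"{name}.csv")


def load_fixture(name: str):
    """Load a packaged fixture table.

    ``table1_sgenotypes``
        -> (list of 17 :class:`Accession`, list of 17 :class:`SGenotype`);
        the S-genotypes of the published blackthorn/damson panel.
    ``table2_locus_stats``
        -> list of dicts with the published per-locus summary statistics
        (9 SSR loci plus the S-RNase second-intron marker).
    ``table3_salleles``
        -> list of 23 :class:`SAllele` plus a parallel list of dicts with
        the published per-species occurrence counts.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    res = _fixture_path(name)
    if name == "table1_sgenotypes":
        with resources.as_file(res) as p:
            return read_sgenotype_table(p)
    if name == "table2_locus_stats":
        with res.open(newline="") as fh:
            rows = []
            for row in csv.DictReader(fh):
                for k in ("annealing_temp_C", "size_min_bp", "size_max_bp",
                          "n_alleles", "n_unique_alleles", "n_genotypes"):
                    row[k] = int(row[k])
                row["pic"] = float(row["pic"])
                row["size_approximate"] = row["size_approximate"] == "True"
                rows.append(row)
            return rows
    # table3_salleles
    with res.open(newline="") as fh:
        alleles, occurrences = [], []
        for row in csv.DictReader(fh):
            alleles.append(
                SAllele(
                    label=row["allele"],
                    fragment_length_bp=int(row["size_bp"]),
                    approximate=row["approximate"] == "True",
                    sequenced=row["sequenced"] == "True",
                )
            )
            occurrences.append(
                {
                    "allele": row["allele"],
                    "reported_frequency_pct": float(row["reported_frequency_pct"]),
                    "occ_spinosa": int(row["occ_spinosa"]),
                    "occ_insititia": int(row["occ_insititia"]),
                    "occ_hybrid": int(row["occ_hybrid"]),
                    "occ_total": int(row["occ_total"]),
                }
            )
        return alleles, occurrences


def sgenotypes_as_locus(
    sgenotypes: Iterable[SGenotype], locus: str = "S"
) -> list[PolyGenotype]:
    """View S-genotypes as a single pseudo-locus multiallelic marker.

    Lets the diversity and clustering machinery treat the S-locus exactly
    like an SSR locus whose alleles are labels rather than sizes.
    """
    return [
        PolyGenotype(accession_id=sg.accession_id, calls={locus: sg.allele_set})
        for sg in sgenotypes
    ]
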