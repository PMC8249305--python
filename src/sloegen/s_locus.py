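"""S-RNase allele analysis: fragment binning, occurrence tables,
functionality scanning and Poisson-corrected peptide divergence.

S-genotyping by intron length polymorphism (ILP) amplifies the S-RNase
second intron and assigns fragment lengths to alleles.  Lengths below
~1 kb come from a capillary sequencer and are bp-exact; longer fragments
are agarose-gel estimates, so the default binning tolerance is adaptive:
±10 bp below 1000 bp and ±3% above.  Alleles whose fragments co-migrate
(e.g. lengths 3 bp apart) can only be separated by DNA sequencing; binning
keeps them apart only when such lengths are supplied as sequence-confirmed
anchors, and otherwise merges them with a warning.
"""

from __future__ import annotations

import itertools
import math
import string
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .core_io import Accession, SAllele, SGenotype

__all__ = [
    "FragmentObservation",
    "AlleleCatalog",
    "default_tolerance",
    "bin_fragments",
    "occurrence_table",
    "shared_alleles",
    "StopScanResult",
    "scan_premature_stop",
    "p_distance",
    "poisson_correction",
    "divergence_matrix",
]


@dataclass(frozen=True)
class FragmentObservation:
    """One amplified S-RNase intron fragment in one accession."""

    accession_id: str
    length_bp: int
    intron_region: str = "second"  # {"first", "second"}
    approximate: bool = False

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("fragment length must be positive")
        if self.intron_region not in {"first", "second"}:
            raise ValueError("intron_region must be 'first' or 'second'")


@dataclass
class AlleleCatalog:
    """Binned allele definitions: label -> representative length and window."""

    alleles: list[SAllele]
    windows: dict[str, tuple[int, int]]

    def label_for_length(self, length: int) -> str:
        for lab, (lo, hi) in self.windows.items():
            if lo <= length <= hi:
                return lab
        raise KeyError(f"length {length} falls in no allele window")


def default_tolerance(length: int) -> float:
    """Adaptive binning tolerance: ±10 bp below 1000 bp (sequencer-exact
    territory), ±3% above (agarose estimates)."""
    return 10.0 if length < 1000 else 0.03 * length


def _letters():
    for size in range(1, 4):
        for combo in itertools.product(string.ascii_uppercase, repeat=size):
            yield "".join(combo)


def bin_fragments(
    observations: Sequence[FragmentObservation],
    tolerance: float | Callable[[int], float] | None = None,
    sequence_confirmed: Iterable[int] = (),
    label_prefix: str = "S_",
) -> tuple[AlleleCatalog, dict[str, SGenotype]]:
    """Assign fragment lengths to S-alleles by single-linkage 1-D clustering.

    Adjacent sorted lengths join one cluster when their gap is within
    tolerance (a number, or a callable of the smaller length; default
    :func:`default_tolerance`).  Lengths listed in ``sequence_confirmed``
    are anchors that always found their own allele: a cluster containing
    several anchors is split between them (unconfirmed lengths join the
    nearest anchor), and any merge of lengths closer than tolerance without
    sequence confirmation raises a warning naming the ambiguous pair.

    Labels are assigned in descending carrier frequency, ties by ascending
    representative length: S_A, S_B, ...  Returns the catalog and one
    :class:`~sloegen.core_io.SGenotype` per accession.
    """
    if not observations:
        raise ValueError("no fragment observations")
    if callable(tolerance):
        tol = tolerance
    elif tolerance is None:
        tol = default_tolerance
    elif tolerance <= 0:
        raise ValueError("tolerance must be positive")
    else:
        tol = lambda L, _t=tolerance: _t  # noqa: E731

    confirmed = set(sequence_confirmed)
    lengths = sorted({obs.length_bp for obs in observations})
    clusters: list[list[int]] = [[lengths[0]]]
    for prev, cur in zip(lengths, lengths[1:]):
        if cur - prev <= tol(prev):
            clusters[-1].append(cur)
        else:
            clusters.append([cur])

    # split clusters around sequence-confirmed anchors
    final: list[list[int]] = []
    for cluster in clusters:
        anchors = [L for L in cluster if L in confirmed]
        if len(anchors) <= 1:
            if len(cluster) > 1:
                warnings.warn(
                    f"fragment lengths {cluster} merged into one allele; "
                    "DNA sequencing would be required to distinguish them",
                    stacklevel=2,
                )
            final.append(cluster)
            continue
        parts: dict[int, list[int]] = {a: [] for a in anchors}
        for L in cluster:
            nearest = min(anchors, key=lambda a: (abs(L - a), a))
            parts[nearest].append(L)
        final.extend(parts[a] for a in anchors)

    # carrier counts per cluster for label ordering
    rep = {tuple(c): min(c, key=lambda L: (L not in confirmed, L)) for c in final}
    carriers: dict[tuple, set] = {tuple(c): set() for c in final}
    member_of = {L: tuple(c) for c in final for L in c}
    for obs in observations:
        carriers[member_of[obs.length_bp]].add(obs.accession_id)
    ordered = sorted(
        final, key=lambda c: (-len(carriers[tuple(c)]), rep[tuple(c)])
    )
    alleles, windows, label_of = [], {}, {}
    for cluster, letter in zip(ordered, _letters()):
        label = f"{label_prefix}{letter}"
        r = rep[tuple(cluster)]
        approx = all(
            obs.approximate for obs in observations if obs.length_bp in cluster
        )
        alleles.append(
            SAllele(
                label=label,
                fragment_length_bp=r,
                approximate=approx,
                sequenced=r in confirmed,
            )
        )
        windows[label] = (min(cluster), max(cluster))
        for L in cluster:
            label_of[L] = label
    catalog = AlleleCatalog(alleles=alleles, windows=windows)

    genotypes: dict[str, set] = {}
    for obs in observations:
        genotypes.setdefault(obs.accession_id, set()).add(label_of[obs.length_bp])
    sgenotypes = {
        acc: SGenotype(accession_id=acc, alleles=tuple(labels))
        for acc, labels in sorted(genotypes.items())
    }
    return catalog, sgenotypes


def occurrence_table(
    sgenotypes: Sequence[SGenotype],
    accessions: Sequence[Accession],
    allele_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-allele carrier counts by species class plus the occurrence-based
    frequency (total carriers / all occurrences).

    One row per allele with columns ``P_spinosa``, ``P_insititia``,
    ``hybrid``, ``total`` and ``frequency``.
    """
    species_of = {a.id: a.species for a in accessions}
    rows: dict[str, dict] = {}
    for sg in sgenotypes:
        if sg.accession_id not in species_of:
            raise KeyError(f"unknown accession id {sg.accession_id!r}")
        sp = species_of[sg.accession_id]
        for lab in sg.allele_set:
            row = rows.setdefault(
                lab, {"P_spinosa": 0, "P_insititia": 0, "hybrid": 0, "total": 0}
            )
            row[sp] += 1
            row["total"] += 1
    if allele_order is None:
        allele_order = sorted(rows)
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(allele_order)
    grand = int(df["total"].sum()) if len(df) else 0
    df["frequency"] = df["total"] / grand if grand else 0.0
    df.index.name = "allele"
    return df


def shared_alleles(g1: SGenotype, g2: SGenotype) -> frozenset:
    """Labels common to two S-genotypes (set intersection)."""
    return g1.allele_set & g2.allele_set


# ---------------------------------------------------------------------------
# Functionality scanning


@dataclass(frozen=True)
class StopScanResult:
    functional: bool
    stop_codon_index: int | None = None  # 1-based codon position of the lesion


_IUPAC = set("ACGTRYSWKMBDHVN")


def scan_premature_stop(
    cds_sequence: str, expected_protein_end: int | None = None
) -> StopScanResult:
    """Scan an in-frame coding sequence for a premature stop codon.

    ``expected_protein_end`` is the expected protein length in codons
    (default: the full sequence length / 3).  A stop at or beyond the
    expected final codon leaves the allele functional; any earlier in-frame
    stop marks it truncated, reporting the 1-based codon index.  This is the
    test that exposes e.g. an AAA→TAA change turning a lysine codon into a
    stop within the rejection hypervariable region.
    """
    seq = cds_sequence.strip().upper().replace("U", "T")
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC bases in sequence: {sorted(bad)}")
    if len(seq) % 3:
        raise ValueError("coding sequence length must be divisible by 3")
    n_codons = len(seq) // 3
    if expected_protein_end is None:
        expected_protein_end = n_codons
    protein = str(Seq(seq).translate())
    stop = protein.find("*")
    if stop == -1 or stop + 1 >= expected_protein_end:
        return StopScanResult(functional=True)
    return StopScanResult(functional=False, stop_codon_index=stop + 1)


# ---------------------------------------------------------------------------
# Peptide divergence


def _complete_deletion_columns(sequences: Sequence[str], gap: str = "-"):
    ncol = len(sequences[0])
    if any(len(s) != ncol for s in sequences):
        raise ValueError("aligned sequences must have equal length")
    gapset = {gap, ".", "?", "X"}
    return [
        k for k in range(ncol)
        if all(s[k].upper() not in gapset for s in sequences)
    ]


def p_distance(
    alignment: Sequence[str], i: int, j: int, gap: str = "-"
) -> float:
    """Proportion of differing positions between aligned peptides i and j.

    Complete deletion: columns containing a gap or missing datum in *any*
    sequence of the alignment are removed before counting, so all pairwise
    distances share one common set of positions.
    """
    seqs = [str(s) for s in alignment]
    cols = _complete_deletion_columns(seqs, gap=gap)
    if not cols:
        raise ValueError("no columns remain after complete deletion")
    a, b = seqs[i].upper(), seqs[j].upper()
    diffs = sum(1 for k in cols if a[k] != b[k])
    return diffs / len(cols)


def poisson_correction(p: float) -> float:
    """Poisson-corrected divergence d = −ln(1 − p) for an observed
    proportion p of amino-acid differences; corrects for multiple hits."""
    if not 0 <= p < 1:
        raise ValueError("p must satisfy 0 <= p < 1 (saturated distance)")
    return -math.log1p(-p)


def divergence_matrix(
    alignment: Sequence[str], names: Sequence[str] | None = None, gap: str = "-"
) -> pd.DataFrame:
    """Pairwise Poisson-corrected divergence matrix (3-decimal report scale
    applies at write-out; values here are unrounded)."""
    n = len(alignment)
    if names is None:
        names = [f"seq{k+1}" for k in range(n)]
    mat = [[0.0] * n for _ in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        d = poisson_correction(p_distance(alignment, i, j, gap=gap))
        mat[i][j] = mat[j][i] = d
    return pd.DataFrame(mat, index=list(names), columns=list(names))
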