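"""Per-locus diversity statistics for dosage-unaware polyploid genotypes.

Allele frequencies are *presence-based*: every accession carrying an allele
contributes exactly one count for it, regardless of (unobservable) copy
number.  The polymorphic information content (PIC) uses the full
Botstein-style formula

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2,

which subtracts the probability that two random genotypes are uninformative
heterozygote pairs; expected heterozygosity He = 1 - sum p_i^2 is reported
alongside it as a secondary column.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import PolyGenotype

__all__ = [
    "FrequencySpectrum",
    "LocusSummary",
    "presence_frequencies",
    "pic",
    "expected_heterozygosity",
    "locus_summary",
    "summarize_loci",
    "find_clonal_groups",
    "minimal_discriminating_sets",
    "DiscriminatingSetResult",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report-table convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FrequencySpectrum:
    """Presence-based allele frequencies at one locus.

    ``counts[a]`` = number of accessions carrying allele ``a``;
    ``total`` = sum of counts (total allele occurrences at the locus);
    ``freqs[a]`` = counts[a] / total.
    """

    locus: str
    counts: Mapping
    total: int

    @property
    def freqs(self) -> dict:
        return {a: c / self.total for a, c in self.counts.items()}

    @property
    def p(self) -> np.ndarray:
        return np.array(list(self.counts.values()), dtype=float) / self.total


@dataclass(frozen=True)
class LocusSummary:
    locus: str
    n_scored: int
    n_alleles: int
    size_range_bp: tuple[int, int] | None
    n_unique_alleles: int
    n_distinct_profiles: int
    pic: float
    expected_heterozygosity: float


def _scored(genotypes: Iterable[PolyGenotype], locus: str):
    """Genotypes with a non-missing call at ``locus``."""
    out = []
    for g in genotypes:
        alleles = g.alleles_at(locus)
        if alleles:
            out.append((g.accession_id, alleles))
    return out


def presence_frequencies(
    genotypes: Iterable[PolyGenotype], locus: str
) -> FrequencySpectrum:
    """Presence-based allele frequency spectrum at one locus.

    Each accession contributes one count per distinct allele it carries;
    accessions missing the locus are excluded from the denominator.
    """
    scored = _scored(genotypes, locus)
    if not scored:
        raise ValueError(f"no accession scored at locus {locus!r}")
    counts: dict = {}
    for _, alleles in scored:
        for a in alleles:
            counts[a] = counts.get(a, 0) + 1
    counts = dict(sorted(counts.items(), key=lambda kv: _allele_key(kv[0])))
    return FrequencySpectrum(locus=locus, counts=counts, total=sum(counts.values()))


def _allele_key(a):
    return (0, a) if isinstance(a, int) else (1, str(a))


def pic(spectrum: FrequencySpectrum | Sequence[float]) -> float:
    """Polymorphic information content of a frequency spectrum.

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2.  Equals 0 for a
    monomorphic locus and approaches 1 for many equifrequent alleles.
    """
    p = spectrum.p if isinstance(spectrum, FrequencySpectrum) else np.asarray(
        spectrum, dtype=float
    )
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    # sum_{i<j} 2 p_i^2 p_j^2 == (sum p^2)^2 - sum p^4
    return 1.0 - s2 - (s2**2 - s4)


def expected_heterozygosity(spectrum: FrequencySpectrum | Sequence[float]) -> float:
    """He = 1 - sum p_i^2 (gene diversity under presence-based frequencies)."""
    p = spectrum.p if isinstance(spectrum, FrequencySpectrum) else np.asarray(
        spectrum, dtype=float
    )
    return 1.0 - float(np.sum(p**2))


def locus_summary(genotypes: Sequence[PolyGenotype], locus: str) -> LocusSummary:
    """All per-locus report statistics: allele counts, unique alleles,
    distinct profiles, PIC and He.

    A *unique* allele is carried by exactly one accession; a *profile* is
    the full allele set of one accession at the locus.
    """
    spectrum = presence_frequencies(genotypes, locus)
    scored = _scored(genotypes, locus)
    sizes = [a for a in spectrum.counts if isinstance(a, (int, np.integer))]
    size_range = (min(sizes), max(sizes)) if len(sizes) == len(spectrum.counts) else None
    profiles = {alleles for _, alleles in scored}
    return LocusSummary(
        locus=locus,
        n_scored=len(scored),
        n_alleles=len(spectrum.counts),
        size_range_bp=size_range,
        n_unique_alleles=sum(1 for c in spectrum.counts.values() if c == 1),
        n_distinct_profiles=len(profiles),
        pic=pic(spectrum),
        expected_heterozygosity=expected_heterozygosity(spectrum),
    )


def summarize_loci(
    genotypes: Sequence[PolyGenotype], loci: Sequence[str] | None = None
) -> pd.DataFrame:
    """Report table with one row per locus (PIC and He rounded to 2 d.p.,
    half-up), mirroring the published per-locus summary layout."""
    if loci is None:
        loci = sorted({loc for g in genotypes for loc in g.calls})
    rows = []
    for locus in loci:
        s = locus_summary(genotypes, locus)
        rows.append(
            {
                "locus": s.locus,
                "n_scored": s.n_scored,
                "size_min_bp": s.size_range_bp[0] if s.size_range_bp else None,
                "size_max_bp": s.size_range_bp[1] if s.size_range_bp else None,
                "n_alleles": s.n_alleles,
                "n_unique_alleles": s.n_unique_alleles,
                "n_distinct_profiles": s.n_distinct_profiles,
                "pic": round_half_up(s.pic),
                "expected_heterozygosity": round_half_up(s.expected_heterozygosity),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clone detection and minimal discriminating marker sets


def _profile(g: PolyGenotype, markers: Sequence[str]):
    return tuple(g.calls[m] for m in markers)


def find_clonal_groups(
    genotypes: Sequence[PolyGenotype], markers: Sequence[str] | None = None
) -> tuple[list[list[str]], list[str]]:
    """Partition accessions by identical multilocus profiles.

    Returns ``(groups, excluded)`` where ``groups`` are lists of accession
    ids sharing an identical profile over ``markers`` (sorted; groups of
    size >= 2 are putative clones) and ``excluded`` lists accessions not
    scored at every requested marker.
    """
    if markers is None:
        markers = sorted({loc for g in genotypes for loc in g.calls})
    markers = list(markers)
    if not markers:
        raise ValueError("empty marker subset")
    excluded = sorted(
        g.accession_id
        for g in genotypes
        if any(g.alleles_at(m) is None for m in markers)
    )
    by_profile: dict = {}
    for g in genotypes:
        if g.accession_id in excluded:
            continue
        by_profile.setdefault(_profile(g, markers), []).append(g.accession_id)
    groups = sorted(
        (sorted(members) for members in by_profile.values()),
        key=lambda grp: grp[0],
    )
    return groups, excluded


@dataclass(frozen=True)
class DiscriminatingSetResult:
    """Result of the minimal discriminating marker-set search."""

    sets: tuple[tuple[str, ...], ...]  # all smallest solutions, () if none
    size: int | None                   # cardinality of the solutions
    unresolved_pairs: tuple[tuple[str, str], ...]  # diagnostic when empty


def minimal_discriminating_sets(
    genotypes: Sequence[PolyGenotype],
    max_size: int,
    markers: Sequence[str] | None = None,
) -> DiscriminatingSetResult:
    """All smallest marker subsets that separate every non-clonal pair.

    Clonal groups (identical over the full marker panel) are collapsed to a
    representative first, since no subset can separate true clones.  The
    search is exhaustive over subsets of size 1..max_size and stops at the
    first size admitting a solution.  When no subset works, the result
    carries the pairs left unresolved by the best subset of ``max_size``.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    if markers is None:
        markers = sorted({loc for g in genotypes for loc in g.calls})
    markers = list(markers)
    groups, excluded = find_clonal_groups(genotypes, markers)
    reps = {grp[0] for grp in groups}
    panel = [
        g for g in genotypes
        if g.accession_id in reps and g.accession_id not in excluded
    ]

    def unseparated(subset):
        by_profile: dict = {}
        for g in panel:
            by_profile.setdefault(_profile(g, subset), []).append(g.accession_id)
        pairs = []
        for members in by_profile.values():
            pairs.extend(itertools.combinations(sorted(members), 2))
        return sorted(pairs)

    best_pairs = None
    for size in range(1, max_size + 1):
        solutions = []
        for subset in itertools.combinations(markers, size):
            pairs = unseparated(subset)
            if not pairs:
                solutions.append(subset)
            elif best_pairs is None or len(pairs) < len(best_pairs):
                best_pairs = pairs
        if solutions:
            return DiscriminatingSetResult(
                sets=tuple(solutions), size=size, unresolved_pairs=()
            )
    return DiscriminatingSetResult(
        sets=(), size=None, unresolved_pairs=tuple(best_pairs or ())
    )
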