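# Methods

## The data model: dosage-unaware polyploid genotypes

Blackthorn (*Prunus spinosa*) is tetraploid, damson plum (*P. domestica*
subsp. *insititia*) hexaploid, and their spontaneous or bred hybrids
pentaploid.  Capillary or gel electrophoresis of an SSR or S-RNase intron
amplicon reveals *which* allele sizes an accession carries at a locus but
not how many genome copies carry each; an accession with fewer distinct
alleles than genome copies may harbour null alleles or multi-copy alleles,
and the two cannot be distinguished from fragment data.  The package
therefore represents a genotype as a set of alleles per locus
(`PolyGenotype`), bounded above by the declared ploidy, with amplification
failure recorded as an explicit *missing* state distinct from any scored
set.  All downstream statistics are defined on this observable.

## Diversity statistics

Allele frequencies are presence-based: each accession contributes one count
per distinct allele it carries, and the denominator is the total number of
(accession, allele) occurrences at the locus.  Accessions missing a locus
are excluded from that locus's spectrum rather than treated as null-allele
carriers.  Presence-based frequencies are a biased estimator of the
underlying chromosomal frequencies — they compress skewed spectra toward
uniformity, because a common allele is counted once per carrier no matter
how many copies the carrier holds — but they are the only estimator
available without dosage, and the bias vanishes as the spectrum approaches
uniformity (the synthetic-data tests exercise exactly that regime).

Polymorphic information content uses the full Botstein-style formula

    PIC = 1 − Σᵢ pᵢ² − Σ_{i<j} 2 pᵢ² pⱼ²,

implemented through the identity Σ_{i<j} 2pᵢ²pⱼ² = (Σpᵢ²)² − Σpᵢ⁴ and
cross-checked in tests against a literal double loop.  Expected
heterozygosity He = 1 − Σpᵢ² is reported as a secondary column; the two
differ at the second decimal for highly multiallelic loci (0.93 vs 0.94 on
the packaged S-locus panel), which is why the distinction matters for
report tables.  Report rounding is two decimals, half-up.  For a uniform
k-allele spectrum, PIC = 1 − 1/k − (k−1)/k³, an identity the tests assert.

Clone detection partitions accessions by identical multilocus profiles;
groups of two or more are putative clones.  The minimal discriminating
marker-set search is exhaustive over subsets of size 1..max_size after
collapsing clonal groups (no subset can separate true clones), stopping at
the first cardinality that admits a solution and returning all solutions of
that size.  With ≤ a dozen markers the search space is trivial; the
implementation makes no attempt at branch-and-bound.

## Distance analysis

Each observed (locus, allele) pair becomes a presence/absence column.
Pairwise similarity is the Dice coefficient D = 2|A∩B|/(|A|+|B|) with
pairwise deletion: columns belonging to a locus missing in either accession
of a pair are excluded for that pair only.  A pair left with no scored
alleles has no defined similarity and raises, except inside bootstrap
replicates where it is scored 0 so a replicate cannot abort the run.

UPGMA (group-average agglomeration on 1−D) is implemented in the package
because two requirements are not served by off-the-shelf linkage routines:
deterministic tie-breaking (ties merge the lexicographically smallest pair
of minimal member ids, so reruns and replicates produce identical trees)
and per-node leaf-bipartition bookkeeping for bootstrap support.  Node
height is half the merge distance, giving ultrametric branch lengths;
monotonicity of merge heights is asserted on every run.  Tests cross-check
the cophenetic distances against an independent average-linkage
implementation on random inputs.

Bootstrap supports resample allele columns with replacement (the standard
unit for binary multilocus fingerprints; `unit="locus"` resamples whole
loci instead), rebuild Dice + UPGMA, and report for each internal node the
percentage of replicates containing its exact leaf bipartition.  The
default replicate count is 2000.

The cophenetic correlation is the Pearson r between input and tree-implied
pairwise distances.  Significance comes from a label-permutation null: leaf
labels are randomly reassigned to tree positions and r recomputed, with a
one-sided (greater) p-value and the +1 correction.  This is an
approximation in the spirit of the standard permutation tests for dendrogram
fit rather than any particular published variant; an exhaustive-enumeration
oracle at four leaves validates the sampled p.  Constant input distances
make r undefined and are reported as NaN rather than an arbitrary value.

PCA operates on the column-centred binary matrix (covariance mode;
correlation mode is an option).  Variance fractions are taken against the
total variance, so they sum to one over all axes even when trailing axes
are rank-deficient.  Sign convention: the largest-magnitude loading on each
axis is made positive.  Cells of missing loci enter as absences, a
simplification acceptable at the panel's low missingness.

## S-locus analysis

Fragment-to-allele binning is single-linkage clustering on the sorted
lengths: adjacent lengths merge while the gap is within tolerance.  The
default tolerance is ±10 bp below 1000 bp (sequencer-exact territory) and
±3% above (agarose estimates).  Lengths supplied as *sequence-confirmed*
anchors always found their own allele: a cluster holding several anchors is
split between them, which is how co-migrating alleles 3 bp apart (713/716
in the packaged catalogue) stay distinct; the same pair without sequence
confirmation merges with a warning.  Labels are assigned by descending
carrier frequency, ties by ascending size.  A flat 20 bp tolerance is *not*
a safe default for the packaged sizes: two unconfirmed sizes sit 17 bp
apart (610/627) and would spuriously merge.

The occurrence table counts carriers per species class and reports
frequency as carriers / total occurrences.  The packaged fixture also
retains the originally published frequency percentages, whose denominator
(79) does not equal the 68 occurrences countable from the genotype table;
the package reports its own occurrence-based values and keeps the printed
column purely as a transcription.

Functionality scanning translates an in-frame CDS and reports the first
in-frame stop before the expected protein end with its 1-based codon index
(detecting e.g. an AAA→TAA lysine→stop change); a stop only at the final
codon leaves the allele functional.  Peptide divergence is the p-distance
under complete deletion (columns with a gap or missing symbol in *any*
sequence are removed for all pairs) with the Poisson correction
d = −ln(1−p); p ≥ 1 is a saturation error, and d is strictly increasing and
convex on [0, 1).

## Mating model

Meiosis in these polysomic polyploids is modelled with equal chance for all
chromosome pairings: every m-subset of a 2m-ploid parent's S-locus copies
is an equally likely pollen gamete.  Probabilities are exact rationals
(`fractions.Fraction`), so enumeration agrees bit-for-bit with the
hypergeometric closed form C(n−s, m)/C(n, m) for n distinct functional
alleles with s shared.  Rejection follows the one-allele-match rule: a
gamete fails iff it carries a functional allele matching a functional
pistil S-RNase; non-functional alleles (premature-stop S-RNases) never
reject.  Competitive interaction between heteroallelic pollen genotypes is
deliberately not modelled.

Two tetraploids sharing two of four functional alleles give a compatible
fraction of C(2,2)/C(4,2) = 1/6 ≈ 16.7%, and a fully shared functional set
gives 0 in both directions — the criterion for a cross-incompatibility
group.  A genotype with a single non-functional allele still predicts zero
accepted self-pollen under this rule; observed self-fertility in such a
genotype is therefore a genuine model-vs-observation discrepancy, which the
package reports as computed rather than patching.

Genotypes with fewer observed alleles than genome copies are handled three
ways: strict mode fills the deficit by duplicating a non-functional allele
when that choice is unique and errors otherwise; the point estimate fills
with inert placeholders (no hidden functional matches); interval mode also
reports a pessimistic bound obtained by filling hidden pollen copies with
distinct functional pistil alleles, which by the monotonicity of the
acceptance fraction in shared alleles is the attained minimum.  Odd-ploidy
parents are refused on the pollen side with an explanatory error — no
pentaploid meiosis model is assumed — and allowed as pistil parents.

## Synthetic data

The generator draws, per accession and locus, `ploidy` allele copies with
replacement from a locus pool with Dirichlet-distributed frequencies, then
discards dosage: the observed call is the distinct-allele set.  S-genotypes
are drawn with rejection so that functional alleles are never duplicated.
Planted structure: clonal duplicates (exact copies), and interploidy
hybrids formed by the union of one random gamete from each parent, with the
pollen gamete resampled until the seed parent's pistil accepts it (and
parent pairs drawn only from crosses with a positive compatible fraction).
Defaults mirror the packaged study panel: 17 accessions — 10 tetraploid,
4 hexaploid including one clone pair, 3 pentaploid hybrids — nine SSR loci
with the panel's per-locus allele-pool sizes and size ranges, and a
23-allele S pool with one non-functional member.

What the generator does not emulate: mutation or coalescent structure,
linkage between loci (all loci independent), population substructure beyond
the planted clusters, allele-size stutter or scoring error.  Passing tests
therefore demonstrate correctness of the statistics on clean set-valued
genotypes, not robustness to genotyping noise.

## Numerical and design choices

- Exact rational arithmetic in the mating model; floating point elsewhere.
- UPGMA tie-break lexicographic; bootstrap and permutation RNG is a single
  seeded `numpy` generator per run, so outputs byte-reproduce.
- Dice of an empty masked pair: error (or 0 inside bootstrap replicates).
- Problem sizes in the test suite are chosen to keep the full run around a
  few seconds: bootstrap tests use 50–400 replicates (clone support of 100%
  is invariant to replicate count), the permutation oracle uses 4 leaves
  against 4999 samples, and the clone-recovery sweep runs 100 seeded
  datasets at the default 17-accession panel.
- First-intron fragment observations can be stored but do not contribute to
  genotype calls; second-intron data are the calling basis.

## Known limitations

- Presence-based frequencies understate common-allele frequencies in
  skewed spectra; no dosage or null-allele inference is attempted.
- The cophenetic permutation test is an approximation, not an exact
  published variant.
- The mating model ignores pollen-fertility losses from unbalanced
  (e.g. pentaploid) meiosis, so its compatible fractions are upper bounds
  on realized siring ability.
- PCA treats missing-locus cells as absences rather than imputing.
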