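# Methods

## SSR detection model

A perfect SSR is a maximal run of period L (1–6) whose initial L-mer is a
primitive motif (not a whole-number power of a shorter string). Runs are
found per period with a vectorized shift-and-compare; the reported tract
starts at the leftmost base of the run and counts whole motif copies only,
so `end − start = L × n_repeats` always holds and a trailing partial copy is
excluded. A run whose initial L-mer is non-primitive (e.g. ATAT at period 4)
is skipped because the identical region is reported at its primitive period
(AT at period 2) — this is what makes "ATATATATATAT is a di, never a tetra"
true by construction. N bases terminate runs and never match; any other
non-ACGT character is an input error naming its offset. Thresholds default
to 10/6/5/5/5/5 minimum repeats for mono–hexa motifs, the standard
MISA-style setting for EST-SSR surveys.

Two or more tracts with successive gaps ≤ 100 bp merge into a compound SSR
spanning first start to last end. The low-level `merge_compound` treats
overlapping inputs as a contract violation; the `mine_sequence` pipeline
instead passes `on_overlap="merge"` because maximal runs of *different*
motifs can legitimately share a base (a mono run abutting a di run), and
MISA likewise folds interleaved repeats into the compound annotation.

Motif tallies are emitted twice: raw (the reported phase, GAG and CCT
separate) and canonical (lexicographic minimum over rotations of the motif
and its reverse complement, so CT/AG is one class). Published tables mix
the two conventions; keeping both avoids silent reinterpretation. The
transcribed motif-type block sums to 429 over a stated 418-locus total —
an inconsistency in the source tables; our own tallies count each locus
exactly once, and percentage recomputation uses the 418 denominator the
source used.

## Marker design

Primer scanning is an exhaustive enumeration of flanking windows under the
bounds: length 16–22 nt, GC 40–60 %, Tm 50–60 °C, product 100–500 bp. Tm is
the basic GC-count formula `64.9 + 41 (n_GC − 16.4)/ℓ` °C — a deterministic,
monotone stand-in for nearest-neighbour thermodynamics, which is out of
scope; the acceptance band (50–60 °C) is what the pipeline actually
enforces. Pairs are ranked |Tm_f − Tm_r| ascending, then product size
closest to 300 bp, then leftmost, giving a total deterministic order where
no canonical ranking exists.

Exon containment is closed-boundary: an amplicon coinciding exactly with an
exon passes, the weaker reading of "inside a single exon". Deduplication
clusters candidates by genomic interval overlap (connected components via a
sweep) and picks one representative per cluster by tract length descending,
then mean primer Tm closest to 55 °C, then motif-type priority
(tri > hexa > di > tetra > penta > mono > compound — frame-preserving
motifs first), then stable id; the representative records the union of
source individuals. Spacing is greedy left-to-right per chromosome at
≥ 1 Mbp between kept starts — simple and deterministic rather than
maximum-cardinality. The exon filter runs before spacing. Marker ids are
assigned in genomic order with a configurable prefix (default `Acro`).

## Marker statistics

All frequency-based statistics use p̂ᵢ = allele count / (2 n_typed) with
missing calls excluded listwise per locus. He is the plain 1 − Σp² (the
GenAlEx default); the (2n)/(2n−1) unbiased variant sits behind a flag.
PIC and PI use the power-sum identities
`PIC = 1 − s₂ − (s₂² − s₄)` and `PI = 2s₂² − s₄` with s_k = Σpᵢᵏ, which are
exact and O(#alleles). Category boundaries: high ≥ 0.50, medium ≥ 0.25,
low > 0, null = 0; the boundaries are closed on the upper category, so
PIC = 0.50 is high and 0.25 is medium. Allele identity is the exact size
in bp (bin width 0 by default). Monomorphic loci get Ne = 1,
He = Ho = I = PIC = 0, PI = 1.

A private allele has positive frequency in exactly one group; the grouping
unit defaults to the sampling-location label. Transfer percentages are
round-half-up and reported both at 1 decimal and as integers because
published tables mix the conventions; 143/145 = 98.62 % therefore prints as
98.6/99, not the floored 98 sometimes seen in print.

## Nei distance and PCoA

D = −ln I with I = J_ab / √(J_a J_b), the J's being locus-averaged gene
identities; loci undefined in either unit are dropped pairwise. I is
clamped at 1 against float fuzz (Cauchy–Schwarz bounds it analytically), so
D ≥ 0 exactly. Disjoint profiles give D = +∞ with a warning; before PCoA,
infinite entries are capped at max finite + 1 (configurable), keeping the
scaling defined while preserving rank order.

PCoA is classical Gower scaling: B = −½ J D² J, symmetric
eigendecomposition, coordinates = eigenvectors × √λ for the positive
spectrum. Negative eigenvalues (non-Euclidean input) are reported but
excluded from the variance denominator. Axis signs are fixed by making each
axis's first nonzero coordinate positive. Individuals-as-units mode treats
each sample as a population of one (frequencies 0/0.5/1), matching the
individual-by-distance workflow; a pooled per-group mode is also available.
The covariance-standardized PCoA variant found in some packages is not
implemented; classical scaling is the documented choice.

## Synthetic data

`generate_genome` plants SSR tracts of known motif/repeat number into
uniform-random background, separated by more than the compound gap so
truth is unambiguous, then repeatedly re-randomizes any window where the
miner detects a non-planted tract (or a lucky extension of a planted one)
until the detectable set equals the planted set exactly — planted bases are
never rewritten, and the loop aborts after 1000 rounds as an infeasible
plan. The truth is therefore exact by construction *with respect to the
detection model*, which is what planted-recovery tests require. Exonic
tracts get a two-exon transcript whose first exon contains the tract with
primer-compatible flanks.

`simulate_genotypes` uses the Balding–Nichols model: ancestral frequencies
~ symmetric Dirichlet(α) (clipped below at 10⁻³ and renormalized so every
planned allele remains representable), group frequencies ~
Dirichlet(p_anc(1−F)/F), Hardy–Weinberg draws within groups, allele sizes
base + step·index, missing-at-random masking. F = 0 short-circuits to
identical group frequencies. Defaults emulate a realistic validation
design: 17 samples in 6 geographic groups (3,3,3,3,3,2), 145 loci with
allele counts cycling 1–8 (mean ≈ 3.3, monomorphic loci included), step
3 bp, F = 0.15, 3 % missing data. `simulate_transfer` draws independent
Bernoulli amplification per species × marker; the default six-species panel
uses the observed rates of the motivating survey (144, 143, 117, 117, 102,
104 out of 145).

What the generators do **not** emulate: assembly chimerism and redundancy
across individuals, stutter/size-homoplasy in electrophoresis, null
alleles, linkage, selection on genic repeats, and realistic base
composition. Passing tests therefore demonstrate correctness of the
algorithms under the stated models, not robustness to those real-data
artefacts.

## Numerical and testing choices

Distance matrices must be symmetric within 1e-12 with zero diagonal;
eigenvalues below 1e-12 of the spectral radius are treated as zero in PCoA.
Percent rounding is decimal round-half-up. Property tests (hypothesis,
derandomized) check miner–oracle equivalence against an exhaustive
substring oracle on sequences up to a few hundred bp plus fixed 5 kb
planted cases; dedup/spacing/merge operations are checked against
independent graph-component and greedy re-implementations; PCoA is checked
against a known 2-D configuration (Procrustes error < 1e-8) and an
independent ordination library. Problem sizes in tests and the acceptance
script (synthetic chromosomes of 20–40 kb, 500 diploids for frequency
recovery, 40–60 loci for ordination) were chosen as the smallest sizes at
which the statistical checks are stable.

## Known limitations

* Primer scanning is exhaustive and quadratic in flank length; it is meant
  for per-locus windows (≤ ~600 bp flanks), not whole-chromosome scans.
* The Tm model ignores salt and nearest-neighbour effects; bounds are
  calibrated to the simple formula only.
* Transcript-to-genome placement is assumed given (loci arrive with genomic
  coordinates); no alignment is performed.
* Nei distance between individuals saturates quickly with few loci and can
  be infinite for disjoint genotypes; the cap keeps ordination defined but
  compresses extreme divergence.
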