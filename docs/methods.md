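# Methods

`hybridtrio` analyses gene expression inheritance in a hybrid trio — one
hybrid sample and one sample from each parental lineage, a single RNA-seq
library per condition. This note describes the statistical procedure, the
parameters that matter, the synthetic benchmark, and the design choices
made where the design was genuinely open.

## Input model

Inputs are gene-level quantification tables in the RSEM `genes.results`
style (`gene_id`, `length`, `expected_count`, `TPM`; extra columns
ignored) plus a design file mapping each file to a role (`hybrid`,
`parent1`, `parent2`). Counts are expected counts and may be non-integer;
they are rounded only where a multinomial draw requires integers. An
optional list of ORF-bearing gene ids feeds the expressed-gene filter;
without one, every gene is treated as ORF-bearing.

## Expressed-gene filter

A gene is *expressed* when it has a potential open reading frame and
reaches at least `min_tpm` (default 1) TPM. TPM is recomputed from counts
and lengths (`TPM_gs = 1e6 (c_gs/l_g) / Σ_g' c_g's/l_g'`); the input TPM
column is ignored for filtering so the filter is self-consistent. The
threshold is applied in **at least one** sample of the trio by default
(`require="any"`): the least destructive reading when quantification is
against a pooled co-assembly. `require="all"` gives the stricter variant.
The boundary is inclusive (TPM = 1 passes). The `length` column is used
as-is; no effective-length correction is attempted.

## TMM normalization

Between-sample scaling follows the trimmed mean of M-values exactly as in
edgeR's `calcNormFactors`: for sample *s* against a reference *r*, genes
with zero counts in either sample are dropped, per-gene log-ratios
`M = log2((c_s/N_s)/(c_r/N_r))` and abundances
`A = ½ log2((c_s/N_s)(c_r/N_r))` are double-trimmed (30% of each tail by
M, 5% by A, rank-based with average ties), and the factor is
`f_s = 2^(Σ w M / Σ w)` with inverse asymptotic binomial-variance weights
`w⁻¹ = (N_s−c_s)/(N_s c_s) + (N_r−c_r)/(N_r c_r)`. The reference sample
is the one whose 75th-percentile count-to-library ratio is closest to the
mean of those ratios; factors are re-centred to geometric mean 1, and a
sample whose log-ratios against the reference are all below 1e-6 in
magnitude gets factor 1. Agreement with edgeR on a 200-gene fixture is
~1e-10 (the package's own test asserts it).

Two numerical notes. First, multiplying a column by a constant leaves all
M values exactly invariant but not the weights (they depend on absolute
counts), so factors move slightly — at the third decimal for a 7.5×
rescale; the reference implementation behaves identically. Second, under
a strongly one-sided composition shift TMM undercorrects somewhat,
because trimming removes asymmetrically from the stable genes' M
distribution; this again matches the reference.

Normalized expression is counts per effectively-normalized million:
`x_gs = c_gs / (N_s f_s) × 1e6`.

## No-replicate differential expression probability

With one library per condition there is no empirical replicate noise, so
it is simulated:

1. **Replicates.** For each condition, `nss` technical replicates are
   drawn multinomially from the observed (rounded) counts, replicate *r*
   having size `round(N · pnr · (1+u_r))` with `u_r ~ U[−v, +v]`.
   Defaults `nss=5`, `pnr=0.2`, `v=0.02` follow the documented defaults
   of the established no-replicate simulation approach (NOISeq-sim);
   they are generic tool defaults, not values fitted to any particular
   dataset.
2. **Scale.** Replicates are put on the TMM-scaled per-million scale
   using the parent sample's TMM factor and each replicate's own total.
3. **Signal.** Per gene, `M = log2(x_A/x_B)` and `D = |x_A − x_B|`
   between the condition means of the simulated replicates (option
   `signal="observed"` uses the raw single libraries instead; the means
   stabilise the signal at the same effective depth). Zeros are replaced
   by the normalized equivalent of `k=0.5` counts before the ratio,
   never before the difference.
4. **Noise.** Every within-condition replicate pair contributes one
   `(|M*|, D*)` point per gene; both conditions are pooled into one
   cloud of `n_genes × 2·C(nss,2)` points (uniformly subsampled with the
   run's seed above `max_cloud=5e6` points).
5. **Probability.** `q = #{|M*| < |M| and D* < D} / #cloud` with strict
   inequalities — ties count against significance. A gene is *up* when
   `M ≥ lfc_threshold` and `q > q_threshold`, *down* symmetrically;
   defaults `lfc_threshold=1`, `q_threshold=0.9`.

Because D is measured on the per-million scale and the cloud pools all
genes, low-expression genes have small D relative to the cloud's upper
tail and effectively cannot exceed `q=0.9` whatever their fold change.
This produces the familiar wedge-shaped MD plot in which significant
genes concentrate at high D, and it is the dominant driver of the
benchmark misses discussed below.

Determinism: each sample's replicate stream is keyed by the sample's
column index under the top-level seed, so contrasting (A,B) versus (B,A)
reuses identical replicates — M flips sign, D and q are unchanged — and
identical seeds give byte-identical outputs end to end.

## Inheritance classification

Three contrasts are scored — hybrid vs parent1 (HvP1), hybrid vs parent2
(HvP2), parent1 vs parent2 (P1vP2) — and each expressed gene receives a
*set* of labels (the categories are not a partition):

* **conserved** — all three calls `non` (always a singleton label);
* **over_dominant** — `up` against both parents, or `up` against one
  with the hybrid at least `lfc` log2 units above both parents and no
  `down` call; **under_dominant** symmetric below;
* **additive** — parents differentially expressed, hybrid strictly
  between them on the normalized scale (ties fail) and differentially
  expressed against at least one parent;
* **dominant_P1** — parents differentially expressed, hybrid not
  distinguishable from parent1 (`non`) but distinguishable from parent2,
  and within `lfc` log2 units of parent1's level; **dominant_P2**
  symmetric;
* pattern (`non`, `non`, DE) — parents differ but the hybrid resolves
  against neither; assigned the nearest archetype among parent1's level,
  the parental log2 midpoint, and parent2's level.

A single `primary_label` is reported with precedence conserved >
over_dominant > under_dominant; a gene carrying both additive and a
parental-dominance label goes to the nearer archetype (midpoint vs the
matching parent, log2 scale, ties to additive). Genes matching no rule
are counted as `unclassified`, never dropped.

Why position enters at all: with a single library per condition the three
calls alone cannot separate the patterns. A truly parent-dominant gene's
hybrid sits *exactly on* the strict-intermediacy boundary, so sampling
noise pushes half of them into the additive region; a strongly
under-dominant gene at moderate expression loses one `down` call to the
D/q criterion yet matches the parental-dominance call pattern while
sitting far below both parents. Purely call-ordered rules therefore
misassign large fractions of dominant and under-dominant genes; the
position criteria restore the intended semantics ("similar level to one
parent", "intermediate", "beyond both parents") using the same normalized
values the calls are based on. Positions use a floor of 1e-3 per-million
before taking logs.

Summaries report counts and percentages per label (set membership) and
per primary label; integer percentages round half away from zero.

## Synthetic trio generator

The generator emulates the statistical structure of single-library
RSEM-style gene tables with planted truth. Per gene, a baseline
`b ~ N(base_mean_log2, base_sd_log2²)` on the log2 scale; non-conserved
genes get parents at `b ± parental_lfc/2` (the higher parent drawn
50/50), and the hybrid mean is placed by mode: equal to baseline
(conserved, additive — the geometric midpoint, chosen to make additivity
maximally distinct from dominance), equal to one parent (dominance), or
`dominance_delta` log2 units beyond the extreme parent (over/under).
Counts are negative binomial with mean `μ_gs · L_s / Σ_g μ_gs` and
variance `μ + φμ²`; `φ < 1e-8` falls back to Poisson. Lengths are uniform
integers in `gene_length_range`; ORF flags are Bernoulli
(`orf_fraction`).

Defaults define the reference scenario: 5,000 genes; proportions 0.70
conserved and 0.06 for each other mode; `parental_lfc=2`,
`dominance_delta=2` (log2 units); `φ=0.05` (typical technical plus low
biological overdispersion for a single library — the study's actual
dispersion is unknowable from single libraries, so this is an exposed
stand-in); three libraries of 5×10⁶; lengths U[500, 5000] bp;
`orf_fraction=1` so the expressed filter is exercised by TPM alone;
`base_mean_log2=5`, `base_sd_log2=2` — a realistic bulk dynamic range of
roughly four orders of magnitude in expression.

What the generator does **not** emulate: read-level artifacts (mapping
ambiguity, positional bias), isoforms and alternative splicing,
length–expression correlation, batch effects, biological replicate
variability, and assembly errors. Passing the recovery benchmark shows
the pipeline recovers planted inheritance structure under realistic count
noise and library-size imbalance; it does not certify performance on real
co-assembled transcriptomes.

## Recovery benchmark and its known misses

On the reference scenario (seed 1), primary-label accuracy is ~0.88, the
conserved share lands within a point or two of the planted 70%, and
per-mode recall by label-set membership is ≥0.70 for every mode
(conserved ~0.94, over-dominant ~0.97, under-dominant ~0.80, additive and
parental dominance ~0.70–0.75). Two structural effects bound the weaker
modes. First, the D/q dead zone: non-conserved genes in the lower
expression tail cannot reach `q > 0.9`, so ~20% of additive and dominant
genes are indistinguishable from conserved — a property of the
no-replicate probability itself, not of the classifier. Second, the
additive/dominance ambiguity: at `parental_lfc=2` an additive hybrid is
exactly 1 log2 unit (the DEG threshold) from each parent, so one of its
two hybrid calls is a coin flip and position must arbitrate; the
archetypes are 1 log2 unit apart while the position noise is ~0.4, giving
~10–15% assignment error each way. Recall is therefore reported both on
the primary label (matching the confusion matrix) and by label-set
membership, which credits a gene whose true mode survives in its label
set even when the primary went to the competing reading.

Problem sizes throughout (5,000-gene recovery, 2,000-gene null trios ×5
seeds, 200-gene normalization fixture) were chosen so every benchmark is
comfortably reproducible on a laptop in seconds while keeping Monte-Carlo
margins far from the asserted bounds.

## Null control

All-conserved trios (no true DE anywhere) give a false-positive DEG
fraction of ~0.03 in a hybrid–parent contrast (mean over 5 seeds,
bound ≤0.10 asserted in tests): with `φ=0.05`, a 2-fold apparent change
needs a ~2σ excursion of the between-library noise and must additionally
clear the q threshold.

## qPCR cross-check

`2^-ΔΔCt` relative quantification: technical replicates are averaged
within each biological replicate, ΔCt (target − endogenous control) is
formed per biological replicate, ΔΔCt references a required calibrator
sample, and fold change is `2^-ΔΔCt`. The averaging order (technical →
biological) is a documented choice; no amplification-efficiency
correction is applied. `compare_to_wts` reports sign agreement between
qPCR log2 fold changes and a sequencing contrast's M values — the level
of concordance (direction, not magnitude) qPCR validation of single-
library RNA-seq supports.

## Limitations

* Single library per condition is a hard design assumption; replicated
  designs need a different noise model and are out of scope.
* The DE probability is behaviourally, not numerically, equivalent to
  the established R implementation of the no-replicate procedure (no
  shared RNG), and inherits its low-expression insensitivity.
* The classifier's position criteria assume the TMM-normalized scale is
  comparable across the trio; strong unmodelled composition shifts would
  distort both the calls and the archetype distances.
* Integer percentages use half-away-from-zero rounding throughout; other
  conventions will differ by one unit on exact halves.
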