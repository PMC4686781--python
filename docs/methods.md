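# Methods

`reprogkit` scores how completely induced pluripotent stem (iPS) cell
lines have reprogrammed the transcriptome of the somatic cells they were
derived from.  The input is a gene × sample matrix of RNA-seq counts for
one embryonic fibroblast (EF) line, two embryonic stem (ES) reference
lines and one or more iPS lines, each with replicated libraries.  The
output is, per iPS line, a partition of the EF-vs-ES *signature genes*
into four categories — correctly reprogrammed, intermediate, not
reprogrammed (somatic memory) and novel — plus the genes sharing a
category across all iPS lines, and an exploratory clustering/PCA layer.

## Count model and differential expression

Counts are modelled as negative binomial: the count of gene *g* in
sample *j* has mean `mu_gj = s_j * q_g(line(j))` and variance
`mu + alpha_g * mu^2`, where `s_j` is a per-sample size factor, `q_g` a
normalized abundance shared by a line's replicates, and `alpha_g` the
gene's dispersion.

**Size factors** are median-of-ratios: `s_j` is the median over reference
genes (positive in every sample) of the ratio of the gene's count in
sample *j* to its across-sample geometric mean.  If no gene is positive
everywhere the code falls back to total-count ratios scaled to geometric
mean one, with a warning.  Proportional columns recover their
proportionality constants; identical columns give all ones.

**Dispersions** are method-of-moments estimates on normalized counts.
The sample variance is pooled *within* cell lines (residuals from each
line's own mean, `n_samples − n_lines` degrees of freedom), so genuine
between-line differences do not masquerade as noise, and
`alpha_raw = (s² − mean) / mean²`.  With three replicates per line this
estimate has very few degrees of freedom; genes whose variance is
underestimated by chance would receive wildly inflated test statistics.
The estimator therefore fits a mean–dispersion trend `a0 + a1/mean`
across genes by non-negative least squares and floors every per-gene
estimate at its trend value (the conservative maximum rule).  On
simulated null data (3 vs 3, dispersion 0.1) this brings the fraction of
raw p < 0.05 from ≈0.12 down to ≈0.04 at nominal 0.05 while keeping the
p-value distribution close to uniform; the price is mild conservatism.
Raw per-gene estimates are available with `stabilize=False`.  Estimates
are clipped to `[1e-8, 10]`; all-zero genes get the floor.  No
empirical-Bayes shrinkage is applied — every number is a closed form or
a one-dimensional fit, which keeps the estimator auditable.

**Wald tests.**  For a two-group contrast the common abundance `q` of
each group is fitted by maximum likelihood at the gene's fixed
dispersion, solving the score equation
`sum_j (k_j − s_j q) / (1 + alpha s_j q) = 0` with a vectorized
fixed-point iteration (`q ← Σ k_j w_j / Σ s_j w_j`, `w_j = 1/(1+alpha
s_j q)`); with equal size factors inside a group this is exactly the mean
of normalized counts.  The statistic is `log2(q_b/q_a)` divided by its
standard error from the Fisher information `I = Σ mu_j/(1+alpha mu_j)`
per group, referred to the standard normal, two-sided.  The Fisher
information here is the expected (GLM) curvature evaluated at the fit;
it coincides with the observed curvature in expectation and is positive
by construction.  A group with no counts at all is floored at half a
normalized count spread over the group's total sequencing depth
(`q = 0.5 / Σ s_j`) for both the fold change and the information, and
flagged `extreme`: a floor of essentially zero would make the
information vanish and a completely silenced gene would paradoxically
test non-significant.  Genes with no counts in either group are flagged
`untestable`, reported with p = 1 and log2FC = 0, and excluded from the
multiple-testing denominator.

**Multiple testing** is Benjamini–Hochberg step-up within each contrast,
implemented directly (`q_(i) = min_{j≥i} m p_(j)/j`, capped at 1) and
cross-checked in the tests against a brute-force restatement of the
definition and against `statsmodels.stats.multitest`.

## Signature selection and the four-way classification

Signature genes are the union of genes with BH-adjusted q below
`alpha_sig` (default 0.05, configurable) in either EF-vs-ES contrast —
"either" because a gene tracked by only one ES reference still marks the
somatic/pluripotent divide.  For each signature gene and iPS line the
decision tree runs in fixed order on the three iPS contrasts
(vs EF, vs ES1, vs ES2) and the size-factor-normalized means:

1. if the gene is **not** significant against both ES lines → *correct*
   (indistinguishable from the pluripotent reference);
2. else if not significant against EF → *not reprogrammed* (kept its
   fibroblast level: somatic memory);
3. else if the iPS mean lies strictly between the EF mean and the pooled
   ES mean → *intermediate* (incomplete promoter switching);
4. else → *novel* (a level outside the EF–ES interval: a reprogramming
   error rather than an incomplete one).

Because rule 1 fires first, the four categories partition the signature
set exactly, and per-line counts always sum to its size.  Design choices
made where the wording of the scheme leaves room:

* *correct* is operationalized as the logical complement of the
  "significantly different from both ES lines" condition, which is what
  makes the partition exact;
* the ES reference for between-ness is the unweighted mean of the two ES
  lines' normalized means, on the linear (not log) scale, and
  between-ness is strict — a tie with either boundary falls to *novel*;
* genes significant against only one ES line still use the pooled ES
  mean in rules 3–4 and are flagged `single_es_signature` in the output;
* no equivalence (TOST) machinery is used for "same level": absence of
  significance is the criterion, so *correct* at low power is a
  statement of non-detection, not proof of equality.

Shared-category counts intersect the per-line labels (same category in
*all* iPS lines).  Percentages are computed with half-up rounding at two
decimals (one-decimal mode for prose-style figures), which is the
convention the report table uses.

## Exploratory layer

Counts are transformed to `log2(count/s_j + 1)`.  The `k` most variable
genes (default 100, ties broken lexicographically) feed two views:
average-linkage agglomerative clustering on correlation distance
(1 − Pearson between sample profiles; scale-invariant, monotone merge
heights; zero-variance profiles get correlation 0 with a warning),
serialized as Newick; and gene-centered PCA of samples with per-component
variance fractions.  Heat-map exports are min–max scaled per gene to
[0, 1]; a constant row carries no contrast and maps to 0.5 by convention.
The transform is deliberately not a variance-stabilizing transform —
log2(normalized + 1) is simple, monotone and exactly testable.

## Synthetic experiments

The generator emulates the study design the pipeline expects: 5 lines
(EF, ES1, ES2, iPS1, iPS2) × 3 replicates = 15 samples, NB counts with
per-sample library factors drawn uniformly from [0.7, 1.4].  Defaults
(the "strong-signal" configuration): 6000 genes, 1500 signature genes,
baseline means log-normal with median 200 (natural-log sd 1.0),
signature |log2FC| = 4 with random sign, dispersion 0.05, category
proportions (0.80, 0.07, 0.07, 0.06) for correct / intermediate / not
reprogrammed / novel, seed 7.  Planted levels: *correct* at the ES mean,
*not reprogrammed* at the EF mean, *intermediate* at the geometric
midpoint, *novel* a factor 4 beyond the ES level, continuing the
direction of the EF→ES change (`novel_direction="overshoot"`;
`"random"` places it on a random side of the interval instead).
Overshoot models an excess of activation or repression during promoter
switching and keeps the fibroblast axis dominant in the sample geometry,
which is what replicated reprogramming experiments show.  Reprogramming
fates are largely locus-intrinsic — somatic-memory genes recur across
independently derived iPS lines — so a planted category is shared by all
iPS lines with probability `category_concordance` (default 0.8) and
drawn line-specifically otherwise.  The two ES lines are near-replicates
by default (`es_line_effect = 1`); setting it away from 1 exercises the
"significant vs either ES line" union logic.  One seed drives everything
through named child streams, so outputs are bit-reproducible.

What the generator does *not* emulate: assembly and alignment artifacts,
contig-level fragmentation (a contig→gene aggregation step exists but
truth is planted at gene level), gene–gene correlation, GC/length bias,
and dispersion heterogeneity across genes (a single dispersion is
planted).  Passing recovery tests therefore demonstrate correctness of
the statistical machinery under its own model assumptions, not
performance on real libraries.

## Known limitations and numerical notes

* With three replicates, planted effects at very low counts are
  undetectable: a novel gene overshooting on the silenced side of a
  16-fold signature sits at 1–7 counts and is necessarily called
  *correct* (rule 1).  At the default configuration this biases the
  recovered *correct* fraction up by about 3 percentage points; overall
  category recovery is ≈97%, and ≥99% for the correct class itself.
* The conservative dispersion floor trades a small amount of power for
  calibration; the observed type-I error at nominal 0.05 is ≈0.04.
* The size-factor fallback for matrices with no all-positive gene uses
  total counts and is composition-sensitive; it warns when used.
* Fold changes are not shrunk; extreme log2FC values for near-zero
  groups reflect the half-count floor and carry the `extreme` flag.
* Problem sizes in the test suite (up to 10 000 genes × 15 samples) were
  chosen so the full statistical behaviour — calibration bands, recovery
  rates, PCA geometry — is measurable in seconds per test; all such
  checks are seeded and deterministic.
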