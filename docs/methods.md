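# Methods

This note records the models and procedures implemented in `cperegnet`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical decisions taken where the design was open.

## 3' UTR motif scanning and architecture (`motifs`)

CPEB proteins recognize the cytoplasmic polyadenylation element (CPE) in 3'
UTRs. The scanner reports exact occurrences of four motif classes over the
RNA alphabet:

* canonical CPE: `UUUUA(1-2)U`, i.e. `UUUUAU` / `UUUUAAU` — bound by all
  four CPEBs;
* G-variant CPE: `UUUUGU`, extended to `UUUUGUA` when the next base is A —
  preferentially bound by the CPEB2–4 subfamily;
* canonical PAS hexamers `AAUAAA` / `AUUAAA`;
* ten non-canonical PAS hexamers from the standard vertebrate
  polyadenylation-signal catalogue (`UAUAAA`, `AGUAAA`, `AAGAAA`, `AAUAUA`,
  `AAUACA`, `CAUAAA`, `GAUAAA`, `AAUGAA`, `UUUAAA`, `ACUAAA`). The
  catalogue is fully configurable because non-canonical PAS usage varies by
  species and annotation.

Overlapping hits across classes are all reported. Within the canonical CPE
class, co-start matches collapse to the longest form so that `UUUUAAU` is
not double-counted as a nested `UUUUA·U` variant; distinct starts remain
distinct hits. Coordinates are 1-based inclusive internally; BED export is
0-based half-open.

A UTR is **predicted regulated** when it has at least one CPE of either
flavour and a PAS hexamer ending within `max_pas_to_end = 60` nt of the 3'
end. The 60-nt window is the relaxed PAS-distance rule; the classical
architecture rules use a tighter window, and the full feature vector
(counts, CPE–PAS distances, minimum PAS distance) is emitted so stricter
downstream rules can be applied without rescanning. CPE–PAS distances run
from the end of the CPE to the start of the PAS and are negative when the
CPE lies downstream.

The scanner is verified against a brute-force oracle that tests every
pattern at every start position on 1,000 random sequences of mixed base
composition (including U-rich, where spurious matches are densest).

## Differential k-mer enrichment (`kmers`)

De novo motif discovery with a PWM optimizer is deliberately replaced by
exhaustive exact k-mer testing: for each k in {8, 10, 12} every observed
k-mer is scored by a one-sided hypergeometric test on the number of
foreground sequences *containing* it versus background, with
Benjamini–Hochberg adjustment within each k (tests at different k are
nested, so each length is treated as its own family). Presence rather than
occurrence counts avoids confounding by sequence length. This is a semantic
departure from degenerate-motif optimization, chosen because it is
deterministic and oracle-checkable while still ranking the planted/true
consensus (e.g. 8-mers containing `UUUUAAU` or `UUUUGUA`) first.

Exact tests have discrete, super-uniform p-values: for a k-mer present in
only one or two sequences the attainable p-values are a handful of points
(e.g. {0.5, 1}), so the p-value distribution under a permuted-label null is
*not* close to U(0,1) no matter how correct the test is. A `midp` option
(half weight on the observed table) is provided; restricted to k-mers
present in ≥ 25 sequences, mid-p values are near-uniform under the null
(KS distance < 0.05 over > 10,000 tests in the acceptance suite). The
conservative tail probability remains the default for inference.

## RIP-Seq enrichment and target calling (`rip`)

Gene-level counts from CPEB IPs, a not-injected (NI) control IP, and input
libraries are modelled as negative binomial. The test is self-contained
rather than a wrapper around an existing count-model package — exact
numerical agreement with any particular tool is a non-goal; the contracts
(calibrated type-I error, shrinkage behaviour, threshold semantics) are
what the tests pin down:

1. **Size factors** — median-of-ratios against the geometric-mean reference
   gene profile.
2. **Dispersion** — per-gene method-of-moments estimate
   `alpha = (var − mu)/mu²` pooled across the two groups of the contrast,
   shrunk 50/50 on the log scale toward a log-linear mean–dispersion trend
   fitted across genes. The raw estimate is floored at one tenth of the
   trend so a by-chance underdispersed gene cannot drive its Wald SE to
   zero (the dominant source of anticonservative calls at n = 6).
3. **Wald test** — on the log2 fold change of normalized group means (a
   pseudocount of 0.5 keeps estimates finite at zero counts), with standard
   error `sqrt((1/mu_A + alpha)/n_A + (1/mu_B + alpha)/n_B)/ln 2` from the
   NB variance function, referred to a t distribution with `n_A + n_B − 2`
   df. The t reference (rather than normal) compensates for estimating the
   dispersion; simulated type-I error at p < 0.05 is 0.04 at the default
   study conditions.
4. **Filtering** — genes with total contrast count < 10 are excluded before
   testing (logged); dispersion estimation is unstable below that.
5. **LFC shrinkage** — normal-prior posterior mode,
   `shrunk = lfc · prior_var/(prior_var + se²)`. The prior variance is the
   observed lfc variance of the high-count half of tested genes minus their
   mean sampling variance, floored at 0.25²; low-information genes shrink
   most, sign is preserved.

**Targets** are genes at least `fc_input = 4`-fold enriched over input and
`fc_ni = 2`-fold over the NI IP on the shrunk lfc, both at BH-adjusted
p ≤ 0.05. **Preferential targets**: a target-union gene is
CPEB1-preferential when shrunk log2FC > 2 at padj < 0.05 in CPEB1 versus
*any* of CPEB2/3/4, CPEB2–4-preferential by the reciprocal, otherwise
shared. Both a twofold and a fourfold (shrunk log2FC > 2) cutoff are
defensible for this contrast; log2FC > 2 is the default and the threshold
is exposed (`--pref-lfc`). A gene qualifying
in both directions under the disjunction is assigned by the larger
absolute shrunk fold change and logged.

The combined enrichment score for the heatmap is the Euclidean norm
(modulus) of the two mean-centered shrunk log2 fold changes; centering is
per contrast by default (the centering constant is a genuine design choice;
per-gene centering is available). Clustering is
agglomerative with complete (full) linkage on Euclidean distances, checked
against an O(n³) oracle, with Newick export.

## BioID proximome calling (`bioid`)

Intensities are log10(iBAQ); missingness is missing-not-at-random (low
abundance drops out), which motivates both the restricted imputation and
the rescue route.

* **Percentile normalization**: each sample's present values are mapped,
  by their within-sample percentile rank, onto the mean of the per-sample
  quantile functions. Rank-equivalent samples become identical columns;
  missing cells stay missing.
* **kNN imputation** (k = 10): only proteins with one or two missing values
  are imputed; each hole takes the column mean of the k nearest rows by
  NaN-aware Euclidean distance (squared distance rescaled by the fraction
  of co-present columns). Rows with ≥ 3 missing values are untouched —
  under MNAR, imputing heavily censored rows would fabricate signal.
  Written in-house because library imputers impute every row.
* **Tested route**: proteins with ≤ 2 missing per condition before
  imputation get a per-protein linear model (condition effect, optional
  replicate covariate) with empirical-Bayes variance moderation: a scaled
  inverse-chi-square prior fitted by moment matching on log variances
  (trigamma inversion by Newton's method) of proteins with the modal
  residual df, then per-protein posterior variances and moderated t with
  `d0 + df` degrees of freedom. Hit: positive fold change and BH-adjusted
  p < 0.05.
* **Rescued route** (raw missingness, never imputed): ≥ n−1 of n control
  replicates missing, ≤ 1 condition replicate missing, and mean detected
  condition intensity above the 25th percentile of all detected values
  pooled across the condition samples (per-sample flooring is available;
  pooled is the default as the floor is a property of the acquisition, not
  of one injection). The two routes are mutually exclusive by
  construction. The original rescue decision was manual; this codifies the
  stated criteria, so any unstated case-by-case judgment is not reproduced.
* **Rank comparison** between two states uses dense ranks (ties share a
  rank) of the enrichment scores, absent proteins ranked last+1.

## Phospho-site occupancy (`phospho`)

Per site and condition, `r = N_phos/(N_phos + N_nonphos)` from PSM counts
pooled across the three search engines (summed by default; deduplication by
spectrum id is available because engines may rescore the same spectra).
Phospho PSMs with localization probability ≤ 0.75 are excluded from
`N_phos` and, being ambiguous rather than negative evidence, from the
denominator as well. The "ratio error" is the binomial standard error
`sqrt(r(1−r)/N)`, the natural error for a proportion of PSMs (a bootstrap
over PSMs is available as an alternative). Gains are
sites with strictly larger occupancy after progesterone, errors propagated
in quadrature; ratios are computed on the pooled replicates (per-replicate
ratios with averaging exist but are non-default, matching the pooled
design). Proline-directed sites are S/T followed immediately by P.

## FRAP kinetics (`frap`)

Three-ROI traces (bleach spot, whole cell, background; 50 pre-bleach + 300
post-bleach frames at ~11 Hz in the reference design) are normalized by the
full-scale double-normalization convention: background subtraction,
division of the bleach signal by the whole-cell signal (cancels
acquisition bleaching exactly, as the invariance tests verify), pre-bleach
mean anchored at 1 and the first post-bleach frame at 0. The first 20
frames are discarded before computing pre-bleach statistics (applied to
the pre-bleach window only, the conservative reading of the discard
convention).

Recovery is fitted by least squares as a single exponential
`f(t) = c + a(1 − e^{−kt})` with `t_half = ln2/k` and mobile fraction
= fitted plateau `c + a`, clipped to [0, 1.05] with a flag. The free
offset `c` exists because full-scale normalization pins the curve to a
*single* noisy frame: Monte-Carlo shows that with a through-origin fit the
anchor-frame noise alone degrades t_half recovery from ~99% to ~55% (at
per-frame noise 0.05), while the offset absorbs it; in noiseless data
`c = 0` exactly and the fit reduces to the through-origin form. A flat
curve (plateau < 10⁻³) is flagged unconverged with mobile ≈ 0 — the rate is
unidentifiable there.

Group comparison: Kruskal–Wallis omnibus plus Dunn's pairwise z tests with
tie correction. Both Holm and Bonferroni corrections are common for Dunn's
test; Holm (uniformly more powerful) is the default, Bonferroni a flag.
Groups with fewer than 3 values are excluded with a warning.

## Synthetic data (`simulate`)

All generators are pure functions of (parameters, seed) and return truth
tables sufficient to score every caller.

* **UTR sets**: lengths log-normal parameterized by median (targets
  1489 nt, non-targets 531 nt, σ_log = 0.6 — only medians are known, so the
  spread is a modelling choice); background uniform over ACGU with an
  optional U-rich mode (U fraction 0.35) to stress the scanner, since real
  3' UTRs are U-rich. Motifs are planted at uniform non-overlapping
  positions (PAS always ending within the 60-nt window; error after 100
  collision retries). Not emulated: dinucleotide structure, conservation,
  real PAS/CPE positional biases.
* **RIP-Seq**: negative-binomial counts with mean
  `baseline × lib_size × 2^lfc(condition)`; defaults 2,000 genes, 150
  targets at 8× over input and 4× over the NI IP, dispersion 0.05, 6
  replicates, log-normal baselines (median 200). A three-class builder
  plants CPEB1-preferential / CPEB2–4-preferential / shared targets for the
  preferential-calling tests. Not emulated: batch effects beyond scalar
  library size, GC/length biases, multimapping.
* **BioID**: Gaussian log10 intensities (noise sd 0.25), logistic MNAR
  dropout `P(missing|x) = expit((midpoint − x)/scale)` with midpoint 6.0
  and scale 0.3 — the standard censoring model for label-free MS and the
  mechanism the rescue rule exists for. Defaults: 1,000 proteins, 30 hits
  — 18 at detectable abundance with a +1.0 log10 shift (tested route) and
  12 at base 5.4 with +2.0 (control drops out; rescued route).
* **PSM tables**: `N_phos ~ Binomial(depth, occupancy)` per site and
  condition, one row per PSM, localization probabilities Beta(20, 1) so
  that ~0.3% of true phospho PSMs fall below the 0.75 filter (a harsher
  Beta would bias occupancy estimates by construction), engines assigned
  uniformly.
* **FRAP**: post-bleach bleach-ROI signal
  `depth + (1 − depth)·mobile·(1 − e^{−kt})` times an exponential
  acquisition-bleaching envelope shared with the whole-cell ROI, plus
  Gaussian noise scaled to each ROI's intensity; by construction the
  noiseless normalize∘fit round trip recovers k to machine precision.

Because the generators draw i.i.d. noise with known parametric forms,
passing recovery tests demonstrates correctness of the estimators and
thresholds under the assumed models — not robustness to the correlated
noise, contamination and annotation error of real datasets.

## Problem sizes and determinism

The acceptance script and test suite use the generator defaults above
(2,000 genes / 1,000 proteins / 100–200 Monte-Carlo replicates / 1,000
oracle sequences), sizes at which every stochastic check is stable across
seeds while the whole suite runs in about a minute. Every stochastic stage
takes an explicit seed (package default 1729); `scripts/acceptance.py`
derives per-stage sub-seeds from its `--seed` via `SeedSequence`.

## Known limitations

* The NB Wald test is calibrated for ≥ 3 replicates per side; at n = 2 the
  dispersion trend dominates and p-values become conservative.
* The k-mer → consensus collapse step (reported consensus strings are
  shorter than the tested k-mers) is intentionally left to the user; the
  output is the enriched k-mer table.
* The rescue rule codifies stated criteria for a decision that was
  originally manual.
* The exact decision table of the classical CPE-architecture script is not
  reproduced; the minimal rule (≥ 1 CPE plus PAS within 60 nt) plus the
  emitted feature vector stand in for it.
* `compare_oligos` is a plain Hamming comparison; it does not attempt
  alignment, so it reports all three positions at which the reference CPE-A /
  CPE-G oligos differ (17–19), of which position 17 is the A→G substitution.
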