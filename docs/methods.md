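# Methods

## Genotype encoding and statistics

Each biallelic SNP is encoded per sample as 1 (homozygous reference), 2
(heterozygous), 3 (homozygous alternate); missing calls are imputed with the
per-SNP mode over all non-missing samples, classes pooled, ties broken toward
the smaller code (the simplest deterministic rule; a SNP missing everywhere is
dropped with a warning). Under this encoding the class means of the codes lie
in [1, 3], so the log₂ fold change between case and control means is bounded
by ±log₂ 3 ≈ 1.585, attained exactly by a perfect separator (all cases 3, all
controls 1); at two printed decimals this bound renders as 1.59 under the
successive half-up rounding convention used for reported values
(`printed_round`: 1.58496 → 1.585 → 1.59).

The mapping hom-ref→1 / het→2 / hom-alt→3 is a convention: any permutation of
the three codes changes fold-change values. Fisher's ratio
FR = (μ₁−μ₂)²/(σ₁²+σ₂²) is invariant under affine recodings but not under
arbitrary permutations either; both facts are covered by tests. Class
variances use the unbiased n−1 estimator, which requires at least two samples
per class. When both class variances are zero and the means differ, FR is
reported as an explicit infinite-separation sentinel (`inf`) that ranks above
every finite value — perfect separators are reported honestly rather than
regularized with an epsilon.

## The two-stage filter

Stage one keeps SNPs in the extreme tails of the panel's empirical
fold-change distribution; the default `tail_fraction = 0.01` splits 1% of
total mass over the two tails (0.5% per tail), reflecting that signal can be
enriched in either class. Stage two requires FR strictly above `fr_min`
(default 1.5). Survivors are ranked by decreasing FR, ties broken by
decreasing |fold change| then lexicographic SNP id, so ranking is total and
deterministic. Both thresholds are configuration, not constants: for cohorts
of this size (n₁ = 120, n₂ = 40) the null FR has expectation
≈ (1/n₁ + 1/n₂)/2 ≈ 0.017, while a planted allele-frequency shift of δ in
cases gives mean separation 2δ and FR ≈ (2δ)²/(σ₁²+σ₂²) — about 0.4–0.65 at
δ = 0.30 — so an FR floor of 1.5 is only appropriate for much stronger
per-SNP effects, and the planted-signal experiments in this repository use
`tail_fraction = 0.02` (1% per tail) and `fr_min = 0.15`, values fixed from
these closed-form scales. No multiple-testing correction is applied: the
procedure is ranking/threshold-based, not p-value-based.

## Classifier and signature search

The LOOCV classifier is nearest centroid on the Euclidean distance over the
active SNP subset: deterministic, hyperparameter-free, and aligned with what
FR selects for (well-separated, within-class-homogeneous features). Exact
distance ties go to the majority training class, majority ties to the case
class; an odd-k k-NN vote is available as an alternative, with neighbour
ties broken by training-sample order. The nearest-centroid LOOCV uses a
closed-form fast path (leaving a sample out only shifts its own class's
centroid), verified against a literal hold-one-out loop in the tests.

The signature search scans rank prefixes top-1 … top-k_max (default k_max =
min(#survivors, 400)) rather than all 2^K subsets; this is exactly the
recursive elimination of the weakest-ranked SNP, and the tests confirm the
forward scan and literal backward elimination produce identical accuracy
curves. The returned signature is the smallest prefix attaining the maximum
LOOCV accuracy. Accuracy is the unweighted proportion correct; because the
cohorts are unbalanced, the per-class rates (TPR for cases, TNR for
controls) are always reported alongside.

## Hold-out stability

Stability of a discovered signature is measured by repeated random 75/25
train/validation splits (default 5000) with the signature held fixed and only
the classifier retrained; re-deriving the signature inside each training
partition is a different (nested) experiment exposed via `rederive`. Splits
are stratified per class — with ~24% controls, unstratified 25% validation
sets would occasionally contain no controls and leave TNR undefined — with
the training share per class rounded to the nearest integer and clamped so
both partitions retain both classes. Quantiles use linear interpolation and
the SD is the n−1 estimator, so summaries are exactly reproducible; the whole
sampler is a pure function of its seed.

## Network sampling and correlation tree

Equivalent-network sampling draws fixed-size SNP subsets without replacement,
drawing items one at a time with probability proportional to FR among those
not yet drawn (successive sampling); sentinel-FR SNPs get weight 10× the
largest finite FR, and zero-FR SNPs get a vanishing but nonzero weight so the
pool stays reachable. Each network is scored by LOOCV accuracy; networks
within `threshold_offset` (default 0.02) of the best sampled accuracy are
retained and each SNP's posterior sampling frequency is its share of the
retained networks. The correlation tree is the maximum spanning tree of the
complete graph on the signature SNPs with edge weight |Pearson r| of the code
vectors (the signed r is reported on each edge): strongest dependence of
either sign is what matters, and the tree is built by Kruskal's algorithm
with deterministic lexicographic tie-breaks. A minimum-tree variant is
exposed because both conventions appear in the applied literature. Tree
optimality is verified exhaustively for up to 7 nodes and against networkx.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes and
nothing more: two phenotype arms (defaults 123 cases / 39 controls, the
unbalanced shape typical of toxicity cohorts), null SNPs sampled under
Hardy–Weinberg proportions at a minor-allele frequency drawn uniformly from
(0.05, 0.5), and planted causal SNPs whose alternate-allele frequency is
shifted upward by `effect_delta` in cases only (capped at 0.95 so planted
columns stay polymorphic). Missing calls are introduced before imputation so
that path is exercised end to end. The generator deliberately omits linkage
disequilibrium, population structure and clinical covariates; passing tests
therefore demonstrate correctness of the algorithmic chain under an
idealized independence model, not performance on real genotypes, where LD
and stratification can inflate or dilute every statistic here.

## Problem sizes and null calibration

The repository's planted-signal experiment uses 120 cases / 40 controls ×
10,000 SNPs with 70 causal SNPs at δ = 0.30 — large enough that the filter's
tail quantiles and FR ranking operate in their intended regime, small enough
to run in seconds. Its two frozen checkpoints (≥ 80% of planted SNPs among
the top 100 ranks; signature LOOCV accuracy ≥ 0.85) were set from the
closed-form calculations above.

Because the filter sees the full data before LOOCV, the discovered
signature's LOOCV accuracy is optimistically biased — under a pure-null
cohort (δ = 0) of the same dimensions the discovery chain still reaches
accuracies far above the 0.75 majority rate. A 100-replicate Monte-Carlo of
the null chain gives mean 0.937, SD 0.024 and a 95% band of [0.8875, 0.9750],
which the null-calibration test checks against a fresh replicate. This
selection bias is inherent to filtering outside the cross-validation loop;
the repeated hold-out experiment (which retrains the classifier, but keeps
the selected signature) inherits it too, and is the main caveat when reading
absolute accuracies from this procedure. Unbiased error estimation would
require nesting the filter inside each fold (`rederive` in the hold-out
sampler is a step in that direction).

## Known limitations

* Only biallelic SNPs; multi-allelic and structural variants are rejected.
* No covariate adjustment, LD modelling, or strand normalization.
* The fold-change bound and code conventions are tied to the 1/2/3 encoding.
* Accuracy estimates are optimistic under in-sample feature selection (see
  above); treat them as internal consistency measures, not generalization
  estimates.
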