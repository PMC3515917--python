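# Methods

This note documents the statistical models behind `naevus-omics`, the
parameter defaults and why they were chosen, what the synthetic data does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## The paired design

Every analysis assumes the paired structure: each patient contributes one
lesional (DNMC) and one normal (MC) melanocyte culture. Patient-level
variation is large relative to the lesion effect — autologous samples
resemble each other more than they resemble other patients' samples — so all
condition comparisons are within-patient: paired log2 differences for
expression, within-gel-set log volume ratios for DIGE, within-patient ΔΔCt
for qPCR. Permutation nulls respect the pairing by flipping whole patients
(or gel sets), never individual genes or spots, which preserves the
correlation structure across features and is what makes the multivariate
procedures valid.

## Random variance model (RVM)

With n = 18 pairs, per-gene variance estimates on n−1 = 17 degrees of freedom
are unstable. The RVM assumes gene precisions τ_g = 1/σ_g² are i.i.d.
Gamma(a, scale b). Marginally the sample variance then satisfies
s²·a·b ~ F(n−1, 2a), giving a likelihood for (a, b) over all genes jointly.

* **Fitting.** The F log-density is evaluated in closed form (via `betaln`)
  and the negative log-likelihood is minimised over (log a, log b) with
  Nelder–Mead from five starts (a ∈ {0.5, 1, 2, 3, 10} with moment-matched
  b). The shape is capped at a_max = 10³: the cap is only reached when the
  variances are (near-)identical, where the likelihood is unbounded in a; a
  warning is raised. Genes with s² = 0 are excluded from the fit (they make
  the F density degenerate) but are still tested — their moderated variance
  is driven by the prior term 2/b.
* **Testing.** s̃² = ((n−1)s² + 2/b)/(n−1+2a) is a convex combination of s²
  and the prior mean variance 1/(ab) with weights (n−1)/(n−1+2a) and
  2a/(n−1+2a); t = d̄/√(s̃²/n) is referred to a t distribution with
  n−1+2a degrees of freedom, two-sided. As a→0 the ordinary paired t-test is
  recovered; as a→∞ all genes share the prior variance.
* **Scale note.** When fitted on variances of *paired differences*, the
  fitted b is half the per-sample generating value, because a difference
  carries two independent noise draws. This is self-consistent: prior, test
  and permutations all operate on the difference scale.

## Multivariate permutation selection

To control false discoveries over the gene list, each permutation flips the
sign of whole patient difference vectors (exhaustive over all 2^n flips when
2^n ≤ n_perm, sampled otherwise), RVM p-values are recomputed, and the
(u+1)-th smallest p-value is recorded. Genes with observed p below the
α-quantile of that permutation distribution are selected; with confidence
1−α at most u of them are false discoveries. The quantile is the ⌊αB⌋-th
smallest permutation value (selecting nothing when ⌊αB⌋ = 0), which is the
conservative choice. The prior (a, b) is fitted once on the observed data
and held fixed across permutations; refitting per permutation would multiply
the cost by n_perm without changing the validity of the permutation null.
Defaults u = 0, α = 0.05, n_perm = 10,000 are the package's own choices for
a stringent screen.

## Functional class scoring

Per class, LS = mean(−ln p) over member genes (p clamped at 1e−300 before
the log) and KS = max_i max(i/n − p_(i), p_(i) − (i−1)/n), the two-sided
one-sample Kolmogorov–Smirnov distance to U(0,1). The per-gene p-values are
the RVM paired-test p-values (ordinary paired t available via the API).

The null is **gene-sampling**: random same-size subsets of the measured
universe. This matches a per-class p-value that is comparable across classes
of very different sizes; a sample-relabelling null is intentionally not the
default. Sampled p-values use the add-one estimator (k+1)/(n_perm+1) with
ties counting as ≥ (conservative); exhaustive enumeration over C(N, k)
subsets is available below a configurable limit (default 10⁶) and returns
the exact fraction. Within `score_all_classes` all classes of one size share
one seeded null stream per statistic, so cost scales with the number of
distinct sizes, not the number of classes. Classes are reported sorted by
LS permutation p (ties broken by the LS statistic, largest first) and
flagged significant at the nominal 0.005 level on either statistic; no
cross-class multiplicity adjustment is applied, by design. Class-size
bounds are 5–100 genes *present in the expression data*.

Both GO annotation modes are supported: with an OBO ontology, genes can be
propagated to all is_a ancestors (default on — the conventional reading of
GO membership) or left as direct annotations only.

## Clustering reproducibility

Samples are clustered on Euclidean distance with complete linkage (merge
heights are monotone; ties resolved by lowest observation index). For the
R/D indices, each of n_perturb = 100 perturbations adds i.i.d.
N(0, noise_sd²) to every matrix entry and re-clusters; both trees are cut to
k clusters ("cut the n−k lowest merges"). R is the mean over original
clusters (and perturbations) of the proportion of within-cluster pairs still
co-clustered — defined as 1 when the cut yields only singletons. D is the
mean over perturbations of Σ_clusters (omitted + added vs. the
best-overlapping perturbed cluster, ties to the smaller index) / k. Zero
noise gives R = 1 and D = 0 exactly. The default noise scale is the median
over genes of the within-pair difference SD — a data-driven estimate of the
measurement noise floor, used because no external noise estimate is
available at run time.

## 2D-DIGE analysis

Volumes are normalized within each gel channel by the channel's total spot
volume (removing loading/label differences; each channel then sums to 1) and
across gels by one median-scaling factor **per gel set** (channels pooled).
A single per-gel factor was chosen deliberately: it preserves every
within-gel DNMC/MC ratio exactly, whereas per-channel factors would distort
the quantity being tested. Spots present (both channels) in fewer than 15 of
18 gel sets are excluded.

Per spot, the Welch unequal-variance t-test compares log-transformed
normalized volumes between conditions (volume data is multiplicative;
ratios are reported as geometric means on the natural scale). The
Westfall–Young step-down maxT adjustment uses one-sample t statistics of the
per-gel-set log ratios under whole-gel-set sign flips, all spots jointly,
with successive tail maxima and enforced monotonicity; it is exhaustive over
2^G flips when feasible. maxT controls **family-wise error**, the strict
criterion; the headline protein filter (p < 0.03, ratio ≥ 2 or ≤ 0.5,
present in ≥ 15 gel sets) is driven by the *raw* Welch p, with the adjusted
p reported alongside. The unpaired Welch default reflects the "Welch-
modified" test naming; a paired alternative is the maxT statistic itself.

Total-volume normalization assumes most spots are unchanged: when a large
fraction of spots is differential in one direction, channel totals absorb
part of the effect and attenuate all ratios. The synthetic defaults
therefore plant a small fraction of differential spots (16 of 200), the
realistic regime.

Note also that for a spot whose true fold change is exactly 2, the observed
geometric-mean ratio exceeds 2 only about half the time under symmetric
noise, so the full headline filter's recovery of exactly-2-fold spots is
bounded near 50% by construction; detection power is therefore quoted at the
p < 0.03 + presence criterion, and the full-filter pass rate is reported
separately by the acceptance script.

## qPCR ΔΔCt

Replicates are averaged first; ΔCt = Ct(target) − Ct(reference) per
condition, ΔΔCt = ΔCt(DNMC) − ΔCt(MC), ratio = E^(−ΔΔCt) with amplification
efficiency E = 2 by default (exposed for sensitivity analysis). The
reference gene cancels any condition-level additive Ct shift; swapping
conditions inverts the ratio.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical assumptions* of the methods:
gene variances drawn from the inverse-gamma prior (so prior fitting is a
genuine recovery problem and s²·a·(b/2) of null paired differences is
F(n−1, 2a)-distributed); an additive patient effect (default SD 0.5 log2
units, per gene and patient, shared by both members of a pair) strong enough
that autologous samples co-cluster and paired analysis visibly beats
unpaired; signed condition effects, half up and half down; log-normal spot
volumes with per-gel-channel scale factors that the normalization must
remove; Bernoulli spot missingness; dye-swap flags with an optional dye bias
(default 0, i.e. no label effect); and Ct tables with a condition-stable
reference gene and duplicate wells.

They do **not** emulate probe-level microarray artefacts, correlated gene
blocks beyond the planted sets, intensity-dependent variance trends,
non-random (abundance-dependent) spot missingness, or qPCR efficiency
drift. Passing tests therefore demonstrate correctness and calibration of
the statistical machinery under the stated model, not robustness to every
artefact of real array or gel data.

Default simulation conditions mirror the study design: 18 patient pairs,
5000 genes (desk-scale stand-in for a genome-wide array), 10% affected genes
at ±1 log2 unit, 50 gene sets of 5–100 genes with 3 enriched sets at 80%
affected members.

## Problem sizes in tests and the acceptance script

Calibration and power checks use deliberately compact problem sizes chosen
as the smallest that leave Monte-Carlo error well inside the asserted
margins: null-uniformity checks use 100 data sets of 300 genes (gene level)
and 1000 genes / 40 classes with 800 class permutations (class level);
selection type-I error uses 500 replicates of 50 genes × 8 pairs with
exhaustive 2⁸ sign flips; family-wise error uses 500 replicates of 50 spots
× 18 gel sets with 256 sampled flips; gene-set recovery uses 50 data sets of
800 genes / 53 classes; spot power uses 10 tables of 200 spots. The
acceptance script reuses these conditions at somewhat smaller replicate
counts and prints each measured rate with its replicate count `n`.

## Known limitations

* The RVM fit assumes a single shared (a, b) across all genes; variance
  heterogeneity beyond the inverse-gamma family (e.g. intensity-dependent
  trends) is not modelled.
* The gene-sampling class null treats genes as exchangeable units;
  inter-gene correlation within a class makes nominal class p-values
  anti-conservative on strongly correlated real data. The sign-flip
  (sample-permutation) route in `paired_diffexpr` is the remedy when that
  matters.
* Class p-values carry permutation granularity 1/(n_perm+1); ranking among
  classes at the floor is resolved by the observed statistic.
* The across-gel median scaling is one reasonable choice among several; any
  monotone per-gel-set scaling leaves all reported ratios and tests
  unchanged, so the choice affects only exported normalized volumes.
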