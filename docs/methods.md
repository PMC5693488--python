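# Methods

`panelcheck` implements, on fully synthetic data, the analytical-verification
battery that a locked gene-expression panel classifier — one that calls usual
interstitial pneumonia (UIP) versus non-UIP from transbronchial-biopsy (TBB)
RNA-seq counts — is put through before clinical use. The clinical cohort, the
locked production classifier and the identities of its 190 panel genes are
proprietary; this package therefore provides the *framework*: a generative
model with the same statistical anatomy, a surrogate locked classifier, and
the estimators (limits of detection, interference tests, variance
components) that make up the battery. What the framework can and cannot say
about the production assay is discussed at the end.

## Synthetic data model

**Panel.** `make_panel` builds a panel of `n_genes` (default 190) synthetic
gene ids with lognormal exonic lengths (median ~1.5 kb, clipped at 200 b) and
designates one gene as the blood marker, playing the role of hemoglobin beta
(HBB). Exonic lengths matter only for the genomic-DNA background, whose reads
are allocated proportional to exonic length (an exon-capture assay retains
exonic gDNA fragments).

**Tissue profiles.** Each tissue or contaminant role is a point on the
(`n_genes`−1)-simplex plus a negative-binomial dispersion. UIP and non-UIP
TBB profiles share a common lognormal lung baseline (ln-scale SD 1.5 across
genes) and differ on exactly `n_discriminating` genes (default 20) by
`log2_fold_change` (default 1.5, half up and half down in UIP) — a deliberate
caricature of a trained signature: strong enough that the surrogate
classifier separates classes cleanly, as the locked production classifier
does on its training cohort. Surgical-lung-biopsy (SLB) and adjacent-normal
profiles are jittered copies (ln-scale SD 0.2) of the corresponding TBB
baselines; the blood profile holds the marker gene at exactly
`blood_marker_fraction` with an otherwise lung-like, non-UIP background. The
TBB baseline pins the marker at `tbb_marker_fraction` = 0.003.

The default pure-blood marker fraction 0.3075 is not arbitrary: with a 0.3%
tissue baseline, linear mixing reaches a 7% marker share at 22% blood only if
the pure-blood marker share is (0.07 − 0.78·0.003)/0.22 = 0.3075. The
framework adopts that implied value so that the generator, the mixture
arithmetic and the marker-based contamination readout are mutually
consistent.

**Counts.** A library is drawn in two stages: the total read count is
negative-binomial — expected depth (default 10⁶) times a gamma factor with
dispersion α (default 0.05) — and the per-gene split is multinomial in the
profile's abundances. Every gene's marginal variance is therefore
μ + αμ², while gene *proportions* carry only multinomial noise. This
library-level realization of the overdispersion was chosen deliberately: it
keeps compositional readouts (the blood-marker share, mixture proportions)
stable across technical replicates, which is the regime of a capture assay
re-sequencing the same pooled RNA. What it does **not** model is independent
gene-level biological noise between samples of the same tissue; profile
jitter stands in for that at the tissue level. Consequently, replicate-level
score noise is injected explicitly (below) rather than emerging from
per-gene dispersion.

**Input mass.** The assay's nominal input is 15 ng of total RNA. Input mass
enters as effective-depth scaling, `depth · (mass/15)^1`, plus a lognormal
depth jitter whose SD grows at low mass (`0.05 · (15/mass)^0.5`): the paper
trail for low-input behavior is an outcome (more score variation at 5 ng, no
mean shift), not a mechanism, so the simplest depth-mediated mechanism is
used. Depth scaling and jitter cancel in proportions; their effect on scores
is through read-sampling noise, which is the intended behavior.

**Run/lab/replicate effects.** Reproducibility studies report technical
effects as score SDs, so the generator injects them on the score scale:
effects are drawn Normal with SDs `run_effect_sd` (default 0.087, i.e.
variance 0.0076), `lab_effect_sd` (0.11) and `replicate_sd` (0.18), and
realized in the counts by a tilt along the classifier weight vector on the
VST scale — the unique direction that shifts the score by exactly the drawn
amount while perturbing the library as little as possible. A truth record of
every injected effect accompanies each simulated study.

## Preprocessing

Counts are normalized by median-of-ratios size factors (the DESeq estimator:
per-sample median of count-to-geometric-mean ratios over genes positive in
all samples, rescaled to geometric mean 1) and transformed with the
closed-form variance-stabilizing transform for the NB mean–variance relation
var = μ + αμ²:

    vst(q) = (2/√α) · asinh(√(αq))   (α > 0),    2√q   (α = 0).

A single pooled method-of-moments dispersion replaces a fitted per-gene
trend. The transform is treated as a fixed input contract of the classifier,
not as an inference step; the closed form is the exact stabilizing integral
for that variance function and is strictly increasing in q for every α ≥ 0.

## Surrogate locked classifier

The production algorithm is undisclosed; the surrogate is L2-penalized
logistic regression on the VST features. An affine decision function
reproduces every property the battery measures — score SDs transfer through
it unchanged, mixtures move monotonically between the parents' scores, and
boundary crossings are well defined. Scores are calibrated so that the
1st–99th percentile range of training scores spans 7 display units with the
logistic decision threshold at 0; UIP is the positive direction, and a score
exactly on the boundary calls non-UIP (the assay is designed to resist false
positives, so ties go to the negative class).

Lockedness is structural: the trained model is a frozen value object, and
scoring is a pure function of (model, sample). To make single-sample scoring
well defined, the model freezes a normalization reference at training time
(per-gene log geometric means of normalized training counts over genes
positive in all training samples) and new libraries get median-of-ratios
size factors against that reference. `estimate_size_factors` itself remains
a per-batch estimator for cohort-level use.

## In silico mixtures and limits of detection

A mixture of a parent and a diluent at diluent mass fraction f is formed at
the composition level, `p_mix = (1−f)·p_parent + f·p_diluent`, taking reads
as proportional to RNA mass (the assay mixes by total RNA mass; no other
conversion is stated anywhere, so the identity is used). Technical
variability enters twice: the realized fraction is truncated-Normal around f
with σ_f = 0.02 (the magnitude of in-vitro mixing error is this framework's
choice; the source studies used a known but unpublished value), and the
measured counts are one multinomial draw at the simulated depth. The
multinomial layer deliberately adds no NB dispersion — the parent counts
already carry it, and adding it again would double-count. When technical
replicates of parent or diluent exist, all pairwise parent×diluent
combinations are cycled through the ensemble.

The **90%-concordance LOD** is the most diluted fraction at which at least
90% of simulated mixtures keep the parent's call. Monte-Carlo noise can make
the raw concordance curve non-monotone, so a decreasing isotonic regression
(weighted by per-point simulation counts) is applied before the threshold
scan; on noise-free decreasing curves this is the identity, and the
estimator reduces to a grid scan. The bootstrap CI resamples simulated calls
within each grid point; for binary calls this is exactly a Binomial(n, ĉ)
draw per point, which is how it is implemented (and why 500 bootstrap
replicates on a 1001-point grid are cheap). The threshold is applied to the
smoothed curve — raw-versus-smoothed is a genuine ambiguity, resolved in
favor of smoothed because the raw rule is not monotone in the threshold.

The **spline-crossing LOD** fits a cubic smoothing spline (smoothing chosen
by generalized cross-validation; an interpolating cubic below 5 distinct
fractions; replicates averaged with weights) to measured score-vs-fraction
series and locates the smallest fraction at which the fitted curve leaves
the parent's side of the boundary, by bracketed root finding. A curve that
never crosses is flagged rather than extrapolated.

## Interference studies

Blood is quantified by the marker-gene share of total reads and stress-tested
by titrating a UIP parent with the blood library through the mixture engine
(the marker share of a mixture is exactly linear in the realized fraction —
an algebraic identity the tests exercise). Genomic DNA is spiked at a
nucleic-acid mass fraction (default 0.30, i.e. 6.43 ng on 15 ng of RNA) with
reads length-allocated; input mass is varied over {5, 10, 15, 20, 30} ng.
Condition effects are tested with ordinary least squares including sample as
a fixed factor (`score ~ C(sample) + condition`) — at these tiny balanced
designs this is the fully specified equivalent of a mixed model, and the
package prefers an estimator whose behavior is exactly reproducible.
Significance is two-sided at 0.05. Both studies inject the assay's
replicate-level score noise (`replicate_sd`) so that effects are judged
against realistic technical variability rather than the bare read-sampling
floor; with noise off, the tests become hypersensitive to the small
depth-mediated bias that the VST's curvature induces on mean scores.

## Reproducibility estimators

From a scores table with sample/lab/run/replicate annotations:

* **within-run SD** — pooled SD of residuals about (sample, lab, run)
  replicate-group means, divisor N − #groups;
* **run-to-run SD** — pooled SD of replicate scores about per-sample means:
  the *nested total* technical SD, which includes the within-run component
  (the convention that matches reporting a run-to-run SD alongside a smaller
  within-run SD);
* **inter-lab pooled SD** — replicates averaged within (sample, lab), then
  pooled SD about per-sample means over samples shared by both labs;
* **inter-class SD** — SD of per-sample mean scores across all labeled
  samples; with positive class separation it dominates every technical
  component, which the validation report checks.

Under the reference design (9 samples × 3 runs × 3 replicates, run variance
0.0076, residual variance 0.0324) the estimators' expectations are 0.18 for
the within-run SD and √(0.0324 + 0.75·0.0076) ≈ 0.195 for the nested
run-to-run SD — the 0.75 is the balanced-design coefficient (1 − n_rep/n) of
the run variance in the pooled sum of squares, so the estimator sits a hair
below the √0.04 = 0.20 population value. The nested ordering
run-to-run ≥ within-run holds in expectation but is not a finite-sample
theorem under these divisors; it is checked on simulated data rather than
enforced in the data structures.

CIs come from a residual bootstrap: residuals of the component's centering
model, inflated by √(N/(N−k)) to undo the mean-removal shrinkage, are
resampled with replacement, scores rebuilt, and the component re-estimated
(percentile 95% interval; vectorized over bootstrap replicates).

**Noise tolerance** adds Gaussian noise to out-of-fold cross-validated
scores before calling and reports the largest grid SD at which both
sensitivity and specificity stay within a margin (default 5 percentage
points — "substantial reduction" is not defined anywhere authoritative, so
the package states its own) of the noise-free baseline; the first breach
caps the tolerance, making the reported limit monotone in the margin.

**Storage stability** is a one-way ANOVA of DV200 (the percentage of RNA
fragments over 200 nucleotides) across cold-storage time bins.

## Validation report

`run_validation_suite` chains the full battery from a single (config, seed):
training cohort → surrogate training → cross-validated quality gate → three
LOD studies (UIP SLB into non-UIP TBB; blood into UIP TBB; adjacent-normal
into UIP TBB) → gDNA and input-mass interference → variance components with
bootstrap CIs, inter-lab concordance, noise tolerance, storage ANOVA. A
failing quality gate (cross-validated sensitivity or specificity below 0.80)
skips the LOD and interference stages, since their reference calls would be
meaningless. Stage seeds derive from the top-level seed via
`SeedSequence([seed, stage_index])`, making the report reproducible
bit-for-bit. Default Monte-Carlo sizes (200 simulations per grid point, 200
bootstrap replicates, depth 10⁵ for mixture ensembles) keep the suite to a
few minutes on one core while holding every estimate well inside its
Monte-Carlo tolerance.

## What passing tests do and do not show

The framework's tests demonstrate *estimator correctness* (against
closed-form oracles, brute-force enumerations and parameter-recovery
simulations) and *internal consistency* of the battery on data with known
truth. They do not — cannot — reproduce the production assay's clinical
numbers: the published LOD percentages and score SDs were measured on
proprietary clinical samples with the proprietary locked classifier. Where
published arithmetic is self-contained (the blood linear-mixing relations;
the variance-component magnitudes used as simulation truth), the package
recovers it; everything else about real TBB data (per-gene biological
variability, library-preparation batch chemistry, RNA degradation patterns)
is outside the generative model and explicitly not claimed.

## Known limitations

* No gene-level biological variation within a tissue role beyond the shared
  library factor; technical-replicate realism comes from injected
  score-scale effects.
* The gDNA background assumes perfectly exonic capture; intronic/intergenic
  carry-through is not modeled.
* The surrogate classifier is linear by construction; battery behavior under
  a strongly non-linear production model is untested.
* Mixtures are compositional: no RNA-quality interaction (e.g. a degraded
  diluent contributing fewer effective reads per ng).
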