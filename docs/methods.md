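# Methods

## Scope

`soynmr` implements the chemometric workflow used to discriminate the
geographical origin of soybeans from one-dimensional ¹H-NMR spectra:
spectral simulation, binning, normalization and scaling, (O)PLS-DA
modelling, permutation validation, leave-one-out classification and
VIP-based variable selection. Because no public deposition of the original
raw spectra exists, the package ships a first-class synthetic-data module
whose defaults encode the study design the analysis assumes; every
downstream stage is exercised and tested against it.

## Synthetic cohort model

**Design.** 68 samples: 8 Korean regions and 9 Chinese provinces, 4
experimental replicates each. Chinese provinces group into three
macro-regions — northeastern (NR: Heilongjiang, Jilin, Liaoning), middle
(MR: Hebei, Shandong, Hubei) and southern (SR: Zhejiang, Guangdong,
Guangxi).

**Concentrations.** Each of the 25 metabolites in the assignment library
has a base concentration in arbitrary units (sugars ~4–10, free amino and
organic acids ~0.1–1.5, chosen once to echo the gross composition of
aqueous-methanol soybean extracts). Group effects are multiplicative
fold-changes attached to tags (country or macro-region): 1.30 for the nine
country discriminators in their reported directions (alanine, citrate,
isoleucine, tartarate, valine up in Korea; asparagine, choline,
galactarate, tryptophan up in China) and 1.40 for the regional markers
(glucose, hypoxanthine, leucine, tartarate up in NR; malonate and alanine
up in SR). Magnitudes are conventions — the source study reports
directions and significance, not effect sizes — picked once so that a
cohort of n = 68 sits in the near-perfect-classification regime its
published confusion tables describe. Replicate variation is multiplicative
lognormal with CV 0.10 (a typical biological+technical replicate spread
for seed extracts).

**Spectra.** Each assignment-table row renders as a first-order multiplet
of Lorentzian lines: offsets k·J/600 ppm (600-MHz instrument), binomial
intensity ratios (s:[1], d:[1,1], t:[1,2,1], q:[1,3,3,1], dd = outer
product of two doublets), total area equal to the metabolite concentration
(one proton-equivalent per row; relative levels are all the analysis
uses). Unresolved multiplets ("m") render as a symmetric 5-line [1,2,3,2,1]
pattern spaced 7 Hz — the fine structure is unspecified and 0.04-ppm
binning erases it; broad singlets use 4× linewidth. Shift ranges "a–b"
enter as midpoints. Defaults: FWHM 1.2 Hz (0.002 ppm, a typical high-field
linewidth), per-sample per-peak shift jitter SD 0.002 ppm, grid 0.0–10.0
ppm at 0.0005 ppm (20 001 points, ≥ 80 points per bin). A TSP reference
singlet at 0.00 ppm has area 5 times a per-sample lognormal drift factor
(CV 0.05) emulating internal-standard/instrumental variability — this
drift is what makes total-area and standardized-area normalization differ
measurably. Intensities in the 4.7–5.0 ppm water-suppression window are
attenuated 100-fold; additive Gaussian noise (SD 3.0) gives a per-peak SNR
of roughly 100 for a unit-concentration singlet (peak height
2/(π·FWHM) ≈ 318). All randomness flows from one integer seed;
simulation and rendering are bit-reproducible.

**What the simulator does not model:** spin-system second-order effects,
baseline and phase distortion, peak-position drift correlated with pH or
ionic strength, ¹³C satellites, and between-cultivar covariance structure.
Passing tests therefore demonstrate that the *pipeline* recovers planted
effects under clean, well-controlled spectra — not that the specific
published accuracies would be reproduced on new real cohorts.

## Preprocessing

**Binning.** Spectra are bucketed into half-open [low, high) bins of 0.04
ppm over 0.08–10.00 ppm (248 raw bins). Bins *fully contained* in the
water window 4.70–4.86 ppm are dropped — exactly [4.72,4.76), [4.76,4.80)
and [4.80,4.84) — leaving 245; partial-overlap bins at either edge are
retained. Full containment is the only exclusion convention consistent
with the published bin count. Bin values are sums of grid-point
intensities (means differ by a constant and cancel under normalization).
The integral of the raw spectrum below the first bin edge (0.0–0.08 ppm,
which holds only the TSP singlet) is captured per sample as the reserved
reference measurement.

**Normalization.** Total-area normalization divides each sample's bins by
their sum (rows become compositional); standardized-area normalization
divides by the sample's reference-peak measurement. Zero denominators
raise errors naming the sample.

**Scaling.** Column-wise: UV divides centred columns by the sample SD
(ddof 1), Pareto by its square root. Columns with SD below 1e−12 are
centred but left unscaled, keeping column indices stable. Scaling
parameters fitted on training data are reused verbatim on held-out
samples.

**Metabolite aggregation.** Per-metabolite features sum the bins holding
that metabolite's peak centres, following the non-overlapping-peak
convention of NMR profiling: ownership of a bin is decided from the actual
multiplet *line* positions (centre ± k·J/600), and only bins touched by a
single metabolite count as unique. A metabolite with no unique bin
(alanine, choline, succinate under the default library) falls back to all
bins holding its centres, logged. This matters quantitatively: the
3.4–4.1 ppm sugar envelope otherwise leaks sucrose and glucose signal into
amino-acid features and erases their group contrasts — which is also why
the crowded-region markers (alanine, choline) end up with the weakest VIP
scores, mirroring how overlapped markers behave in real spectra.

## Models

**NIPALS PLS2.** Components are extracted by the classical iteration
(w = Xᵀu/‖Xᵀu‖, t = Xw, c = Yᵀt/tᵀt, u = Yc/cᵀc) with both X and Y
deflated by t. Convergence: relative score change ≤ 1e−10, cap 500
iterations; u initializes from the first Y column (ties in degenerate
eigendirections resolve deterministically). On reaching the cap the
current score is accepted with a RuntimeWarning — near-degenerate
eigenpairs of XᵀYYᵀX (routine under permuted multi-class responses) make
the score rotate indefinitely inside a well-determined subspace;
`strict_convergence=True` raises instead. Regression coefficients are
B = W(PᵀW)⁻¹Cᵀ; models centre X and Y internally and store training means.

**OPLS.** Orthogonal-signal filtering in the Trygg–Wold form: from
w ∝ Xᵀy, repeatedly extract (w_o, t_o, p_o) with w_o ∝ p − (wᵀp)w and
deflate X by t_o p_oᵀ, then fit one predictive PLS component on the
filtered matrix. Orthogonal scores have zero covariance with y by
construction; fitted training values coincide with a (1+k)-component PLS
model. Multi-response OPLS is not implemented (two-class models use a
single 0/1 code; the three-class design uses PLS2 on the dummy matrix).

**Fit statistics.** R²Y from the full fit; Q²Y from PRESS over stratified
7-fold CV (shuffled with a fixed seed, scaling refit per fold; LOO is
reserved for the classification layer). **Autofit** grows the component
count (or the orthogonal count k in "1+k") greedily while Q²Y improves by
more than 0.01, always returning at least one component; the threshold is
a configurable stand-in for the unpublished rule of commercial autofit
implementations.

**VIP.** VIP_j = √(p·Σₐ w²ₐⱼ·SSYₐ/ΣSSYₐ) over Y-predictive components with
SSYₐ = (cₐᵀcₐ)(tₐᵀtₐ); for OPLS only the predictive component enters, so
the formula collapses to √p·|w_j| and the Σ VIP² = p identity is exact
(commercial variants blend orthogonal components and break it).

## Validation layer

**Class coding.** The first-named class of a comparison is the case,
coded 1; a sample is called "case" when its LOO-predicted value exceeds
0.5 (exact ties — a probability-zero event — go to control). For three
classes, three independent case-vs-rest models are built; the indicator
coding is the complement of the (0 1 1)/(1 0 1)/(1 1 0) dummy-row
convention and yields identical models after centring.

**LOO-CV.** For each sample: remove it, refit scaling on the remainder,
refit the model with the component signature and variable subset *frozen*
from the full-data selection, predict the held-out sample (Ypredcv). Fully
nested re-selection per fold is intentionally not the default — one model
is applied, as in the published workflow. Confusion metrics are reported
as percentages rounded half-up to one decimal.

**Permutation test.** Response rows are shuffled (stratification labels
jointly); the model is refit per permutation with unchanged structure;
R²Y and Q²Y are regressed on the mean absolute Pearson correlation between
permuted and original response, including the unpermuted model at
correlation 1. Validity requires R²Y-intercept < 0.40 and Q²Y-intercept
< 0.05; 100 permutations by default (count unpublished; seeded).

**ROC.** AUC via the trapezoid rule on the empirical ROC curve, equal to
the concordance probability with ties counted ½ (cross-checked against
exhaustive pair counting in the tests).

## Workflow conventions

The model-selection grid evaluates {standardized, total} × {UV, Pareto},
autofits each cell, and marks selected the cell with the highest Q²Y among
those passing the permutation bounds *and* having Q²Y > 0 (the intercept
bounds alone cannot reject a null model whose flat permutation line sits
below them); ties break by R²Y, then fewer components. The VIP sweep
scores cutoffs against the full-data base model's VIP ranking without
recomputation after refits; the cutoff-0 row is the base model and rows
retaining fewer than two variables are flagged infeasible.

Preset feature spaces differ deliberately. The two-class country model
(`korea_china`: total-area + UV + OPLS-DA, no VIP cutoff) runs on the 25
metabolite features. The regional preset (`china_regions`:
standardized-area + UV + PLS-DA, VIP ≥ 1.0) runs its grid and permutation
diagnostics on the metabolite table — where n = 36 > p = 25 keeps
permutation intercepts meaningful — but selects variables and classifies
at bin resolution: blind 0.04-ppm bin sums cannot reproduce the
per-compound deconvolution that vendor software performs on real spectra,
and the middle-region model (the one with no markers of its own) needs the
uncontaminated bin-level contrasts. Each one-vs-rest model autofits its
own component count, frozen inside the LOO folds.

Group-level comparisons use Welch's two-sided t-test per metabolite with a
significance flag at p < 0.05 and no multiplicity correction by default
(Holm/Bonferroni available), matching the descriptive use of such tests in
origin studies.

## Problem sizes and determinism

Default analyses run the full 68-sample cohort, 245 bins, 100
permutations and complete leave-one-out loops; a full preset run takes a
few seconds on one CPU. The test suite uses the same cohort plus reduced
permutation counts (20–30) for auxiliary checks and 20 seeded replicate
cohorts for the marker-retention property. Every stochastic step (cohort
draw, render noise, CV folds, permutations) is driven by explicit integer
seeds; repeated runs are byte-identical, and output files carry the seed
and a configuration hash in their headers.

## Known limitations

- Simulated spectra are baseline-clean and alignment-perfect; no warping,
  baseline correction or peak alignment is implemented or needed here.
- Bin-to-metabolite aggregation is centre/line-based and cannot resolve
  co-resonant compounds; crowded-region features remain partially mixed.
- The autofit rule is a greedy Q²Y heuristic, not a reproduction of any
  proprietary component-significance test.
- Published real-data statistics (e.g. R²Y 0.882 / Q²Y 0.783 for the
  country model on the original cohort) depend on unavailable raw spectra;
  the package reproduces the procedure and its confusion-count arithmetic,
  and demonstrates recovery of planted effects, not those exact values.
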