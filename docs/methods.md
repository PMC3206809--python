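# Methods

This note records the models implemented by `fibroscore`, the assumptions
behind them, the parameter defaults and why they were chosen, and what the
synthetic data generator does and does not emulate.

## Per-feature effect statistics (KR)

Every (drug, marker, feature, concentration) condition is compared with the
drug's own drug-free control on the same plate:

- **Unimodal features.** Signed two-sample Kolmogorov–Smirnov score:
  magnitude `D = max_x |ECDF_treated(x) − ECDF_control(x)|`, sign from
  `median(treated) − median(control)`. When medians tie exactly the mean
  difference decides; when that is also zero the score is 0. Only the D
  statistic is used — KR is an effect size, not a hypothesis test, so no
  p-value enters the pipeline. D is computed by sorting and `searchsorted`
  on the pooled support; the test suite checks it against both
  `scipy.stats.ks_2samp` and a brute-force ECDF enumeration over all small
  discrete samples.
- **Bimodal features.** Some readouts split cells into two populations
  (BrdU incorporation being the canonical case). For these the score is
  `p_treated − p_control`, the difference in the fractions of cells above a
  threshold placed at the midpoint of the two component means of a
  two-Gaussian mixture fitted to pooled control cells (Otsu histogram split
  as a degenerate-fit fallback). Both conventions are bounded in [−1, 1] by
  construction.

**Modality classification.** Whether a feature is scored by KS or by ratio
is decided once per (marker, feature), on control cells pooled across
drugs, by comparing one- and two-component Gaussian mixture fits by BIC and
requiring genuine separation of the winning two-component fit: Ashman's
`D = |µ1 − µ2| / sqrt((σ1² + σ2²)/2) ≥ 2` with both weights ≥ 0.05. The
separation floor reflects the analytic fact that an equal-weight
two-Gaussian mixture stops having two density modes below ≈ 2σ separation,
so borderline mixtures are deliberately classified unimodal. The mixture
fits use a fixed initialisation, making the label deterministic given the
sample; at least 50 control cells are required. For screens with very large
pooled controls the classification sample is capped at ~2000 cells by
deterministic striding — the shape call does not improve beyond that, and
the scoring itself always uses every cell.

## SAUC

Per drug and marker, each feature's KR-versus-concentration curve is
integrated by the trapezoid rule and the feature areas are summed:

    SAUC(drug, marker) = scale × direction(marker) × Σ_f AUC_f .

Numerical conventions:

- The concentration axis is the **dilution index** (control, step 1, …,
  step K) normalised to [0, 1] by default. Each drug is screened up to its
  own IC50-anchored maximum concentration, so an index axis is the only
  choice that makes areas comparable across drugs; `log2` (identical for
  exact 2-fold series) and `raw_um` modes exist for completeness. The axis
  mode is recorded on the matrix.
- Every curve is anchored at (0, 0): the control scored against itself is
  identically zero. A consequence worth knowing: a series at the ceiling
  KR = 1 integrates to 1 − 1/(2K) (0.95 at K = 10 steps), not 1, because
  the first segment rises from the anchor.
- `direction(marker)` ∈ {+1, −1} encodes the anti-fibrotic direction
  (caspase 3 up is anti-fibrotic: +1; collagen III, BrdU, ΔΨm, F-actin,
  DHE, TIMP-1, Smad3 nuclear translocation, pCREB down: −1; MMP-2 up: +1).
  The assignments live in a packaged CSV, not in code, and are
  user-overridable — they are biological conventions, not algorithm.
- `scale = 1000` is cosmetic, chosen so synthetic E_predict magnitudes are
  of the same order as the published values.

SAUC is linear in KR and bounded by `scale × n_features × axis length`.

## In vivo efficacy index

`E_in_vivo = (Sc − St) × Sc`, with both scores linearly rescaled to the
0–4 range shared by the common fibrosis staging systems (Metavir, Knodell,
Ludwig). The `× Sc` factor weights score reduction by disease severity:
clearing severe fibrosis counts for more than clearing mild fibrosis.
Negative values (the drug worsened histology) are retained — unlike
E_predict, this index is not clipped. When several studies cover the same
(drug, model) pair the highest index is kept, always within a model; the
severity induced by different hepatotoxins differs, so indices are never
compared across models. Displayed values are rounded to 1 decimal, half
away from zero; internal values are never rounded.

## E_predict and weight optimization

`E_predict = max(0, Σ_m w_m · SAUC_m)` with `w ∈ {0,1,2}` per marker.
The weights are fitted by exhaustive enumeration of all 3^10 = 59049
vectors against a training E_in_vivo set, scored by Spearman rank
correlation with **one outlier allowed**: for each vector the best rho over
the full set and every leave-one-out subset is taken (the literature
training sets are small, so a single aberrant study should not veto a
vector). The enumeration is vectorised: one matrix product gives all
candidate E_predict rows, and tie-corrected Spearman is computed as Pearson
on ranks for all rows at once, so the full lattice evaluates in well under
a second. Implementation choices:

- Candidate values are clipped at 0 *before* the correlation, matching the
  definition of the predictor being optimized (a flag disables this).
- A vector whose candidate values are all tied (e.g. the zero vector) has
  undefined rho and can never count as concordant.
- Among all vectors achieving rho = 1 the optimized weight per marker is
  the most frequent value; ties go to the smaller weight (parsimony). The
  per-marker weight histograms and the rho = 1 count are part of the
  results object — they measure how constrained each marker actually is.
- If no vector reaches rho = 1 the fit raises, reporting the best rho
  attained, rather than silently returning a sub-concordant solution.
- Each vector may discard a *different* outlier; the allowance is per
  evaluation, not a global choice of drug.

**Non-specific flag.** Drugs that increase collagen III expression with
dose are scored zero regardless of the weighted sum: the flag trips when
the collagen III cytoplasmic total-intensity KR exceeds +0.2 at the top two
concentrations and is non-decreasing (tolerance 0.05) over the upper half
of the concentration range. The thresholds are configurable; the defaults
are set so a monotone concentration-dependent increase trips the flag while
null drugs (|KR| < 0.05) cannot.

**Robustness.** `weight_robustness` reports the fraction of the whole
lattice reaching rho = 1, against the same fraction after randomly
permuting the in vivo ranks — a real in vitro–in vivo relationship shows up
as a large gap between the two.

## IVIVC regression and prediction

Ordinary least squares of E_in_vivo on E_predict per fibrosis model
(statsmodels). Outlier handling: a named drug can be excluded, or `auto`
mode removes the point with the largest absolute externally studentized
residual provided the removal improves R² by more than 0.1 — a deliberately
conservative rule so that well-behaved panels keep all points. R² is always
computed on the included points only. The fitted line converts an
E_predict into a predicted E_in_vivo; inverting the index definition gives
the predicted treated score `St = Sc − E/Sc`, clipped into [0, Sc]. On the
packaged tables this reproduces: CCl4-treatment R² = 0.961 (taurine
excluded), DMN-treatment R² = 0.960 (colchicine excluded), CCl4-preventive
R² = 0.532 (PCN excluded) — the preventive model is biologically expected
to correlate worse, since an already-activated HSC line mimics treatment,
not prevention.

## Drug profiling

- **Groups**: n = all drugs with E_predict exactly 0; vp = the 7 largest
  positive values (boundary ties resolved alphabetically — documented,
  arbitrary); p = the rest.
- **PCA** on the drugs × markers SAUC matrix, column-centered and unscaled
  by default (all columns share units; a switch enables unit-variance
  scaling). Variance ratios sum to 1; a constant matrix raises.
- **Marker saturation**: mean over random marker subsets of the best
  lattice-attainable rho, as a function of subset size — the curve's
  plateau indicates how many markers a panel actually needs.
- **Group intensity summaries**: per group and marker, boxplot statistics
  (median, quartiles, 1.5×IQR whiskers, outlier drugs) of per-drug mean
  average-intensity KR.

## Synthetic screens

The generator emulates the *structure* of the screen — drugs ×
(control + 2-fold dilution series) × markers × per-cell features — with a
known ground truth:

- each drug has a latent `true_efficacy ∈ [0, 1]`, per-marker
  susceptibilities, and a Hill dose–response
  `h(c) = c^n / (c^n + EC50^n)` (defaults EC50 = 2.5 µM, n = 1.5, top
  concentration 10 µM over 10 steps);
- unimodal features are Gaussian with marker-specific σ (15–33 a.u.); the
  treated mean shifts by `2σ × direction × efficacy × susceptibility ×
  h(c)` (nuclear shape features respond at 0.4× — morphology moves less
  than biochemistry); the shift follows the marker-direction table, so
  anti-fibrotic drugs produce positive SAUC by construction;
- the BrdU average-intensity feature is an equal-weight two-Gaussian
  mixture with modes 8σ apart whose responder fraction moves by up to 0.45
  with the same factor — this exercises the bimodal KR branch
  unambiguously;
- non-specific drugs get a dose-dependent *increase* of 2σ·h(c) in collagen
  III intensity features regardless of efficacy, to exercise the flag;
- matched in vivo records use `Sc ~ Uniform(2.5, 4)` and
  `St = clip(Sc − g(e)·Sc + ε, 0, Sc)` with the identity link `g(e) = e`
  (the simplest monotone choice, configurable) and Gaussian score noise ε.

Everything is driven by one `numpy` Generator seed; identical seeds give
byte-identical tables.

**What passing on synthetic data shows — and what it does not.** The
generator contains no segmentation error, plate/edge effects, well drift,
feature correlations, or heavy-tailed intensity distributions, and the
per-marker effect magnitudes of real drugs are unknown (the published
per-cell data is not available). Tests on synthetic screens therefore
validate the *statistical machinery* — bounds, null behaviour, rank
recovery, oracle equivalence — not the absolute published E_predict scale,
which enters the correlation analyses as a fixed packaged input.

## Problem sizes and tolerances

Suite defaults were chosen as the smallest sizes at which sampling error is
comfortably inside the asserted bounds: null-drug KR bounds use 5000
cells/condition (KS sampling noise ≈ 0.027 at that size, asserted < 0.05);
the 12-drug rank-recovery screen uses 250 cells/condition with weights
trained on a 6-drug subset — the size of the actual training panel — and
asserts Spearman ≥ 0.8 over all 12; the robustness comparison averages 20
seeded 6-drug screens at 100 cells/condition with 4 features per marker.
Monotonicity checks on KR dose–response curves use a 0.1 tolerance for
sampling noise. Rounding of displayed indices is half-away-from-zero at 1
decimal; rho = 1 detection uses a 1e-9 tolerance on the tie-corrected
coefficient.

## Known limitations

- The modality rule and the bimodal threshold are principled
  reconstructions (the original screen's exact rule is not published);
  both are overridable per feature.
- The published optimized weight vector is unknown, so analyses that need
  published E_predict values consume them as data rather than recomputing
  them.
- Absolute SAUC/E_predict magnitudes depend on the axis mode and scale
  constant; only ranks and fitted lines are comparable across
  configurations.
- One outlier allowance is hard-capped at a single point; with training
  sets of 4–6 drugs, allowing more would make rho = 1 nearly vacuous.
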