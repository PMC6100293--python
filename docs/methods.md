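# Methods

## Scope and model

`pepqsar` implements a position-wise 2D-QSAR workflow for short peptides,
specialized to antioxidant tripeptides whose activity is expressed as a
TEAC value (µM Trolox equivalents per µM peptide). The model class is
deliberately simple: a peptide of `n` residues described by `m`
amino-acid property scales becomes a vector of `n × m` descriptors
`V_jk` (property `k` of the residue at position `j`), and activity is
regressed on a screened subset of those descriptors. For tripeptides
against a 195-scale panel this is the classical 585-variable encoding.
Position 1 is the N-terminus; position 3 (the C-terminus) is the
position the antioxidant-peptide literature repeatedly identifies as
activity-determining.

Assumptions worth keeping in mind:

- Additivity: activity is modelled as a sum of independent per-position
  residue effects. Cooperative effects between positions are not
  representable by the linear models (SVR/RF can capture some).
- The descriptor panel is treated as fixed and complete; property scales
  with missing residue values are excluded, not imputed, because any
  imputation scheme would be arbitrary at 20 support points.

## Autoscaling and the meaning of coefficients

Both descriptors and the response are autoscaled (mean 0, sd 1, `ddof=1`)
before screening and fitting. Consequences:

- the OLS intercept vanishes by construction, so fitted linear equations
  are intercept-free;
- fitted coefficients are normalized regression coefficients (NRCs) and
  can be compared across variables as importance measures;
- zero-variance columns are undefined under scaling and are dropped
  before modelling, with the dropped names reported.

Predictions are always reported back on the original activity scale via
the stored response mean/sd.

## Stepwise screening

Variable screening is classical forward-entry / backward-removal
stepwise OLS. The thresholds are probability-of-F levels — enter at
p ≤ 0.05, remove at p ≥ 0.10 — i.e. the defaults of the major
statistics packages; raw F-value thresholds of 0.05/0.10 would admit
essentially everything. Residual degrees of freedom account for the
implicitly fitted intercept (`n − k − 1` for `k` variables), so partial-F
p-values agree with an intercept-including OLS fit on uncentered data.

Determinism and termination:

- ties between equal p-values break toward the earlier column;
- the screen stops when no action fires, when the next entry would
  re-enter the variable just removed, or when an enter is immediately
  undone by the removal phase (the classic stepwise livelock) — in that
  case the variable is dropped and the run ends;
- a numerically exact fit (vanishing residual) terminates entry rather
  than producing infinitely significant noise variables;
- the variable count is capped at `rows − 2`, recorded via a
  `truncated` flag.

Collinearity of the screened set is checked with VIF = 1/(1 − r²),
where r² comes from regressing each selected column on the others;
values below 5 are treated as uncorrelated, and exact collinearity is
reported as infinite rather than capped.

## Model fitting and validation

Four methods are fitted on the screened variables: MLR (in-house least
squares), PLS, RBF-kernel ε-SVR and random-forest regression (the latter
three via scikit-learn behind the module interface).

- PLS: when the component count is not given it is chosen by maximizing
  leave-one-out Q². Components beyond the design rank carry no signal
  and are numerically unstable, so the effective count is capped at the
  rank (predictions are unchanged by the cap).
- SVR: hyperparameters are chosen once by a seeded 5-fold grid search
  over C ∈ {0.1, 1, 10, 100}, γ ∈ {0.01, 0.1, 1}, ε ∈ {0.01, 0.1};
  cross-validation loops then refit with the frozen winner. Re-tuning
  inside every LOO fold would nest the search and answer a different
  question than a validated model table does.
- RF: 500 trees by default, seeded; scikit-learn defaults otherwise.

Validation metrics follow chemometric convention: R² is the squared
Pearson correlation of observed versus calculated/predicted values (for
OLS on training data this equals 1 − RSS/SS; for other methods and on
test data it does not, and the Pearson definition is the one matching
the scatter-plot reading). PRESS is the leave-one-out predicted residual
sum of squares on the original activity scale, Q² = 1 − PRESS/SS_total
with SS_total about the full training mean — an identity the
implementation satisfies exactly because Q² is computed from PRESS.
k-fold Q² uses a seeded shuffle into near-equal folds; with `k = n` and
no shuffling it reduces to LOO. SD = √(RSS/(n − m − 1)) and
F = (R²/m)/((1 − R²)/(n − m − 1)).

The train/test split sorts peptides by descending activity (ties by
sequence) and sends every third rank (1, 4, 7, …) to the test set —
91 peptides split 60/31. This stratifies the skewed activity range
across both subsets.

## Residue contributions and design

For a linear model, contribution(a, j) = Σ over selected variables
`v = acc_pj` of NRC(v) · z_acc(a), where z_acc(a) standardizes property
`acc`'s value for residue `a` with the same column statistics as the
descriptor matrix. This is the unique definition under which the
standardized prediction of any peptide equals the sum of its
per-position contributions, which the tests assert directly. Rankings
report signed totals: predominant = most positive, deleterious = most
negative (not smallest in magnitude). Positions with no selected
variable contribute zero and are flagged degenerate in rankings.

Design enumerates the Cartesian product of per-position allowed residue
sets in lexicographic order, encodes and scores candidates with a fitted
model, and ranks them (ties lexicographic). Candidates whose selected
descriptors fall outside the training min/max are flagged as
extrapolations — model-guided designs deliberately push into favourable
corners of descriptor space, where linear predictions are least
trustworthy.

## Assay quantitation

DPPH scavenging is the percent absorbance loss at 517 nm,
100·(A_c − A_s)/A_c; negative values (pro-oxidant behaviour) are
returned as-is. TEAC and FRAP invert a fitted calibration line
(absorbance on concentration, ordinary least squares; the fit refuses
r² < 0.98 by default) to an equivalent analyte concentration — trolox at
734 nm, FeSO₄ at 593 nm — and divide by the peptide molar concentration.
Molar masses are average-isotopic (residue masses + one water), matching
synthesis-vendor conventions. Read-offs outside the calibrated range
(trolox 150–1500 µM, FeSO₄ 200–1200 µM) are flagged, not refused.
Replicates aggregate as mean ± sd (ddof = 1) with n reported; sample
concentration is an explicit per-measurement input, never a constant.

## Synthetic data: what it emulates and what it does not

The generator draws distinct tripeptides uniformly over residues and
assigns activity = offset + scale·(Σ β_k z_k + ε), ε ~ N(0, noise_sd),
over autoscaled descriptor columns. Defaults (the reference study
conditions used throughout the tests): 91 peptides, 3 true variables —
a dominant positive weight (1.1) on the C-terminal solution-free-energy
scale, a steric weight (0.35) at position 1 and a negative-charge
penalty (−0.25) at position 2 — noise sd 0.15, offset 0.55, scale 0.42.
The affine map was calibrated once so that, pooled over seeds, well over
60% of activities fall in the 0.028–0.995 µM TE/µM bulk and at least 5%
exceed 1.5, with the tail reaching ≈ 2.3: the skew characteristic of
published antioxidant tripeptide panels, produced here by the bimodal
C-terminal scale (aromatic/thiol residues high) rather than by a
nonlinear transform.

What passing tests on this generator do *not* show: real panels have
correlated descriptor scales, sequence composition biases, heteroscedastic
assay error, and an activity floor at zero (the linear surrogate emits a
small fraction of slightly negative activities, which are kept to
preserve exact linear-recovery arithmetic). Recovery rates and Q² values
on synthetic data are therefore upper bounds on what the same pipeline
achieves on laboratory data.

Plate simulation places standards exactly on a calibration line
(trolox: slope −4.5·10⁻⁴ AU/µM, intercept 0.72 — a decolorization
assay; FeSO₄: slope 8·10⁻⁴ AU/µM, intercept 0.05) plus Gaussian
absorbance noise, and samples at the equivalent concentration implied by
their true value, in triplicate. Zero-noise plates must round-trip
exactly; at 0.005 AU noise, recovery is within 5% for ≥95% of samples
when equivalent concentrations sit inside the calibrated range.

## Problem sizes used in the checks

The default test and acceptance runs use the 20-scale bundled+synthetic
panel (60 descriptor columns) with 91-peptide datasets, 100-replicate
screens for the oracle-agreement and recovery rates, and a 500-peptide
dataset for the asymptotic Q² check. These sizes make every property of
interest measurable while keeping a full run in the tens of seconds; the
585-column encoding is exercised directly where column arithmetic is the
point.

## Known limitations

- The bundled property fixture is synthetic: it reuses published
  accession identifiers with constructed values that follow each scale's
  semantics. Reproducing published fits requires a genuine AAindex1
  release and the original curated activity table, supplied externally.
- Stepwise screening inherits the known biases of greedy selection
  (overfitting at liberal thresholds, instability under collinearity);
  the VIF gate mitigates only the latter.
- Contribution analysis is defined for linear models only; no
  permutation-importance analogue is provided for SVR/RF.
- Only equal-length peptides are supported; there is no alignment or
  gap handling.
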