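# Methods

## The data model

The unit of analysis is a specimen table: one row per ant worker with a
species label, a boolean infection status, and 21 linear trait
measurements in μm following the standard *Temnothorax* protocol (CL,
CWb, EL, FRS, ML, MW, NOH, NOL, PEH, PEW, PoOC, PPH, PPL, PPW, SL, SPL,
SPBA, SPST, SPTI, SPWI, PEL). Validation is strict and total: traits
must be strictly positive finite numbers, specimen ids unique, and
missing values are rejected rather than imputed — no published handling
of missing measurements exists for this workflow, and silent imputation
would corrupt the moment estimates downstream. Units are fixed to μm; a
configurable scale factor on read (`TableDialect.scale`) supports
deposits stored in mm, and infection encodings ({0,1}, TRUE/FALSE,
infected/uninfected, …) are mapped through a user-extendable synonym
table.

## Linear-model analysis of infection effects

Traits confound two scales of variation: species body size and the
infection effect. Before per-trait modelling, every trait is z-scaled
within species (sample SD, n−1 divisor; the subtracted mean and divisor
are kept so the transform inverts exactly). On that scale:

- the **global model** `value ~ trait * infected * species` over the
  long (specimen × trait) table, decomposed by sequential (Type I) sums
  of squares with terms in the fixed order trait, infected, species,
  trait:infected, trait:species, infected:species,
  trait:infected:species. Sequential decomposition matches the
  convention of R's `anova.lm`, which the published table layout
  follows. F is the term mean square over the residual mean square. The
  df identity Σdf = N − 1 is asserted on every fit. Factors left with a
  single level are dropped from the formula, so the model degenerates
  gracefully (one trait, one species → a plain two-group comparison
  whose F equals the squared pooled t).
- **per-trait models** `value ~ species * infected` (21 of them);
  species × infection interaction p-values are Bonferroni-adjusted with
  family size m = 21 (the traits).
- **contrasts**: the uninfected-minus-infected difference of predicted
  cell means per species × trait, with SE from the OLS coefficient
  covariance and t on the residual df. Because the contrast is a
  difference of cell means, the factor coding cannot affect it;
  estimates agree with R's `emmeans` to ≥8 significant digits (tested).
  The Bonferroni family for contrasts defaults to 21 (one family per
  species) and is exposed as `family_size`, since no canonical family
  is established for this design.

The scale entering the *global* model is genuinely ambiguous in
published practice: per-species z-values, raw μm, or mm. The pipeline
exposes `prescale ∈ {species-z, none, factor:<x>}` and defaults to
`factor:0.001` (mm): the published global table's structure — a
dominant trait term and total SS of order 50 for 1701 observations — is
only consistent with retaining raw between-trait differences on a mm
scale. The design degrees of freedom are invariant to this choice.

Residual homoscedasticity/normality checks are provided as plots only
(residual-vs-fitted, normal Q–Q); nothing is gated on them, mirroring
how such checks are used in practice.

## Neural-network species classifier

Predictors are the 21 raw traits, the 0/1 infection indicator, and the
21 trait × infection products (raw product, then the product column is
z-scaled like every other column) — 43 columns. The network is fixed at
three hidden layers of ten logistic units. Class probabilities are a
softmax over the output pre-activations and training minimises
multiclass cross-entropy by full-batch gradient descent
(backpropagation), with Xavier-uniform initialisation from the run
seed. An earlier variant squashed the output nodes through a logistic
before normalising; that caps every logit difference at 1 (probability
ratios at e) and starves minority classes of gradient — on the default
scenario its training accuracy pinned at the two-largest-class fraction
(64/81) regardless of learning rate. The linear-output softmax head is
the standard pairing with cross-entropy and trains to separation;
hidden nodes remain logistic.

Defaults: learning rate 0.05, up to 5000 epochs, stop when the loss
improves by < 1e-8. All exposed in `NNConfig`. Ties in the argmax break
to the first class in canonical (sorted) label order.

Generalisation is estimated by stratified 10-fold cross-validation:
each class's members are shuffled and dealt round-robin to folds
(per-class fold counts differ by ≤1; classes dealt consecutively keep
total fold sizes balanced). Column z-scaling is refit on the training
rows of every fold; held-out rows never touch the scaling parameters
(asserted by test). Per-fold confusion matrices yield accuracy,
one-vs-rest precision/sensitivity/specificity (macro-averaged by
default; micro available — the published per-fold values do not state
the aggregation), and the multiclass Matthews correlation coefficient
(R_k statistic), which provably reduces to the binary MCC on 2 × 2
matrices (property-tested, and cross-checked against scikit-learn).

## Wild-type reconstruction by distribution mapping

Per species × trait, Gaussian maximum-likelihood moments are estimated
separately for infected (μ_inf, σ_inf) and uninfected (μ_un, σ_un)
specimens: arithmetic mean, SD with divisor n (the ML convention;
divisor n−1 available by config, and the convention used is recorded in
the output so results are self-describing). An infected specimen's
observed value y maps to

    d = (y − μ_inf)/σ_inf,    p = d·σ_un + μ_inf + s,    s = μ_un − μ_inf.

The second form p = d·σ_un + μ_un is algebraically identical; the code
computes both and asserts agreement rather than assuming it. The map is
affine with slope σ_un/σ_inf > 0: ordering within a trait is preserved,
matched moments give the identity map, swapping the two groups' roles
inverts it exactly, and the reconstructed sample's ML mean and SD equal
(μ_un, σ_un) by construction — this moment-transfer identity is
asserted at 1e-9 on every run. Reconstruction is univariate per trait;
no cross-trait covariance mapping is attempted, because the procedure
is defined trait-wise and a multivariate extension would be a different
method. Cells smaller than 5 specimens warn (estimates are noisy) but
proceed, since real infected cells can be as small as 6. Species
without both infected and uninfected reference specimens cannot be
reconstructed — this is a limitation of the method itself, not of the
implementation.

## Ordination

PCA is fitted per species (the published panels are per-species) on the
correlation matrix by default — traits share μm units but span an order
of magnitude. The decomposition is an SVD of the centred/scaled data
with a deterministic sign convention (largest-|loading| entry of each
axis positive), the first two axes retained for plotting. Reconstructed
specimens are projected into the space fitted on observed specimens,
never refitted, so their position is commensurable with the observed
clouds. Uninfected/infected/reconstructed specimens are drawn as
circles, filled triangles and empty triangles respectively.

## Synthetic scenarios

The generator draws, per specimen, a shared log-size factor
ε ~ N(−size_sd²/2, size_sd²) (the offset makes E[m·e^ε] = m exactly),
then per trait value = m·e^ε + noise + infected·δ·σ, with σ the
analytic within-species SD of the uninfected trait
(σ² = m²(e^{size_sd²} − 1) + noise_sd²) so that infection shifts δ are
specified in within-species SD units, directly comparable to the
contrast estimates. The single size factor induces the positive
trait–trait correlation characteristic of linear size measurements; no
free covariance matrix is modelled.

The default scenario fixes the study conditions: three species with
group sizes (uninfected/infected) 20/19, 15/10, 11/6; baseline trait
means at plausible μm values for small myrmicine workers, scaled per
species by near-geometric factors 0.74/0.86/1.00 so adjacent species
are separated by ≥ 6.2 within-species SDs on every trait (measured
against the larger of the two SDs) — the regime in which near-perfect
classification is attainable, as observed in the real system; 2%
shared size variation and 1% measurement noise; infection shifts of
−0.8, −0.5 and +0.6 SD uniform across traits (two species shrink, the
third enlarges). A null variant zeroes the shifts for type-I
calibration.

What the generator does **not** emulate: colony substructure and
relatedness, trait-specific (allometric) infection responses,
non-Gaussian measurement error, parasite load, and any covariance
beyond the single size factor. Passing tests therefore demonstrate the
statistical machinery under the model's own assumptions — they do not
certify performance on real tables, where effects are allometric and
species differ in shape as well as size.

## Numerical and design choices

- Degenerate inputs are typed errors, never coerced: constant traits
  within species (scaling undefined), empty species × infection cells
  (rank-deficient design), cells of <2 specimens (moments undefined),
  zero group SDs (map undefined), classes of <2 members
  (stratification undefined), non-finite training loss (divergence).
- All stochastic stages (generation, fold assignment, weight
  initialisation) are driven by one seed fanned out via fixed offsets;
  reruns are byte-identical.
- CSV output uses `%.17g` so write→read round-trips float64 exactly;
  reading uses round-trip float parsing.
- Problem sizes in the routine checks were chosen to keep a full run on
  a laptop-class single core in minutes: 10 cross-validation seeds of
  the 81-specimen scenario, 500 null replicates for type-I calibration,
  5 replicates at n = 200/cell for contrast recovery, 100 replicates
  (reference n = 2000, test n = 200) for the distributional recovery
  check.

## Known limitations

- Reconstruction assumes within-group normality and a consistent
  (same-direction, same-extent) infection effect; hosts in which
  parasitism inflates variance without shifting the mean violate the
  model and will not be flagged beyond the residual diagnostics.
- The classifier requires a species hypothesis space fixed in advance
  and both phenotypes in training data; it cannot place a specimen of
  an unseen species.
- Bonferroni control is conservative for the 21 correlated traits; no
  FDR alternative is offered because the published workflow is the
  reference point.
- The per-trait interaction tests at the default scenario's moderate
  effect sizes (0.5–0.8 SD) and n = 81 are underpowered after
  adjustment; the global infected:species term carries the pooled
  signal (see example 02).
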