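# Methods

## Scope and data model

The package analyses respiration-chamber balance trials in growing pigs.
Its data model follows the factorial energy-flow bookkeeping: gross energy
intake loses fecal energy (→ DE), urinary and methane energy (→ ME), and
heat increment (→ NE); ME minus total heat production is retained energy
(RE), which splits into protein deposition (PD, derived from nitrogen
retention as NR × 6.25 × 23.86 kJ/g) and lipid deposition (LD = RE − PD).
Internally everything is kept in kJ and kg dry matter; MJ and percentages
appear only at the I/O boundary, because the published tables mix MJ/kg DM
densities with kJ/kg BW^0.6/d rates. All rates are scaled by metabolic body
weight BW^0.6, with the period body weight taken as the arithmetic mean of
the start and end weights (the weighing protocol records days 1/7/13/14 but
no averaging rule; the mean is the neutral choice and is recorded in every
run log).

Heat production uses the Brouwer coefficients 16.18, 5.02, −2.17 kJ/L for
O₂, CO₂, CH₄ and −5.99 kJ/g for urinary N. Trace summaries average
per-interval gas heat within the fed and fasted windows and scale to a
daily rate; the urinary-N term is apportioned uniformly over the day (the
interval-level distribution of urinary N is unobservable, so any other
apportionment would be arbitrary). Traces without a fasted window report
FHP as absent and the caller must supply it. When methane energy is not
measured it is converted from volume at 39.54 kJ/L (standard combustion
value); the factor is written to the run log. Negative digestibilities and
THP below FHP are warned about and carried through unmodified —
auditability of suspect records beats silent repair.

## Difference method and the nested model

A test diet replaces part of the energy-supplying fraction (corn + soybean
meal, r0 = 0.961 of the basal diet) with one nutrient; with r1 the basal
ingredient proportion and r2 the nutrient proportion of the test diet,
nutrient-level values follow from value_j = (value_test − value_basal/r0 ·
r1)/r2. Proportions default to the as-fed basis (the only basis the
formulation table states); a DM basis is available but approximates the
pure nutrients' unknown DM content by the diet's. By default each test pig
is differenced against the basal treatment mean and the per-pig nutrient
values are averaged; a means mode reproduces naive arithmetic on treatment
means.

Two printed-form ambiguities are resolved in favour of internal
consistency, with the literal forms retained as options:

* **kj.** The efficiency of using ME for protein-free NE is defined here
  as kj = PD-free NE/(ME·(1 − pj)) — the division form — because the LD
  identity uses kj·(1 − pj)·ME as the protein-free term; the multiplicative
  reading (kj = PD-free NE/ME·(1 − pj)) is available as
  ``kj_form="printed"``. The two differ by a factor (1 − pj)².
* **Sign of the NE_PD term.** The fitted model is y = x1 − a·x2 − b·x3
  with (y, x1, x2, x3) = (LD, PD-free NE, heat, PD); a positive b = NE_PD
  (an energy *cost* of protein deposition) therefore subtracts. The
  published prediction identity carries a plus sign on that term;
  ``predict_ld`` evaluates it literally, while the fit and the simulator
  use the subtractive convention that yields the conventional positive
  NE_PD. The x2 regressor is FHP by default, THP by option, since the two
  descriptions of the model disagree on this point.

The model is linear in (a, b), so the Newton–Raphson iteration (initial
values a = 1, b = 0.5, at most 1000 iterations, objective-change tolerance
1e-15) reaches the normal-equations solution in one step; the test suite
checks agreement with an independent least-squares oracle to 1e-10 on
random instances, and a property test confirms start-point independence.
Weights are optional and default to none (the weighting of the original
"multivariate weighted–nested regression" is unspecified). Collinear
regressors raise a singular-system error rather than returning a
pseudo-inverse solution silently.

## Identifiability and what the simulator can promise

Because HI, NE, RE, PD-free NE are *defined* through the measured heats,
every diet-level partition satisfies LD = PD-free NE − FHP identically, and
nutrient-level rows obtained by differencing satisfy LD_j = PDfreeNE_j −
c_j·FHP with c_j = (1 − r1/r0)/r2 fixed by the formulation (c ≈ 1.09 for
the starch diets, 1.14 for soybean oil, 0.99 for casein). An arbitrary
joint choice of (pj, K_BR, NE_PD, FHP) therefore cannot be consistent with
the bookkeeping. The trial generator's default mode resolves this by
*deriving* the nutrient protein depositions, PD_j = FHP·(c_j − K_BR)/NE_PD,
which makes the nested model hold exactly through the entire pipeline; the
derived pj are part of the reported ground truth. The derived pj (≈ 0.15
for the starches, 0.20 for oil, 0.04 for casein) are a property of this
construction, not estimates of the real nutrients. Supplying pj explicitly
switches to an accounting-consistent trial in which only pj and kj — not
K_BR/NE_PD — are recoverable. The basal ME→PD efficiency defaults to 0.16,
slightly below the observed diet-level PD/MEI ratio, so that the digestible
nitrogen of the low-protein starch diets can cover the derived deposition;
higher values raise a generation error naming the violated constraint.

## Synthetic data: what it emulates and what it does not

`generate_trial` reproduces the study conditions: six diets (the packaged
formulations), six pigs per diet, initial BW 28.1 ± 0.8 kg (truncated at
±3 sd), feeding level 1.92 MJ ME/kg BW^0.6/d, FHP 840 kJ/kg BW^0.6/d
(mid-range of the treatment means), nutrient kj from the published point
values (0.88/0.80/0.86/0.95/0.68), K_BR = 0.96, NE_PD = 0.35, per-diet
digestibilities and ME/DE ratios at the published treatment means, 5-min
traces over five fed days plus a 96-interval (8 h) fasted window with fed/
fasted respiratory quotients from the published table. Noise is
independent Gaussian per channel, with defaults matched to the published
pooled SEMs (per-pig sd = SEM·√6): fecal/urinary energies and nitrogen,
between-pig THP/FHP, and a small per-interval gas jitter. Gas volumes are
chosen so the Brouwer summary returns the latent heats exactly; before
noise every accounting identity holds to machine precision.

Not emulated: digesta kinetics, diurnal heat rhythms, activity heat,
within-trace autocorrelation, pig-level random effects shared across
diets, and the crossover structure of the real trial. The last two matter:
with SEM-matched *per-channel* noise, differencing by r2 (down to 0.05 for
soybean oil) amplifies regressor noise ~20-fold, and the errors-in-
variables attenuation then overwhelms the nested fit — as it would in a
real completely-randomized design with these SEMs. The published precision
is only achievable because pig effects cancel in the paired design.
Parameter-recovery claims are therefore made at the observation level:
`generate_nested_observations` emulates a 36-pig trial's nutrient rows
(five test diets × six pigs) with per-pig FHP variation (sd = FHP SEM·√6 ≈
118) and Gaussian noise on the response LD (sd = LD SEM·√6 ≈ 42.7). At
that noise level 100-replicate Monte Carlo puts |bias(K_BR)| < 0.02 and
|bias(NE_PD)| < 0.03, and RMSE shrinks as 1/√n across trial sizes.
Passing these tests certifies the estimator under Gaussian response noise;
it does not certify recovery from fully noisy balance channels in a
completely randomized design, which the analysis above shows is not
attainable.

The ingredient-table generator draws covariates from a correlated Gaussian
matched to the packaged 47-ingredient table's sample moments (clipped to
physical ranges) and builds PD/LD from the published headline coefficient
vectors with noise sds equal to their reported RMSEs. Responses are not
clipped at zero so that noise-free fits recover the generating coefficients
exactly; observed tables are nonnegative, and users emulating one should
clip and accept the resulting censoring.

## Regression stage

Pearson correlations use t-distribution p-values with n − 2 df;
zero-variance columns yield flagged NaNs. Forward–backward stepwise
selection adds the candidate with the smallest entry p-value below 0.05,
then drops any included term above 0.05, until no move is possible; ties
break by the table's column order, and an add/remove cycle detector
guarantees termination (at exactly zero residual noise, p-values of
spurious terms are numerically arbitrary). The stepwise fixed point is
cross-checked against an exhaustive enumeration oracle: several fixed
points can coexist (on the packaged table the LD response admits both the
two-term and the five-term published equations), and forward–backward
selection from the empty model reaches the most parsimonious one, which is
what the oracle returns. Metrics follow the Gaussian-likelihood forms
R² = 1 − SSE/SST, RMSE = √(SSE/(n−k−1)), AIC = n·ln(SSE/n) + 2(k+1),
BIC = n·ln(SSE/n) + (k+1)·ln n — constant offsets differ between software
conventions, so only orderings across models on the same data are
meaningful, and tests assert orderings, not absolute values. Validation R²
is the squared Pearson correlation of predicted vs observed on the held-out
30%. The original split membership is unknown, so the split here is a
seeded, documented operation and split-dependent quantities carry loose
tolerances; full-data refits are used where a deterministic comparison is
needed. The model ladder flags as optimal the row that wins the majority
rank over {R²↑, validation R²↑, RMSE↓, AIC↓, BIC↓}, ties to fewer terms.

## Numerical and degenerate-input choices

Rounding for table comparison is half-away-from-zero at the printed
decimals; all programmatic checks compare unrounded values with explicit
tolerances, since treatment-mean rounding alone propagates ±0.02 through
the identities. Perfectly collinear stepwise candidates are dropped
later-ordered-first with a warning. AIC/BIC guard log(0) for exact fits.
The train/valid split requires n ≥ 5 and a fraction strictly inside (0, 1);
correlation needs n ≥ 3 and no missing values. Measured nutrient profiles
whose efficiencies fall outside physical ranges (possible after
high-amplification differencing) are flagged with warnings rather than
rejected, keeping noisy runs auditable.

## Known limitations

* The published nutrient NE values and the K_BR/NE_PD point estimates
  cannot be re-derived from the published treatment means (per-pig
  replicates and the pure nutrients' DM basis are unavailable); the
  corresponding tables ship as reference fixtures only, and the estimator
  is certified by construction-based properties instead.
* Treatment-level ratios (ME/DE, NE/ME) printed in the source tables are
  not always the ratio of the printed means; re-derivations use the cells
  where the two readings agree.
* The DM-basis option for substitution proportions approximates unknown
  pure-nutrient DM contents by the diet's.
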