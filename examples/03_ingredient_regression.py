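"""Predicting protein and lipid deposition from ingredient composition.

Screens the packaged 47-ingredient table for correlations with PD and LD,
then builds the stepwise prediction-equation ladder with a seeded 70/30
train/validation split.
"""

from nepartition import fixtures
from nepartition.regression import correlation_matrix, model_table, stepwise_fit

df = fixtures.ingredient_table()
cm = correlation_matrix(df)
print("r(PD, CP) = %5.2f   r(LD, EE) = %5.2f   r(LD, GE) = %5.2f"
      % (cm[("pd", "cp")], cm[("ld", "ee")], cm[("ld", "ge")]))

m = stepwise_fit(df, "pd", p_enter=0.05, p_remove=0.05)
print("\nstepwise PD model (all 47 rows):", m.equation())

print("\nladder (seed 0, 70/30 split):")
for mod in model_table(df, seed=0):
    flag = "  <- optimal" if mod.optimal else ""
    print(f"  {mod.response.upper()} k={len(mod.terms)}  R2={mod.r2:.3f} "
          f"RMSE={mod.rmse:6.1f}  AIC={mod.aic:6.1f}  valR2={mod.validation_r2:.2f}{flag}")
# Crude protein dominates PD (r ~ 0.92) and enters first with a positive
# coefficient; ether extract and gross energy dominate LD.  The optimal row
# balances fit (R2, validation R2) against the AIC/BIC complexity penalties.
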