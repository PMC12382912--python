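# nepartition

Net-energy partition analysis for growing pigs: energy and nitrogen balance
from indirect calorimetry, single-nutrient energy values and efficiencies by
the difference method with a nested efficiency model, and ingredient-based
prediction of protein and lipid deposition.

The package is aimed at animal-nutrition researchers who work with
respiration-chamber balance trials. It reimplements, as a tested pipeline, a
factorial analysis in which the net energy (NE) of a diet is split into
protein deposition (PD) and lipid deposition (LD), and in which nutrient
monomers (corn/pea/tapioca starch, soybean oil, casein) are characterized by
their chained energy efficiencies.

## The model

All rates are scaled by metabolic body weight, BW^0.6 (kJ/kg BW^0.6/d).
From a balance record and a 5-min chamber gas trace:

    ATTD       = (intake − fecal) / intake
    DE         = GE_i − GE_f,   ME = DE − GE_u − CH4E
    HP         = 16.18·O2 + 5.02·CO2 − 2.17·CH4 − 5.99·urinary N   (Brouwer)
    HI         = THP − FHP,     NE = ME − HI,     RE = ME − THP
    PD         = (N intake − fecal N − urinary N) × 6.25 × 23.86
    PD-free NE = NE − PD,       LD = RE − PD

For a nutrient j substituted into a basal corn–soybean meal diet at
proportions (r0, r1, r2), the difference method isolates its value,

    value_j = (value_test − value_basal/r0 · r1) / r2 ,

and the chained efficiencies are dj = DE_j/GE_j, mj = ME_j/DE_j,
pj = PD_j/ME_j and kj = PD-free NE_j / (ME_j·(1 − pj)). Across nutrients the
nested model

    LD_j = kj·(1 − pj)·ME_j − K_BR·FHP − NE_PD·PD_j

is fitted by Newton–Raphson least squares (initial values a = 1, b = 0.5),
giving K_BR, the efficiency of using body reserves for ATP synthesis during
fasting, and NE_PD, the additional energy cost of protein deposition.

A companion 47-ingredient dataset links ingredient composition (GE, CP, EE,
starch, NDF, ADF, ash) to measured PD and LD through forward–backward
stepwise regression (p = 0.05 entry/removal, seeded 70/30 train/validation
split, R²/RMSE/AIC/BIC model ladder).

Because per-pig replicates for the nutrient experiment were never published,
the package also ships synthetic-trial generators with known ground truth;
parameter recovery on those trials is the acceptance mechanism for the
estimators.

## Worked example

```python
from nepartition.pipeline import analyze_trial
from nepartition.simulate import NoiseSpec, TrialSpec, generate_trial

data = generate_trial(TrialSpec(noise=NoiseSpec.zero(), seed=0))
an = analyze_trial(data.records, data.traces)
print(f"K_BR = {an.fit.k_br:.4f}  NE_PD = {an.fit.ne_pd:.4f}")
```

prints

```
K_BR = 0.9600  NE_PD = 0.3500
```

— the full chain (balance records, Brouwer trace summaries, per-pig
differencing, Newton fit) returns the generator's latent parameters exactly
when noise is off. `examples/` contains one narrative script per
capability; `examples/03_ingredient_regression.py` prints

```
r(PD, CP) =  0.92   r(LD, EE) =  0.93   r(LD, GE) = -0.94
stepwise PD model (all 47 rows): PD = 14.88 + 28.78 x CP - 18.75 x ADF
```

meaning crude protein dominates protein deposition (and enters the stepwise
equation first with a positive sign), while ether extract and gross energy
dominate lipid deposition.

A thin CLI mirrors the stages:
`nepartition {simulate, balance, difference, regress, run}`.

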