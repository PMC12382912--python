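"""Synthetic calorimetry trials and ingredient tables with known ground truth.

Emulates the two experiments the pipeline consumes, so every stage can be
exercised and parameter recovery can be verified without animal data:

* :func:`generate_trial` builds a six-diet trial (basal corn–soybean meal
  diet plus five single-nutrient test diets) with per-pig balance records
  and 5-min chamber gas traces.  The forward model runs the analysis
  equations in reverse: latent nutrient efficiencies determine diet-level
  deposition rates, heat production follows from energy closure, and gas
  volumes are chosen so the Brouwer equation returns the latent heats.
  Before noise, every accounting identity holds exactly.

* :func:`generate_ingredient_table` draws ingredient nutrient profiles from
  a correlated Gaussian model matched to the packaged 47-ingredient table
  and assigns PD/LD from a known linear model plus Gaussian noise.

Identifiability note: because heat increment and retained energy are
*defined* through the measured heats, the diet-level bookkeeping pins
LD = PD-free NE − FHP, and the nutrient-level rows obtained by differencing
satisfy LD_j = PDfreeNE_j − c_j·FHP with c_j = (1 − r1/r0)/r2 fixed by the
formulation.  A free choice of all of (pj, K_BR, NE_PD) cannot be
simultaneously consistent with that bookkeeping, so by default the
generator *derives* the nutrient protein depositions as
PD_j = FHP·(c_j − K_BR)/NE_PD, which makes the nested model hold exactly
through the entire pipeline; the derived pj are reported in the ground
truth.  Supplying ``pj`` explicitly overrides this, after which only pj/kj
(not K_BR/NE_PD) are recoverable from the trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import fixtures
from .balance import (
    CH4_ENERGY_PER_L,
    DEFAULT_BROUWER,
    MINUTES_PER_DAY,
    N_TO_PROTEIN,
    PROTEIN_ENERGY,
    BalanceRecord,
    GasTrace,
)
from .difference import InclusionScheme

__all__ = [
    "GenerationError",
    "NoiseSpec",
    "TrialSpec",
    "TrialTruth",
    "TrialData",
    "IngredientTableSpec",
    "generate_trial",
    "generate_nested_observations",
    "generate_ingredient_table",
]

#: per-pig standard deviations implied by the published pooled SEMs (n=6 per
#: treatment): sd = SEM * sqrt(6).
_SEM_SQRT6 = np.sqrt(6.0)


class GenerationError(ValueError):
    """An infeasible latent combination; the message names the constraint."""


@dataclass(frozen=True)
class NoiseSpec:
    """Per-channel Gaussian noise standard deviations.

    Defaults are matched to the published pooled SEMs (per-pig sd =
    SEM*sqrt(6)): fecal/urinary energies in MJ/d, nitrogen in g/d, heats in
    kJ/kg BW^0.6/d (between-pig), gas jitter in L per 5-min interval.
    """

    fecal_ge_sd: float = 0.16
    urinary_ge_sd: float = 0.05
    fecal_n_sd: float = 0.16 * _SEM_SQRT6
    urinary_n_sd: float = 0.38 * _SEM_SQRT6
    thp_sd: float = 39.03 * _SEM_SQRT6
    fhp_sd: float = 48.16 * _SEM_SQRT6
    gas_jitter_sd: float = 0.02

    def __post_init__(self) -> None:
        for name in ("fecal_ge_sd", "urinary_ge_sd", "fecal_n_sd",
                     "urinary_n_sd", "thp_sd", "fhp_sd", "gas_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseSpec":
        """Noise-free generation (exact identities and round trips)."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    def scaled(self, factor: float) -> "NoiseSpec":
        return NoiseSpec(*(factor * getattr(self, f) for f in (
            "fecal_ge_sd", "urinary_ge_sd", "fecal_n_sd", "urinary_n_sd",
            "thp_sd", "fhp_sd", "gas_jitter_sd")))


#: latent ME -> PD-free NE efficiencies per test diet (published point values).
_DEFAULT_KJ = {"T2": 0.88, "T3": 0.80, "T4": 0.86, "T5": 0.95, "T6": 0.68}


@dataclass
class TrialSpec:
    """Study conditions of a synthetic trial.

    Defaults reproduce the source trial's conditions: 6 pigs per diet,
    initial BW 28.1 +/- 0.8 kg, feeding level 1.92 MJ ME/kg BW^0.6/d,
    fasting heat production 840 kJ/kg BW^0.6/d (mid-range of the treatment
    means), the published diet formulations/substitution schemes, and
    SEM-matched noise.  ``pj=None`` activates the self-consistent mode (see
    module docstring); diet-level digestibilities and ME/DE ratios default
    to the published treatment means.
    """

    n_pigs_per_diet: int = 6
    seed: int = 0
    mei_level: float = 1.92          # MJ ME/kg BW^0.6/d
    fhp: float = 840.0               # kJ/kg BW^0.6/d
    k_br: float = 0.96
    ne_pd: float = 0.35
    kj: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_KJ))
    pj: Mapping[str, float] | None = None
    # basal ME->PD efficiency sits slightly below the observed diet-level
    # PD/MEI ratio so that the low-protein starch diets' digestible N can
    # cover the nutrient PD implied by the self-consistent construction
    basal_pj: float = 0.16
    basal_kj: float = 0.81
    bw_mean: float = 28.1
    bw_sd: float = 0.8
    bw_gain: float = 4.2             # kg over the balance period
    ch4_share: float = 0.2           # share of DE-ME lost as methane
    trace_days: int = 5
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    diets: Mapping[str, object] | None = None
    schemes: Mapping[str, InclusionScheme] | None = None

    def __post_init__(self) -> None:
        if self.n_pigs_per_diet < 1:
            raise ValueError("n_pigs_per_diet must be >= 1")
        for name in ("mei_level", "fhp", "bw_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for d, v in self.kj.items():
            if not 0.0 < v <= 1.0:
                raise GenerationError(f"kj[{d}]={v} must be in (0, 1]")
        if not 0.0 < self.k_br <= 1.5:
            raise GenerationError(f"k_br={self.k_br} outside (0, 1.5]")
        if self.ne_pd <= 0:
            raise GenerationError(f"ne_pd={self.ne_pd} must be > 0")
        if not 0.0 <= self.ch4_share < 1.0:
            raise ValueError("ch4_share must be in [0, 1)")


@dataclass
class NutrientTruth:
    """Latent nutrient-level values (rates on the kJ/kg BW^0.6/d scale)."""

    nutrient: str
    diet: str
    c: float                         # (1 - r1/r0)/r2
    me_rate: float
    pd: float
    pj: float
    kj: float
    pd_free_ne: float
    ld: float


@dataclass
class DietTruth:
    """Latent diet-level partition rates, kJ/kg BW^0.6/d."""

    diet: str
    mei: float
    pd: float
    ld: float
    re: float
    thp: float
    fhp: float
    hi: float
    ne: float
    pd_free_ne: float


@dataclass
class TrialTruth:
    k_br: float
    ne_pd: float
    fhp: float
    mei: float
    diets: dict[str, DietTruth]
    nutrients: dict[str, NutrientTruth]
    pigs: pd.DataFrame

    def nested_observations(self) -> np.ndarray:
        """Latent nutrient rows as (LD, PD-free NE, FHP, PD) fit input."""
        rows = [
            (t.ld, t.pd_free_ne, self.fhp, t.pd)
            for t in self.nutrients.values()
        ]
        return np.array(rows, dtype=float)


@dataclass
class TrialData:
    records: list[BalanceRecord]
    traces: dict[str, GasTrace]
    truth: TrialTruth


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws truncated at +/- 3 sd (redrawn, not clipped)."""
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = np.abs(out - mean) > 3 * sd
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = np.abs(out - mean) > 3 * sd
    return out


def _diet_defaults() -> tuple[pd.DataFrame, pd.DataFrame]:
    dig = fixtures.digestibility_nitrogen_table().set_index("diet")
    eb = fixtures.energy_balance_table().set_index("diet")
    return dig, eb


def _latent_structure(spec: TrialSpec) -> tuple[dict[str, DietTruth], dict[str, NutrientTruth]]:
    schemes = dict(spec.schemes) if spec.schemes is not None else fixtures.inclusion_schemes()
    mei = spec.mei_level * 1000.0
    fhp = spec.fhp

    # basal diet
    pd0 = spec.basal_pj * mei
    pdfree0 = spec.basal_kj * (1.0 - spec.basal_pj) * mei
    ld0 = pdfree0 - fhp
    if ld0 <= 0:
        raise GenerationError(
            f"basal LD = {ld0:.1f} <= 0: basal_kj/basal_pj/fhp imply negative lipid deposition"
        )
    diets: dict[str, DietTruth] = {}

    def close(diet: str, pd_i: float, ld_i: float) -> DietTruth:
        re = pd_i + ld_i
        thp = mei - re
        if thp < fhp:
            raise GenerationError(
                f"{diet}: implied THP {thp:.1f} < FHP {fhp:.1f} (deposition too high)"
            )
        hi = thp - fhp
        ne = mei - hi
        return DietTruth(diet=diet, mei=mei, pd=pd_i, ld=ld_i, re=re, thp=thp,
                         fhp=fhp, hi=hi, ne=ne, pd_free_ne=ne - pd_i)

    diets[fixtures.BASAL_DIET] = close(fixtures.BASAL_DIET, pd0, ld0)

    nutrients: dict[str, NutrientTruth] = {}
    for diet, nutrient in fixtures.TEST_NUTRIENTS.items():
        if diet not in spec.kj:
            continue
        scheme = schemes[diet]
        c = scheme.dilution
        me_j = c * mei
        kj = spec.kj[diet]
        if spec.pj is None:
            pd_j = fhp * (c - spec.k_br) / spec.ne_pd
            if not 0.0 <= pd_j < me_j:
                raise GenerationError(
                    f"{diet}: derived PD_j = {pd_j:.1f} outside [0, ME_j={me_j:.1f}); "
                    f"c={c:.4f} vs K_BR={spec.k_br} incompatible"
                )
            pj = pd_j / me_j
        else:
            pj = float(spec.pj[diet])
            if not 0.0 <= pj < 1.0:
                raise GenerationError(f"{diet}: pj={pj} outside [0, 1)")
            pd_j = pj * me_j
        pdfree_j = kj * (1.0 - pj) * me_j
        # accounting-consistent nutrient LD (equals the nested-model value
        # exactly in the derived-pj mode)
        ld_j = pdfree_j - c * fhp
        if ld_j <= 0:
            raise GenerationError(
                f"{diet}: implied nutrient LD = {ld_j:.1f} <= 0 (kj too low for FHP)"
            )
        nutrients[diet] = NutrientTruth(
            nutrient=nutrient, diet=diet, c=c, me_rate=me_j, pd=pd_j, pj=pj,
            kj=kj, pd_free_ne=pdfree_j, ld=ld_j,
        )
        # forward mixture to the diet level
        frac = scheme.r1 / scheme.r0
        pd_i = pd0 * frac + pd_j * scheme.r2
        ld_i = ld0 * frac + ld_j * scheme.r2
        diets[diet] = close(diet, pd_i, ld_i)
    return diets, nutrients


def _make_trace(
    pig_id: str,
    thp_d: float,
    fhp_d: float,
    urinary_n: float,
    ch4_vol_d: float,
    rq_fed: float,
    rq_fasted: float,
    trace_days: int,
    jitter_sd: float,
    rng: np.random.Generator,
) -> GasTrace:
    """Gas trace whose Brouwer summary returns the target daily heats."""
    spd = MINUTES_PER_DAY / 5.0
    n_fed = int(trace_days * spd)
    n_fasted = 96                                 # 22:30-06:30 at 5-min steps
    c = DEFAULT_BROUWER

    v_ch4 = ch4_vol_d / spd
    gas_fed = (thp_d - c.c_un * urinary_n) / spd - c.c_ch4 * v_ch4
    o2_fed = gas_fed / (c.c_o2 + c.c_co2 * rq_fed)
    gas_fast = (fhp_d - c.c_un * urinary_n) / spd
    o2_fast = gas_fast / (c.c_o2 + c.c_co2 * rq_fasted)
    if o2_fed <= 0 or o2_fast <= 0:
        raise GenerationError(f"{pig_id}: implied O2 consumption <= 0")

    o2 = np.concatenate([np.full(n_fed, o2_fed), np.full(n_fasted, o2_fast)])
    co2 = np.concatenate([
        np.full(n_fed, rq_fed * o2_fed), np.full(n_fasted, rq_fasted * o2_fast)
    ])
    ch4 = np.concatenate([np.full(n_fed, v_ch4), np.zeros(n_fasted)])
    fed = np.concatenate([np.ones(n_fed, bool), np.zeros(n_fasted, bool)])
    if jitter_sd > 0:
        o2 = np.clip(o2 + rng.normal(0, jitter_sd, o2.shape), 0, None)
        co2 = np.clip(co2 + rng.normal(0, jitter_sd, co2.shape), 0, None)
    t = 5.0 * np.arange(n_fed + n_fasted)
    return GasTrace(pig_id=pig_id, time_min=t, o2=o2, co2=co2, ch4=ch4, fed=fed)


def generate_trial(spec: TrialSpec) -> TrialData:
    """Simulate one balance/calorimetry trial with known ground truth.

    Returns per-pig :class:`~nepartition.balance.BalanceRecord` and
    :class:`~nepartition.balance.GasTrace` objects plus a
    :class:`TrialTruth` carrying every latent value.  With
    ``spec.noise = NoiseSpec.zero()`` the analysis pipeline reproduces the
    latent partition exactly; with the default SEM-matched noise it emulates
    the published between-pig variability.
    """
    rng = np.random.default_rng(spec.seed)
    diets_truth, nutrients_truth = _latent_structure(spec)
    forms = dict(spec.diets) if spec.diets is not None else fixtures.diet_formulations()
    dig, eb = _diet_defaults()
    noise = spec.noise
    mei = spec.mei_level * 1000.0

    records: list[BalanceRecord] = []
    traces: dict[str, GasTrace] = {}
    pig_rows = []
    for diet in sorted(diets_truth):
        dt = diets_truth[diet]
        form = forms[diet]
        attd_ge = dig.loc[diet, "attd_ge"] / 100.0
        attd_cp = dig.loc[diet, "attd_cp"] / 100.0
        me_de = eb.loc[diet, "me_de"] / 100.0
        rq_fed = eb.loc[diet, "rq_fed"]
        rq_fasted = eb.loc[diet, "rq_fasted"]

        bw0 = _truncnorm(rng, spec.bw_mean, spec.bw_sd, spec.n_pigs_per_diet)
        for i in range(spec.n_pigs_per_diet):
            pig_id = f"{diet}-p{i + 1}"
            bw_start = float(bw0[i])
            bw_end = bw_start + spec.bw_gain
            w = (0.5 * (bw_start + bw_end)) ** 0.6

            thp_rate = dt.thp + float(rng.normal(0, noise.thp_sd)) if noise.thp_sd else dt.thp
            fhp_rate = dt.fhp + float(rng.normal(0, noise.fhp_sd)) if noise.fhp_sd else dt.fhp

            me_d = mei * w / 1000.0                       # MJ/d
            de_d = me_d / me_de
            ge_d = de_d / attd_ge
            fecal_true = ge_d - de_d
            loss = de_d - me_d
            ch4_e = spec.ch4_share * loss
            urinary_true = loss - ch4_e
            dmi = ge_d / form.ge_dm

            nr_d = dt.pd * w / (N_TO_PROTEIN * PROTEIN_ENERGY)
            n_intake = form.nutrient_dm("cp") / 100.0 * dmi * 1000.0 / N_TO_PROTEIN
            fecal_n_true = (1.0 - attd_cp) * n_intake
            urinary_n_true = n_intake - fecal_n_true - nr_d
            if urinary_n_true < 0:
                raise GenerationError(
                    f"{pig_id}: implied urinary N {urinary_n_true:.2f} g/d < 0 "
                    f"(latent PD exceeds digestible N intake)"
                )

            fecal_ge = max(0.0, fecal_true + float(rng.normal(0, noise.fecal_ge_sd))) if noise.fecal_ge_sd else fecal_true
            urinary_ge = max(0.0, urinary_true + float(rng.normal(0, noise.urinary_ge_sd))) if noise.urinary_ge_sd else urinary_true
            fecal_n = max(0.0, fecal_n_true + float(rng.normal(0, noise.fecal_n_sd))) if noise.fecal_n_sd else fecal_n_true
            urinary_n = max(0.0, urinary_n_true + float(rng.normal(0, noise.urinary_n_sd))) if noise.urinary_n_sd else urinary_n_true

            rec = BalanceRecord(
                pig_id=pig_id, diet_id=diet, dmi=dmi,
                ge_intake=ge_d, fecal_ge=fecal_ge, urinary_ge=urinary_ge,
                ch4_energy=ch4_e, n_intake=n_intake, fecal_n=fecal_n,
                urinary_n=urinary_n, bw_start=bw_start, bw_end=bw_end,
            )
            records.append(rec)
            traces[pig_id] = _make_trace(
                pig_id, thp_rate * w, fhp_rate * w, urinary_n,
                ch4_e * 1000.0 / CH4_ENERGY_PER_L, rq_fed, rq_fasted,
                spec.trace_days, noise.gas_jitter_sd, rng,
            )
            pig_rows.append({
                "pig_id": pig_id, "diet": diet, "bw_start": bw_start,
                "bw_end": bw_end, "metabolic_bw": w,
                "thp_rate": thp_rate, "fhp_rate": fhp_rate,
            })

    truth = TrialTruth(
        k_br=spec.k_br, ne_pd=spec.ne_pd, fhp=spec.fhp, mei=mei,
        diets=diets_truth, nutrients=nutrients_truth,
        pigs=pd.DataFrame(pig_rows),
    )
    return TrialData(records=records, traces=traces, truth=truth)


def generate_nested_observations(
    n_pigs: int = 36,
    spec: TrialSpec | None = None,
    fhp_sd: float = 48.16 * _SEM_SQRT6,
    ld_noise_sd: float = 17.44 * _SEM_SQRT6,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, float]]:
    """Nutrient-level observations for the nested fit, with known truth.

    Emulates the estimator's input in a trial of ``n_pigs`` pigs (one sixth
    on the basal diet): each test pig contributes one nutrient-level row
    (LD, PD-free NE, FHP, PD) built from the trial's latent structure, with
    the pig's fasting heat production varying around the mean (sd matched
    to the published FHP SEM) and Gaussian noise on the response LD (sd
    matched to the published LD SEM, both on the per-pig scale).  Returns
    the (n, 4) array and the generating parameters.
    """
    if n_pigs % 6 != 0 or n_pigs < 6:
        raise ValueError("n_pigs must be a positive multiple of 6")
    spec = spec or TrialSpec()
    rng = np.random.default_rng(seed)
    _, nutrients = _latent_structure(spec)
    per_diet = n_pigs // 6
    rows = []
    for diet in sorted(nutrients):
        t = nutrients[diet]
        for _ in range(per_diet):
            fhp_k = float(_truncnorm(rng, spec.fhp, fhp_sd, 1)[0])
            pdfree = t.kj * (1.0 - t.pj) * t.me_rate
            ld = pdfree - spec.k_br * fhp_k - spec.ne_pd * t.pd
            ld += float(rng.normal(0.0, ld_noise_sd)) if ld_noise_sd else 0.0
            rows.append((ld, pdfree, fhp_k, t.pd))
    truth = {"k_br": spec.k_br, "ne_pd": spec.ne_pd, "fhp": spec.fhp}
    return np.array(rows, dtype=float), truth


@dataclass
class IngredientTableSpec:
    """Generative model for a synthetic ingredient deposition table.

    Covariates (ge, cp, ee, starch, ndf, adf, ash) are drawn from a
    correlated Gaussian matched by default to the packaged 47-ingredient
    table's sample moments and clipped to their physical ranges; PD and LD
    are linear in the covariates plus Gaussian noise.  Default coefficient
    vectors are the published headline prediction equations, with noise sds
    equal to their reported RMSEs.  Generated PD/LD are *not* clipped at
    zero (exact noise-free recovery requires the unclipped response);
    observed tables are nonnegative.
    """

    n: int = 47
    means: Mapping[str, float] | None = None
    sds: Mapping[str, float] | None = None
    corr: np.ndarray | None = None
    coef_pd: Mapping[str, float] = field(default_factory=lambda: {
        "intercept": 364.36, "ge": -18.44, "cp": 29.10, "ee": -3.79, "adf": -21.37,
    })
    coef_ld: Mapping[str, float] = field(default_factory=lambda: {
        "intercept": -1503.50, "cp": 21.58, "ee": 51.98, "starch": 26.30,
        "ndf": 26.81, "adf": -23.87,
    })
    noise_sd_pd: float = 105.15
    noise_sd_ld: float = 172.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if self.noise_sd_pd < 0 or self.noise_sd_ld < 0:
            raise ValueError("noise sds must be >= 0")


_COVS = ("ge", "cp", "ee", "starch", "ndf", "adf", "ash")


def generate_ingredient_table(
    spec: IngredientTableSpec,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Draw a synthetic ingredient table; returns (table, generating coefficients)."""
    ref = fixtures.ingredient_table()
    means = dict(spec.means) if spec.means else {c: float(ref[c].mean()) for c in _COVS}
    sds = dict(spec.sds) if spec.sds else {c: float(ref[c].std(ddof=1)) for c in _COVS}
    if spec.corr is not None:
        corr = np.asarray(spec.corr, dtype=float)
    else:
        corr = ref[list(_COVS)].corr().to_numpy()
    if corr.shape != (len(_COVS), len(_COVS)):
        raise GenerationError(f"correlation matrix must be {len(_COVS)}x{len(_COVS)}")
    eig = np.linalg.eigvalsh((corr + corr.T) / 2.0)
    if eig.min() < -1e-8:
        raise GenerationError(
            f"correlation matrix is not positive semi-definite (min eig {eig.min():.3g})"
        )

    rng = np.random.default_rng(spec.seed)
    d = np.array([sds[c] for c in _COVS])
    cov = corr * np.outer(d, d)
    # tiny ridge keeps the Cholesky of a PSD-but-singular matrix defined
    X = rng.multivariate_normal([means[c] for c in _COVS], cov + 1e-10 * np.eye(len(_COVS)),
                                size=spec.n, method="cholesky")
    df = pd.DataFrame(X, columns=list(_COVS))
    df["ge"] = df["ge"].clip(lower=0.0)
    for c in _COVS[1:]:
        df[c] = df[c].clip(0.0, 100.0)

    def response(coef: Mapping[str, float], sd: float) -> np.ndarray:
        y = np.full(spec.n, coef.get("intercept", 0.0))
        for c, b in coef.items():
            if c != "intercept":
                y = y + b * df[c].to_numpy()
        if sd:
            y = y + rng.normal(0.0, sd, size=spec.n)
        return y

    df["pd"] = response(spec.coef_pd, spec.noise_sd_pd)
    df["ld"] = response(spec.coef_ld, spec.noise_sd_ld)
    df.insert(0, "name", [f"synthetic-{i + 1}" for i in range(spec.n)])
    truth = {"pd": dict(spec.coef_pd), "ld": dict(spec.coef_ld)}
    return df, truth
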