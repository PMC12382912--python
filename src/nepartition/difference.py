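"""Single-nutrient energy values and efficiencies by the difference method.

A test diet replaces a fixed share of the energy-supplying fraction of a
basal (corn–soybean meal) diet with one nutrient.  Differencing the two diet
values isolates the nutrient's own energy value:

    value_j = (value_test - value_basal / r0 * r1) / r2

with r0 the energy-supplying fraction of the basal diet, r1 the basal
ingredient proportion of the test diet and r2 the tested-nutrient proportion.
Chained efficiencies dj = DE/GE, mj = ME/DE, pj = PD/ME and kj (ME to
protein-free net energy) then describe the nutrient, and the nested model

    LD = kj*(1 - pj)*ME - K_BR*x2 - NE_PD*PD

estimated across nutrients yields K_BR, the efficiency of using body
reserves for ATP synthesis during fasting, and NE_PD, the additional energy
cost coefficient of protein deposition.  x2 is fasting heat production by
default (total heat production optionally).

Note on conventions: the published form of the prediction identity carries a
plus sign on the NE_PD term while the fitted model subtracts it; the fit and
the simulator use the subtractive (internally consistent) convention, which
yields the conventional positive NE_PD, and :func:`predict_ld` evaluates the
published identity literally.  The published kj definition multiplies by
(1 - pj); the default here divides, which makes the kj and LD equations
mutually consistent — the multiplicative form remains available via
``kj_form="printed"``.
"""

from __future__ import annotations

import warnings
from dataclasses import InitVar, dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np

__all__ = [
    "InclusionScheme",
    "NutrientEnergyProfile",
    "NestedFitResult",
    "SingularSystemError",
    "Efficiencies",
    "nutrient_energy",
    "efficiencies",
    "fit_kbr_nepd",
    "predict_ld",
    "profiles_from_partitions",
]


class SingularSystemError(np.linalg.LinAlgError):
    """The nested-model normal equations are singular (collinear regressors)."""


@dataclass(frozen=True)
class InclusionScheme:
    """Substitution proportions of one basal/test diet pair (fractions).

    ``r0``: energy-supplying fraction of the basal diet; ``r1``: basal
    ingredient proportion in the test diet; ``r2``: tested-nutrient
    proportion in the test diet.  ``basis`` records whether the proportions
    are on the as-fed or the dry-matter basis.
    """

    r0: float
    r1: float
    r2: float
    basis: Literal["as_fed", "dm"] = "as_fed"

    def __post_init__(self) -> None:
        if not 0.0 < self.r0 <= 1.0:
            raise ValueError(f"r0={self.r0} must be in (0, 1]")
        if not 0.0 < self.r2 <= 1.0:
            raise ValueError(f"r2={self.r2} must be in (0, 1]")
        if not 0.0 <= self.r1 < 1.0:
            raise ValueError(f"r1={self.r1} must be in [0, 1)")
        if self.r1 + self.r2 > 1.0 + 1e-9:
            raise ValueError(f"r1 + r2 = {self.r1 + self.r2} exceeds 1")

    @property
    def dilution(self) -> float:
        """(1 - r1/r0)/r2 — the factor linking diet-level and nutrient-level rates."""
        return (1.0 - self.r1 / self.r0) / self.r2


@dataclass
class NutrientEnergyProfile:
    """Energy densities and efficiencies of one nutrient.

    Densities in MJ/kg DM; deposition rates in kJ/kg BW^0.6/d; efficiencies
    are fractions.  dj/mj may slightly exceed 1 under measurement noise.
    Construction validates the physical ranges; ``check=False`` downgrades
    violations to warnings (used when noisy measured values are carried
    through for audit rather than rejected).
    """

    nutrient: str
    ge: float = float("nan")
    de: float = float("nan")
    me: float = float("nan")
    ne: float = float("nan")
    dj: float = float("nan")
    mj: float = float("nan")
    pj: float = float("nan")
    kj: float = float("nan")
    pd: float = float("nan")
    pd_free_ne: float = float("nan")
    ld: float = float("nan")
    me_rate: float = float("nan")
    check: InitVar[bool] = True

    def __post_init__(self, check: bool) -> None:
        problems = []
        for name, hi in (("dj", 1.05), ("mj", 1.05)):
            v = getattr(self, name)
            if np.isfinite(v) and not 0.0 <= v <= hi:
                problems.append(f"{name}={v} outside [0, {hi}]")
        if np.isfinite(self.pj) and not 0.0 <= self.pj < 1.0:
            problems.append(f"pj={self.pj} outside [0, 1)")
        if np.isfinite(self.kj) and self.kj <= 0.0:
            problems.append(f"kj={self.kj} must be > 0")
        if problems:
            msg = f"{self.nutrient}: " + "; ".join(problems)
            if check:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=3)


@dataclass
class NestedFitResult:
    """Estimates of the nested energy-partition model.

    ``k_br`` (a) multiplies the heat regressor, ``ne_pd`` (b) the protein
    deposition regressor in LD = PDfreeNE - a*x2 - b*PD.
    """

    k_br: float
    ne_pd: float
    residuals: np.ndarray
    iterations: int
    converged: bool
    sse: float


class Efficiencies(NamedTuple):
    dj: float
    mj: float
    pj: float
    kj: float


def nutrient_energy(test: float, basal: float, scheme: InclusionScheme) -> float:
    """Energy value of the tested nutrient by the difference method.

    Evaluates (test - basal/r0 * r1) / r2 (left-to-right, i.e. the basal
    value is first rescaled to the energy-supplying fraction).  Applies to
    any additive diet quantity: MJ/kg DM densities or kJ/kg BW^0.6/d rates.
    """
    if scheme.r2 == 0:
        raise ValueError("r2 must be nonzero")
    return (test - basal / scheme.r0 * scheme.r1) / scheme.r2


def efficiencies(
    ge: float,
    de: float,
    me: float,
    pd: float,
    pd_free_ne: float,
    me_rate: float | None = None,
    kj_form: Literal["consistent", "printed"] = "consistent",
) -> Efficiencies:
    """Chained energy efficiencies of one nutrient.

    ``ge``/``de``/``me`` are densities (MJ/kg DM); ``pd``/``pd_free_ne`` are
    rates on the kJ/kg BW^0.6/d scale and are related to ME through
    ``me_rate``, the nutrient's ME intake on the same scale (defaults to
    ``me`` — valid when all quantities share one scale).

    kj defaults to PD-free NE/(ME*(1-pj)), the form consistent with the LD
    identity; ``kj_form="printed"`` uses PD-free NE/ME*(1-pj).
    """
    if ge <= 0 or de <= 0 or me <= 0:
        raise ValueError("ge, de and me must be > 0")
    me_r = me if me_rate is None else me_rate
    if me_r <= 0:
        raise ValueError("me_rate must be > 0")
    dj = de / ge
    mj = me / de
    pj = pd / me_r
    if pj >= 1.0:
        raise ValueError(f"pj={pj} >= 1: kj undefined")
    if kj_form == "consistent":
        kj = pd_free_ne / (me_r * (1.0 - pj))
    elif kj_form == "printed":
        kj = pd_free_ne / me_r * (1.0 - pj)
    else:
        raise ValueError(f"unknown kj_form {kj_form!r}")
    return Efficiencies(dj=dj, mj=mj, pj=pj, kj=kj)


def _design(obs: np.ndarray, weights: np.ndarray | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    obs = np.asarray(obs, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 4:
        raise ValueError("obs must be an (n, 4) array of (ld, pd_free_ne, x2, pd)")
    if obs.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    y = obs[:, 1] - obs[:, 0]          # pd_free_ne - ld = a*x2 + b*pd
    X = obs[:, 2:4]
    if weights is None:
        w = np.ones(len(y))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape or np.any(w < 0):
            raise ValueError("weights must be a nonnegative vector matching obs")
    return X, y, w


def fit_kbr_nepd(
    obs: Sequence[Sequence[float]] | np.ndarray,
    init: tuple[float, float] = (1.0, 0.5),
    tol: float = 1e-15,
    max_iter: int = 1000,
    weights: Sequence[float] | None = None,
) -> NestedFitResult:
    """Estimate K_BR and NE_PD from nutrient-level partition observations.

    ``obs`` rows are (LD, PD-free NE, x2, PD) on the kJ/kg BW^0.6/d scale,
    where x2 is fasting (or total) heat production.  The model
    y = x1 - a*x2 - b*x3 is fitted by least squares via Newton–Raphson
    from ``init`` (defaults a=1, b=0.5); because the model is linear in
    (a, b) the iteration reaches the normal-equations solution in one step,
    which property tests exploit.  Optional nonnegative per-observation
    weights give weighted least squares.

    Raises :class:`SingularSystemError` when (x2, x3) are collinear.
    """
    X, y, w = _design(np.asarray(obs), None if weights is None else np.asarray(weights))
    theta = np.asarray(init, dtype=float)

    def sse(t: np.ndarray) -> float:
        r = y - X @ t
        return float(np.sum(w * r * r))

    hess = 2.0 * (X.T * w) @ X           # constant: model is linear in (a, b)
    if np.linalg.matrix_rank(hess) < 2 or np.linalg.cond(hess) > 1e12:
        raise SingularSystemError("x2 and pd regressors are collinear")

    converged = False
    prev = sse(theta)
    it = 0
    for it in range(1, max_iter + 1):
        grad = -2.0 * X.T @ (w * (y - X @ theta))
        step = np.linalg.solve(hess, grad)
        theta = theta - step
        cur = sse(theta)
        if abs(prev - cur) <= tol * max(1.0, abs(prev)):
            converged = True
            break
        prev = cur
    resid = y - X @ theta
    return NestedFitResult(
        k_br=float(theta[0]),
        ne_pd=float(theta[1]),
        # residuals on the LD scale: observed LD minus model LD
        residuals=-resid,
        iterations=it,
        converged=converged,
        sse=sse(theta),
    )


def predict_ld(
    profile: NutrientEnergyProfile,
    fhp: float,
    fit: NestedFitResult,
) -> float:
    """Lipid deposition from the published identity, kJ/kg BW^0.6/d.

    Evaluates kj*(1 - pj)*ME - K_BR*FHP + NE_PD*PD exactly as published
    (note the plus sign on the NE_PD term; see the module docstring).
    ``profile.me_rate`` is used when set, otherwise ``profile.me``.
    """
    if not fit.converged:
        raise ValueError("nested fit did not converge")
    me = profile.me_rate if np.isfinite(profile.me_rate) else profile.me
    return (
        profile.kj * (1.0 - profile.pj) * me
        - fit.k_br * fhp
        + fit.ne_pd * profile.pd
    )


def profiles_from_partitions(
    basal,
    tests: dict[str, Sequence],
    schemes: dict[str, InclusionScheme],
    kj_form: Literal["consistent", "printed"] = "consistent",
    mode: Literal["per_pig", "means"] = "per_pig",
    nutrient_ge: dict[str, float] | None = None,
) -> dict[str, NutrientEnergyProfile]:
    """Build nutrient profiles by differencing diet-level partitions.

    ``basal`` is a sequence of :class:`~nepartition.balance.EnergyPartition`
    for the basal diet; ``tests`` maps nutrient name to the partitions of the
    corresponding test diet; ``schemes`` supplies the substitution
    proportions.  With ``mode="per_pig"`` each test pig is differenced
    against the basal treatment mean and per-pig nutrient values are then
    averaged; ``mode="means"`` differences the treatment means directly
    (naive arithmetic on table means).  ``nutrient_ge`` carries the bomb
    calorimetry GE of each pure nutrient (MJ/kg DM), which cannot be
    obtained by differencing; when present it fills ge and dj.
    """
    def col(parts, name):
        return np.array([getattr(p, name) for p in parts], dtype=float)

    basal_mean = {k: float(np.mean(col(basal, k))) for k in
                  ("mei", "pd", "ld", "pd_free_ne", "de_density", "me_density",
                   "ne_density", "fhp")}
    out: dict[str, NutrientEnergyProfile] = {}
    for nutrient, parts in tests.items():
        scheme = schemes[nutrient]

        def diff(name: str) -> float:
            b = basal_mean[name]
            if mode == "per_pig":
                vals = [nutrient_energy(v, b, scheme) for v in col(parts, name)]
                return float(np.mean(vals))
            return nutrient_energy(float(np.mean(col(parts, name))), b, scheme)

        me_rate = diff("mei")
        pd = diff("pd")
        ld = diff("ld")
        pdfree = diff("pd_free_ne")
        de = diff("de_density")
        me = diff("me_density")
        ne = diff("ne_density")
        pj = pd / me_rate
        if kj_form == "consistent":
            kj = pdfree / (me_rate * (1.0 - pj))
        else:
            kj = pdfree / me_rate * (1.0 - pj)
        ge_j = float("nan")
        dj = float("nan")
        if nutrient_ge and nutrient in nutrient_ge:
            ge_j = float(nutrient_ge[nutrient])
            if ge_j > 0:
                dj = de / ge_j
        out[nutrient] = NutrientEnergyProfile(
            nutrient=nutrient,
            ge=ge_j, de=de, me=me, ne=ne,
            dj=dj, mj=me / de if de else float("nan"),
            pj=pj, kj=kj,
            pd=pd, pd_free_ne=pdfree, ld=ld,
            me_rate=me_rate,
            check=False,  # measured values are flagged, not rejected
        )
    return out
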