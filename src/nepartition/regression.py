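"""Correlation screening and stepwise regression of deposition on nutrients.

Predicts protein deposition (PD) and lipid deposition (LD, kJ/kg BW^0.6/d)
of growing pigs from ingredient nutrient characteristics (GE and the
proximate fractions CP, EE, starch, NDF, ADF, ash).  Pearson correlations
identify candidate predictors; forward–backward stepwise selection with a
p-value stopping rule (0.05 for both entry and removal) builds the
prediction equations, reported with R², RMSE, AIC, BIC and a held-out
validation R² from a seeded 70/30 split.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "COVARIATES",
    "RESPONSES",
    "IngredientRecord",
    "CorrelationMatrix",
    "RegressionModel",
    "correlation_matrix",
    "split_train_valid",
    "stepwise_fit",
    "model_metrics",
    "model_table",
    "best_subset_fit",
]

#: candidate predictors, in table column order (ties break by this order).
COVARIATES = ("ge", "cp", "ee", "starch", "ndf", "adf", "ash")
RESPONSES = ("pd", "ld")


@dataclass
class IngredientRecord:
    """One ingredient: proximate composition and measured deposition.

    ``ge`` in MJ/kg; composition in %; ``pd``/``ld`` in kJ/kg BW^0.6/d.
    """

    name: str
    ge: float
    cp: float
    ee: float
    starch: float
    ndf: float
    adf: float
    ash: float
    pd: float
    ld: float
    category: str = ""

    def __post_init__(self) -> None:
        if self.ge < 0:
            raise ValueError(f"{self.name}: ge must be >= 0")
        for nm in ("cp", "ee", "starch", "ndf", "adf", "ash"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{self.name}: {nm}={v} outside [0, 100] %")
        if self.pd < 0 or self.ld < 0:
            raise ValueError(f"{self.name}: pd and ld must be >= 0")


def records_to_frame(records: Iterable[IngredientRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r and two-sided p-values over named columns."""

    labels: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    degenerate: tuple[str, ...] = ()

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.r.loc[a, b])


@dataclass
class RegressionModel:
    """A fitted linear prediction equation for PD or LD."""

    response: str
    terms: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    r2: float = float("nan")
    rmse: float = float("nan")
    aic: float = float("nan")
    bic: float = float("nan")
    validation_r2: float = float("nan")
    n_train: int = 0
    n_valid: int = 0
    pvalues: dict[str, float] = field(default_factory=dict)
    optimal: bool = False

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        out = np.full(len(data), self.intercept, dtype=float)
        for t in self.terms:
            out += self.coefficients[t] * data[t].to_numpy(dtype=float)
        return out

    def equation(self) -> str:
        parts = [f"{self.response.upper()} = {self.intercept:.2f}"]
        for t in self.terms:
            c = self.coefficients[t]
            parts.append(f"{'-' if c < 0 else '+'} {abs(c):.2f} x {t.upper()}")
        return " ".join(parts)


def correlation_matrix(records, columns: Sequence[str] | None = None) -> CorrelationMatrix:
    """Pearson correlations (with t-distribution p-values, n-2 df).

    Zero-variance columns yield undefined (NaN) correlations and are listed
    in ``degenerate`` with a warning rather than dropped silently.
    """
    df = _as_frame(records)
    if columns is None:
        columns = [c for c in (*COVARIATES, *RESPONSES) if c in df.columns]
    df = df[list(columns)].astype(float)
    n = len(df)
    if n < 3:
        raise ValueError(f"need at least 3 records, got {n}")
    if df.isna().any().any():
        raise ValueError("missing values are not allowed")

    degenerate = tuple(c for c in columns if df[c].std(ddof=1) == 0.0)
    if degenerate:
        warnings.warn(f"zero-variance columns: {degenerate}", stacklevel=2)

    r = df.corr(method="pearson")
    with np.errstate(divide="ignore", invalid="ignore"):
        rv = r.to_numpy(copy=True)
        t = rv * np.sqrt((n - 2) / (1.0 - rv**2))
        pv = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(pv, 0.0)
    p = pd.DataFrame(pv, index=r.index, columns=r.columns)
    return CorrelationMatrix(labels=tuple(columns), r=r, p=p, degenerate=degenerate)


def split_train_valid(
    records, fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded disjoint train/validation split; train size = round(fraction*n)."""
    df = _as_frame(records)
    n = len(df)
    if n < 5:
        raise ValueError(f"need at least 5 records to split, got {n}")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction={fraction} must be in (0, 1)")
    n_train = int(round(fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"fraction={fraction} leaves an empty subset at n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return df.iloc[np.sort(order[:n_train])], df.iloc[np.sort(order[n_train:])]


def _ols(df: pd.DataFrame, response: str, terms: Sequence[str]):
    X = sm.add_constant(df[list(terms)].astype(float), has_constant="add")
    return sm.OLS(df[response].astype(float), X).fit()


def _drop_collinear(df: pd.DataFrame, candidates: Sequence[str]) -> list[str]:
    """Drop later-ordered candidates that are perfectly collinear with earlier ones."""
    kept: list[str] = []
    base = np.ones((len(df), 1))
    for c in candidates:
        X = np.column_stack([base, df[list(kept)].to_numpy(dtype=float),
                             df[c].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn(f"candidate {c!r} is collinear with earlier terms; dropped",
                          stacklevel=3)
        else:
            kept.append(c)
    return kept


def stepwise_fit(
    train,
    response: str,
    candidates: Sequence[str] = COVARIATES,
    p_enter: float = 0.05,
    p_remove: float = 0.05,
) -> RegressionModel:
    """Forward–backward stepwise selection on partial-F p-values.

    At each step the excluded candidate with the smallest entry p-value
    below ``p_enter`` is added, then any included term whose p-value exceeds
    ``p_remove`` is removed (worst first).  Terminates when no move is
    possible; deterministic given the data (ties break by candidate order).
    For a single added term the partial-F test equals the squared-t test
    reported by OLS, which is what is used.
    """
    df = _as_frame(train)
    candidates = [c for c in candidates if c != response]
    unknown = set(candidates) - set(df.columns)
    if unknown:
        raise ValueError(f"unknown candidates: {sorted(unknown)}")
    if len(df) <= len(candidates) + 2:
        raise ValueError(
            f"n={len(df)} too small for {len(candidates)} candidates"
        )
    candidates = _drop_collinear(df, candidates)

    included: list[str] = []
    seen = {tuple(included)}
    while True:
        changed = False
        # forward: best entry p-value (non-finite p, e.g. from an already
        # perfect fit, never admits a term)
        excluded = [c for c in candidates if c not in included]
        best_c, best_p = None, np.inf
        for c in excluded:
            p = _ols(df, response, included + [c]).pvalues[c]
            if np.isfinite(p) and p < best_p - 1e-15:
                best_c, best_p = c, p
        if best_c is not None and best_p < p_enter:
            included.append(best_c)
            changed = True
        # backward: worst removal p-value
        if included:
            fit = _ols(df, response, included)
            pv = fit.pvalues.drop("const")
            worst = pv.idxmax()
            if np.isfinite(pv[worst]) and pv[worst] > p_remove:
                included.remove(worst)
                changed = True
        state = tuple(included)
        if not changed or state in seen:   # fixed point or add/remove cycle
            break
        seen.add(state)

    return _model_from_terms(df, response, included)


def _model_from_terms(df: pd.DataFrame, response: str, terms: Sequence[str]) -> RegressionModel:
    fit = _ols(df, response, terms)
    coef = {t: float(fit.params[t]) for t in terms}
    pvals = {t: float(fit.pvalues[t]) for t in terms}
    return RegressionModel(
        response=response,
        terms=tuple(terms),
        intercept=float(fit.params["const"]),
        coefficients=coef,
        pvalues=pvals,
        n_train=len(df),
    )


def model_metrics(
    model: RegressionModel, train, valid=None
) -> RegressionModel:
    """Fill in R², RMSE, AIC, BIC and validation R² on a fitted model.

    R² = 1 - SSE/SST on the training data; RMSE = sqrt(SSE/(n-k-1));
    AIC = n*ln(SSE/n) + 2(k+1) and BIC = n*ln(SSE/n) + (k+1)*ln(n)
    (Gaussian-likelihood forms up to an additive constant, so only
    differences across models on the same data are meaningful);
    validation R² is the squared Pearson correlation between predicted and
    observed responses on the held-out set.
    """
    train = _as_frame(train)
    n, k = len(train), len(model.terms)
    if n <= k + 1:
        raise ValueError(f"n={n} <= k+1={k + 1}: RMSE undefined")
    y = train[model.response].to_numpy(dtype=float)
    resid = y - model.predict(train)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    model.r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    model.rmse = math.sqrt(sse / (n - k - 1))
    # guard log(0) for exact fits
    model.aic = n * math.log(max(sse / n, 1e-300)) + 2 * (k + 1)
    model.bic = n * math.log(max(sse / n, 1e-300)) + (k + 1) * math.log(n)
    if valid is not None and len(valid) >= 3:
        valid = _as_frame(valid)
        pred = model.predict(valid)
        obs = valid[model.response].to_numpy(dtype=float)
        if np.std(pred) == 0 or np.std(obs) == 0:
            model.validation_r2 = float("nan")
        else:
            model.validation_r2 = float(stats.pearsonr(pred, obs)[0] ** 2)
        model.n_valid = len(valid)
    return model


def _forward_path(df: pd.DataFrame, response: str, candidates: Sequence[str]) -> list[list[str]]:
    """Greedy forward path: best single addition at each size, no stopping rule."""
    included: list[str] = []
    path: list[list[str]] = []
    while len(included) < len(candidates):
        excluded = [c for c in candidates if c not in included]
        best_c, best_p = excluded[0], np.inf
        for c in excluded:
            p = _ols(df, response, included + [c]).pvalues[c]
            if p < best_p - 1e-15:
                best_c, best_p = c, p
        included.append(best_c)
        path.append(list(included))
    return path


def model_table(
    records,
    responses: Sequence[str] = RESPONSES,
    seed: int = 0,
    candidates: Sequence[str] = COVARIATES,
    fraction: float = 0.7,
) -> list[RegressionModel]:
    """Ladder of prediction equations of increasing size per response.

    For each response the greedy forward-selection sequence (one model per
    size, up to the forced full model) is fitted on a seeded 70/30 training
    split and scored with :func:`model_metrics`.  The criterion-optimal
    model per response — best on the majority of {R² high, validation R²
    high, RMSE/AIC/BIC low}, ties to fewer terms — is flagged ``optimal``.
    """
    df = _as_frame(records)
    train, valid = split_train_valid(df, fraction=fraction, seed=seed)
    out: list[RegressionModel] = []
    for response in responses:
        cands = _drop_collinear(train, [c for c in candidates if c != response])
        ladder = [
            model_metrics(_model_from_terms(train, response, terms), train, valid)
            for terms in _forward_path(train, response, cands)
        ]
        # rank-score across the five criteria; lowest total rank wins
        def ranks(vals, reverse):
            order = np.argsort([-v if reverse else v for v in vals], kind="stable")
            rk = np.empty(len(vals), dtype=int)
            rk[order] = np.arange(len(vals))
            return rk
        score = (
            ranks([m.r2 for m in ladder], True)
            + ranks([m.validation_r2 for m in ladder], True)
            + ranks([m.rmse for m in ladder], False)
            + ranks([m.aic for m in ladder], False)
            + ranks([m.bic for m in ladder], False)
        )
        ladder[int(np.argmin(score))].optimal = True
        out.extend(ladder)
    return out


def best_subset_fit(
    train,
    response: str,
    candidates: Sequence[str],
    p_enter: float = 0.05,
    p_remove: float = 0.05,
) -> RegressionModel:
    """Exhaustive search for the most parsimonious subset under the p-rules.

    A subset is admissible (a fixed point of the entry/removal rules) when
    every included term's p-value is at most ``p_remove`` and no excluded
    candidate would enter with p below ``p_enter``.  Several fixed points
    may exist; since forward–backward selection starts from the empty model
    and stops as soon as no move is possible, its result is characterized
    as the *smallest* admissible subset (ties broken by SSE), which this
    enumeration returns.  Exponential in ``len(candidates)`` — an
    independent oracle for :func:`stepwise_fit` on small problems.
    """
    from itertools import combinations

    df = _as_frame(train)
    candidates = [c for c in candidates if c != response]
    if len(candidates) > 10:
        raise ValueError("best-subset oracle limited to 10 candidates")
    admissible: list[tuple[int, float, tuple[str, ...]]] = []
    for k in range(len(candidates) + 1):
        for terms in combinations(candidates, k):
            fit = _ols(df, response, list(terms))
            pv = fit.pvalues.drop("const")
            if len(terms) and pv.max() > p_remove:
                continue
            entering = False
            for c in candidates:
                if c in terms:
                    continue
                p = _ols(df, response, list(terms) + [c]).pvalues[c]
                if p < p_enter:
                    entering = True
                    break
            if entering:
                continue
            sse = float(fit.ssr)
            admissible.append((k, sse, terms))
    if not admissible:
        raise RuntimeError("no admissible subset found")
    kmin = min(a[0] for a in admissible)
    best = min((a for a in admissible if a[0] == kmin), key=lambda a: a[1])
    return _model_from_terms(df, response, list(best[2]))
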