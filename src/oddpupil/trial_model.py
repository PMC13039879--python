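"""Linear mixed-effects modelling of trial-level and aggregated features.

Outcomes are standardized (centered/scaled) across all trials, then fit
by REML with a participant random intercept.  The default fixed-effect
structure is ``stimulus * group * manipulation + block_direction + age +
gender``.  Post-hoc contrasts are differences of marginal means over an
equally-weighted reference grid, with delta-method confidence
intervals.  Model fit is summarised by Nakagawa marginal/conditional
R-squared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from scipy.linalg import qr as scipy_qr
from statsmodels.regression.mixed_linear_model import MixedLM

DEFAULT_FIXED_EFFECTS = (
    "stimulus * group * manipulation + block_direction + age + gender"
)

Z95 = float(stats.norm.ppf(0.975))


class SingularDesignError(ValueError):
    """Raised when the fixed-effects design matrix is rank deficient."""


@dataclass
class ContrastResult:
    """Difference of estimated marginal means with a 95% CI."""

    delta: float
    se: float
    ci_low: float
    ci_high: float

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


@dataclass
class ModelResult:
    """Fitted mixed model: estimates, variance components and term tests."""

    outcome: str
    formula: str
    fixed_effects: pd.DataFrame  # term, estimate, se, ci_low, ci_high
    sigma2_alpha: float  # random-intercept variance
    sigma2_eps: float  # residual variance
    sigma2_f: float  # variance of the fixed-effects linear predictor
    reml: bool
    tests: pd.DataFrame  # term, statistic, df, p (Wald chi-square)
    converged: bool
    # retained for marginal-mean machinery
    _fe_params: np.ndarray = None  # type: ignore[assignment]
    _cov_fe: np.ndarray = None  # type: ignore[assignment]
    _design_info: object = None
    _data: pd.DataFrame = None  # type: ignore[assignment]

    def coef(self, term: str) -> float:
        row = self.fixed_effects.loc[self.fixed_effects["term"] == term]
        if row.empty:
            raise KeyError(f"no fixed-effect term {term!r}")
        return float(row["estimate"].iloc[0])


def standardize(values) -> np.ndarray | pd.Series:
    """Center and scale to sample SD 1, preserving missing entries."""
    is_series = isinstance(values, pd.Series)
    x = np.asarray(values, dtype=float)
    mask = np.isfinite(x)
    if mask.sum() < 2:
        raise ValueError("need >= 2 non-missing values to standardize")
    sd = np.std(x[mask], ddof=1)
    if sd == 0:
        raise ValueError("zero variance: cannot standardize")
    out = np.full_like(x, np.nan)
    out[mask] = (x[mask] - np.mean(x[mask])) / sd
    if is_series:
        return pd.Series(out, index=values.index, name=values.name)
    return out


MEASURE_COLUMNS = (
    "bps", "sepr", "mmn_amp", "mmn_lat", "p3a_amp", "p3a_lat",
)

CONDITION_COLUMNS = ("stimulus", "manipulation", "block_direction")
SUBJECT_COLUMNS = ("group", "age", "gender")


def aggregate_by_condition(table: pd.DataFrame) -> pd.DataFrame:
    """Mean of each measure per subject x stimulus x manipulation x
    direction cell; subject-level covariates carried through."""
    if table.empty:
        raise ValueError("empty trial table")
    keys = ["subject_id"] + [c for c in CONDITION_COLUMNS if c in table.columns]
    measures = [c for c in MEASURE_COLUMNS if c in table.columns]
    carried = [c for c in SUBJECT_COLUMNS if c in table.columns]
    grouped = table.groupby(keys, observed=True, sort=True)
    out = grouped[measures].mean().reset_index()
    if carried:
        first = grouped[carried].first().reset_index()[keys + carried]
        out = out.merge(first, on=keys)
    return out


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return
    _q, r, piv = scipy_qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    aliased = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    aliased += [X.columns[j] for j in piv[len(diag):]]
    raise SingularDesignError(
        f"design matrix is rank deficient; aliased term(s): {aliased}"
    )


def fit_lmm(
    table: pd.DataFrame,
    outcome: str,
    formula_spec: str | None = None,
    *,
    reml: bool = True,
    group_col: str = "subject_id",
) -> ModelResult:
    """REML fit of ``outcome ~ fixed effects + (1 | subject)``.

    ``formula_spec`` is the right-hand side of the fixed-effects formula
    (default :data:`DEFAULT_FIXED_EFFECTS`).  Rows with missing values in
    any model variable are dropped listwise.
    """
    rhs = formula_spec or DEFAULT_FIXED_EFFECTS
    formula = f"{outcome} ~ {rhs}"
    if group_col not in table.columns:
        raise ValueError(f"missing grouping column {group_col!r}")
    if table[group_col].nunique() < 2:
        raise ValueError("need >= 2 subjects to fit a random intercept")

    y, X = patsy.dmatrices(
        formula, table, return_type="dataframe", NA_action="drop"
    )
    _check_full_rank(X)
    groups = table.loc[X.index, group_col]

    model = MixedLM(np.asarray(y).ravel(), np.asarray(X), groups=groups)
    model.exog_names[:] = list(X.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml)

    k_fe = model.k_fe
    beta = np.asarray(result.fe_params)
    cov_fe = np.asarray(result.cov_params())[:k_fe, :k_fe]
    se = np.sqrt(np.clip(np.diag(cov_fe), 0.0, None))
    fixed = pd.DataFrame(
        {
            "term": list(X.columns),
            "estimate": beta,
            "se": se,
            "ci_low": beta - Z95 * se,
            "ci_high": beta + Z95 * se,
        }
    )

    sigma2_alpha = float(np.asarray(result.cov_re)[0, 0])
    sigma2_eps = float(result.scale)
    linpred = np.asarray(X) @ beta
    sigma2_f = float(np.var(linpred, ddof=1))

    tests = _wald_term_tests(X.design_info, beta, cov_fe, X.columns)

    return ModelResult(
        outcome=outcome,
        formula=formula,
        fixed_effects=fixed,
        sigma2_alpha=sigma2_alpha,
        sigma2_eps=sigma2_eps,
        sigma2_f=sigma2_f,
        reml=reml,
        tests=tests,
        converged=bool(result.converged),
        _fe_params=beta,
        _cov_fe=cov_fe,
        _design_info=X.design_info,
        _data=table.loc[X.index].copy(),
    )


def _wald_term_tests(design_info, beta, cov_fe, columns) -> pd.DataFrame:
    """Large-sample Wald chi-square test per model term."""
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(len(columns))[sl]
        b = beta[idx]
        v = cov_fe[np.ix_(idx, idx)]
        try:
            chi2 = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError:
            chi2 = float("nan")
        df = len(idx)
        rows.append(
            {
                "term": term,
                "statistic": chi2,
                "df": df,
                "p": float(stats.chi2.sf(chi2, df)),
                "method": "wald_chi2",
            }
        )
    return pd.DataFrame(rows)


def term_test(result: ModelResult, term: str) -> tuple[float, int, float]:
    """(statistic, df, p) of the Wald test for one model term."""
    row = result.tests.loc[result.tests["term"] == term]
    if row.empty:
        raise KeyError(
            f"no term {term!r}; available: {list(result.tests['term'])}"
        )
    return (
        float(row["statistic"].iloc[0]),
        int(row["df"].iloc[0]),
        float(row["p"].iloc[0]),
    )


def _reference_grid(result: ModelResult) -> pd.DataFrame:
    """Equal-weight grid over all categorical factors in the model;
    continuous covariates fixed at their sample mean."""
    di = result._design_info
    cat: dict[str, list] = {}
    num: dict[str, float] = {}
    for factor, info in di.factor_infos.items():
        name = factor.name()
        if info.type == "categorical":
            cat[name] = list(info.categories)
        else:
            num[name] = float(np.mean(result._data[name]))
    if not cat:
        grid = pd.DataFrame([num])
    else:
        index = pd.MultiIndex.from_product(cat.values(), names=cat.keys())
        grid = index.to_frame(index=False)
        for k, v in num.items():
            grid[k] = v
    return grid


def marginal_contrast(
    result: ModelResult,
    factor: str,
    levels: tuple[str, str],
    within: dict[str, str] | None = None,
) -> ContrastResult:
    """Difference of marginal means ``levels[0] - levels[1]`` of ``factor``.

    Means are model-implied predictions averaged with equal weights over
    the levels of all other factors (optionally restricted by
    ``within``), with continuous covariates at their sample mean.  The
    95% CI uses the delta method on the fixed-effects covariance.
    """
    grid = _reference_grid(result)
    if factor not in grid.columns:
        raise ValueError(f"factor {factor!r} not in model")
    for lev in levels:
        if lev not in set(grid[factor]):
            raise ValueError(f"unknown level {lev!r} of factor {factor!r}")
    if within:
        for key, val in within.items():
            if key not in grid.columns:
                raise ValueError(f"unknown factor {key!r} in within=")
            if val not in set(grid[key]):
                raise ValueError(f"unknown level {val!r} of factor {key!r}")
            grid = grid[grid[key] == val]

    (X_grid,) = patsy.build_design_matrices([result._design_info], grid)
    X_grid = np.asarray(X_grid)
    rows_a = np.asarray(grid[factor] == levels[0])
    rows_b = np.asarray(grid[factor] == levels[1])
    x_a = X_grid[rows_a].mean(axis=0)
    x_b = X_grid[rows_b].mean(axis=0)
    contrast = x_a - x_b
    delta = float(contrast @ result._fe_params)
    var = float(contrast @ result._cov_fe @ contrast)
    se = float(np.sqrt(max(var, 0.0)))
    return ContrastResult(
        delta=delta, se=se, ci_low=delta - Z95 * se, ci_high=delta + Z95 * se
    )


def nakagawa_r2(result: ModelResult) -> tuple[float, float]:
    """Marginal and conditional R-squared of a random-intercept fit."""
    total = result.sigma2_f + result.sigma2_alpha + result.sigma2_eps
    m_r2 = result.sigma2_f / total
    c_r2 = (result.sigma2_f + result.sigma2_alpha) / total
    return float(m_r2), float(c_r2)


def pupil_erp_model(
    table: pd.DataFrame,
    erp_outcome: str,
    pupil_predictors: tuple[str, ...] = ("bps", "sepr"),
    *,
    interact_with_group: bool = False,
    reml: bool = True,
) -> ModelResult:
    """ERP outcome modelled with pupil metrics added to the fixed-effect
    structure (optionally interacting with group)."""
    for pred in pupil_predictors:
        if pred not in table.columns:
            raise ValueError(f"predictor {pred!r} not in table")
        x = table[pred].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        if len(x) < 2 or np.std(x, ddof=1) == 0:
            raise ValueError(f"predictor {pred!r} has no variance")
    extra = list(pupil_predictors)
    if interact_with_group:
        extra += [f"{p}:group" for p in pupil_predictors]
    rhs = DEFAULT_FIXED_EFFECTS + " + " + " + ".join(extra)
    return fit_lmm(table, erp_outcome, rhs, reml=reml)
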