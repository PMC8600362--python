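"""Multivariate pipeline: PCA, Horn's parallel analysis, interaction models.

The 30 EEG variables mix units (Hz, uV^2, fractions), so the PCA operates on
the correlation matrix of z-scored features (unrotated). Component retention
uses Horn's parallel analysis: observed eigenvalues are compared with the
95th percentile of eigenvalues from 900 same-shape standard-normal matrices,
and a component is retained when its *adjusted* eigenvalue
``observed - (percentile - 1)`` exceeds 1.

Retained component scores (scaled to unit variance) then enter ordinary
least squares models of the memory scores (CBE, NET) with an age-group main
effect, component main effects and all age x component interactions. Age is
coded as a centered +-0.5 contrast, so component main effects are cross-group
averages. The full model is simplified by backward AIC minimisation under
marginality (an interaction blocks the removal of its parents), and nested
models are compared with the incremental-R^2 F test. Per-group component
slopes come from re-parameterizing the fitted model with the group of
interest as the reference level; their t tests use the fitted model's
residual degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "PCAResult",
    "ParallelAnalysisResult",
    "RegressionModel",
    "SlopeTest",
    "zscore_features",
    "run_pca",
    "parallel_analysis",
    "fit_interaction_model",
    "simplify_aic",
    "nested_f_test",
    "group_slopes",
]

AGE_CODES = {"young": -0.5, "older": 0.5}


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending; sums to the number of variables
    components: np.ndarray  # variables x components, unit-norm eigenvectors
    loadings: np.ndarray  # variables x components, eigenvector * sqrt(eigenvalue)
    scores: np.ndarray  # subjects x components, unit variance
    variance_explained: np.ndarray
    cumulative_variance: np.ndarray
    feature_names: tuple = ()


@dataclass
class ParallelAnalysisResult:
    observed: np.ndarray
    null_percentiles: np.ndarray
    adjusted: np.ndarray
    n_retained: int


@dataclass(frozen=True)
class Term:
    """One model term: intercept, 'age', 'comp_k' or 'age:comp_k'."""

    name: str

    @property
    def is_interaction(self) -> bool:
        return ":" in self.name

    @property
    def parents(self) -> tuple:
        if not self.is_interaction:
            return ()
        return tuple(self.name.split(":"))


@dataclass
class RegressionModel:
    outcome: str
    terms: tuple  # term names, intercept first
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    aic: float
    df_resid: int
    rss: float
    nobs: int
    _design: pd.DataFrame = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _age_code: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class SlopeTest:
    group: str
    component: int
    slope: float
    se: float
    t: float
    df: int
    p: float


def zscore_features(matrix, feature_names=None) -> np.ndarray:
    """Column-wise standardisation (mean 0, sd 1, ddof=1).

    Raises on constant columns, naming the offending feature.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-d matrix with at least 3 subjects")
    if np.isnan(X).any():
        raise ValueError("missing values in the feature matrix")
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [feature_names[i] if feature_names else f"column {i}" for i in bad]
        raise ValueError(f"constant feature(s): {names}")
    return (X - X.mean(axis=0)) / sd


def run_pca(Z: np.ndarray, feature_names=None) -> PCAResult:
    """Unrotated PCA via eigendecomposition of the correlation matrix.

    Signs follow the convention that each loading column's largest-magnitude
    entry is positive. Numerically negative eigenvalues of rank-deficient
    inputs are truncated to zero; unit-variance scores are produced only for
    components with positive eigenvalue.
    """
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    R = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.where(eigvals < 1e-10, 0.0, eigvals)
    # deterministic sign convention
    for k in range(p):
        j = np.argmax(np.abs(eigvecs[:, k]))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    loadings = eigvecs * np.sqrt(eigvals)
    raw_scores = Z @ eigvecs
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(eigvals > 0, raw_scores / np.sqrt(eigvals), 0.0)
    var_exp = eigvals / p
    return PCAResult(
        eigenvalues=eigvals,
        components=eigvecs,
        loadings=loadings,
        scores=scores,
        variance_explained=var_exp,
        cumulative_variance=np.cumsum(var_exp),
        feature_names=tuple(feature_names) if feature_names is not None else (),
    )


def null_eigenvalues(n: int, p: int, n_iter: int, rng: np.random.Generator) -> np.ndarray:
    """Eigenvalue samples (n_iter x p) from standard-normal n x p matrices."""
    out = np.empty((n_iter, p))
    for i in range(n_iter):
        X = rng.standard_normal((n, p))
        R = np.corrcoef(X, rowvar=False)
        out[i] = np.linalg.eigvalsh(R)[::-1]
    return out


def parallel_analysis(
    Z: np.ndarray,
    n_iter: int = 900,
    centile: float = 95.0,
    seed: np.random.Generator | int | None = None,
) -> ParallelAnalysisResult:
    """Horn's parallel analysis with adjusted eigenvalues.

    adjusted_k = observed_k - (percentile_k - 1); components are retained
    from the top for as long as the adjusted eigenvalue exceeds 1 (the
    standard sequential stopping rule — counting non-consecutive exceedances
    further down the spectrum would retain spurious components on pure
    noise). Defaults: 900 iterations, 95th centile.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False))[::-1]
    nulls = null_eigenvalues(n, p, n_iter, rng)
    percentiles = np.percentile(nulls, centile, axis=0)
    adjusted = observed - (percentiles - 1.0)
    above = adjusted > 1.0
    n_retained = int(np.argmin(above)) if not above.all() else int(above.size)
    return ParallelAnalysisResult(
        observed=observed,
        null_percentiles=percentiles,
        adjusted=adjusted,
        n_retained=n_retained,
    )


def _build_design(
    scores: np.ndarray, age_code: np.ndarray, terms: tuple[str, ...]
) -> pd.DataFrame:
    cols = {}
    for t in terms:
        if t == "intercept":
            cols[t] = np.ones_like(age_code)
        elif t == "age":
            cols[t] = age_code
        elif t.startswith("age:comp_"):
            k = int(t.split("_")[1])
            cols[t] = age_code * scores[:, k - 1]
        elif t.startswith("comp_"):
            k = int(t.split("_")[1])
            cols[t] = scores[:, k - 1]
        else:
            raise ValueError(f"unknown term {t!r}")
    return pd.DataFrame(cols)


def _fit(
    outcome_name: str, y: np.ndarray, scores: np.ndarray, age_code: np.ndarray, terms: tuple
) -> RegressionModel:
    X = _build_design(scores, age_code, terms)
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError("singular design matrix")
    res = sm.OLS(y, X).fit()
    return RegressionModel(
        outcome=outcome_name,
        terms=tuple(terms),
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        aic=float(res.aic),
        df_resid=int(res.df_resid),
        rss=float(res.ssr),
        nobs=int(res.nobs),
        _design=X,
        _y=np.asarray(y, dtype=float),
        _age_code=np.asarray(age_code, dtype=float),
    )


def fit_interaction_model(
    scores: np.ndarray,
    age_group,
    outcome,
    outcome_name: str = "outcome",
    n_components: int | None = None,
) -> RegressionModel:
    """OLS of a memory score on age, components, and age x component terms.

    ``age_group`` holds 'young'/'older' labels (coded -0.5/+0.5); ``scores``
    is the subjects x components matrix (the first ``n_components`` columns
    are used, all by default).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 1:
        raise ValueError("need at least one retained component")
    if n_components is None:
        n_components = scores.shape[1]
    y = np.asarray(outcome, dtype=float)
    age_code = np.array([AGE_CODES[g] for g in age_group], dtype=float)
    if not (len(y) == len(age_code) == scores.shape[0]):
        raise ValueError("outcome, age_group and scores must be aligned")
    terms = (
        ["intercept", "age"]
        + [f"comp_{k}" for k in range(1, n_components + 1)]
        + [f"age:comp_{k}" for k in range(1, n_components + 1)]
    )
    return _fit(outcome_name, y, scores, age_code, tuple(terms))


def _droppable(terms: tuple) -> list:
    """Terms whose removal respects marginality (intercept never drops)."""
    out = []
    for t in terms:
        if t == "intercept":
            continue
        if ":" not in t:
            # a main effect is blocked while any interaction contains it
            if any(t in other.split(":") for other in terms if ":" in other):
                continue
        out.append(t)
    return out


def simplify_aic(model: RegressionModel) -> RegressionModel:
    """Backward elimination by AIC under marginality.

    Repeatedly drops the single term whose removal lowers AIC the most;
    stops when no removal lowers AIC. The AIC sequence is non-increasing.
    """
    current = model
    while True:
        best = None
        for term in _droppable(current.terms):
            reduced_terms = tuple(t for t in current.terms if t != term)
            candidate = _fit(
                current.outcome, current._y,
                _scores_from_design(current), current._age_code, reduced_terms,
            )
            if candidate.aic < current.aic - 1e-12 and (best is None or candidate.aic < best.aic):
                best = candidate
        if best is None:
            return current
        current = best


def _scores_from_design(model: RegressionModel) -> np.ndarray:
    """Recover the component-score columns used to build a model's design."""
    comp_cols = sorted(
        (int(c.split("_")[1]) for c in model._design.columns if c.startswith("comp_")),
    )
    max_k = max(comp_cols) if comp_cols else 0
    # interactions may reference components whose main column was dropped
    for c in model._design.columns:
        if c.startswith("age:comp_"):
            max_k = max(max_k, int(c.split("_")[1]))
    scores = np.zeros((len(model._y), max_k))
    for k in range(1, max_k + 1):
        col = f"comp_{k}"
        icol = f"age:comp_{k}"
        if col in model._design:
            scores[:, k - 1] = model._design[col].values
        elif icol in model._design:
            with np.errstate(divide="ignore", invalid="ignore"):
                scores[:, k - 1] = model._design[icol].values / model._age_code
    return scores


def nested_f_test(full: RegressionModel, reduced: RegressionModel):
    """Incremental F test: ((RSS_red - RSS_full)/ddf) / (RSS_full/df_full).

    Returns (delta_r2, F, df_num, df_den, p).
    """
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("models are not nested (reduced terms not a subset)")
    if full.nobs != reduced.nobs or full.outcome != reduced.outcome:
        raise ValueError("models must share outcome and subjects")
    df_num = len(full.terms) - len(reduced.terms)
    df_den = full.df_resid
    delta_r2 = full.r2 - reduced.r2
    if df_num == 0:
        return 0.0, 0.0, 0, df_den, 1.0
    F = ((reduced.rss - full.rss) / df_num) / (full.rss / df_den)
    p = float(sps.f.sf(F, df_num, df_den))
    return float(delta_r2), float(F), df_num, df_den, p


def group_slopes(model: RegressionModel, component: int) -> dict[str, SlopeTest]:
    """Per-group slope of a component, via reference re-leveling.

    For each group, the model is re-fit with identical column space but the
    age factor dummy-coded with that group as reference (0); the component's
    main-effect coefficient is then that group's slope. t uses the fitted
    model's residual df.
    """
    comp_term = f"comp_{component}"
    int_term = f"age:comp_{component}"
    if comp_term not in model.terms and int_term not in model.terms:
        raise ValueError(f"component {component} absent from the model")
    scores = _scores_from_design(model)
    out: dict[str, SlopeTest] = {}
    for ref in AGE_CODES:
        # shift coding so that the reference group's age code is 0
        shifted = model._age_code - AGE_CODES[ref]
        cols = {}
        for t in model.terms:
            if t == "intercept":
                cols[t] = np.ones_like(shifted)
            elif t == "age":
                cols[t] = shifted
            elif t.startswith("age:comp_"):
                k = int(t.split("_")[1])
                cols[t] = shifted * scores[:, k - 1]
            else:
                k = int(t.split("_")[1])
                cols[t] = scores[:, k - 1]
        X = pd.DataFrame(cols)
        res = sm.OLS(model._y, X).fit()
        if comp_term in res.params.index:
            slope = float(res.params[comp_term])
            se = float(res.bse[comp_term])
        else:  # interaction retained without the main effect: slope is 0 at reference
            slope, se = 0.0, float("nan")
        df = int(res.df_resid)
        t = slope / se if se and not math.isnan(se) else float("nan")
        p = float(2.0 * sps.t.sf(abs(t), df)) if not math.isnan(t) else float("nan")
        out[ref] = SlopeTest(group=ref, component=component, slope=slope, se=se, t=t, df=df, p=p)
    return out
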