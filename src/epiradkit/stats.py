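"""Linear-model layer: Welch t-tests, OLS with AGE/SEX factors, AICc selection.

Models are ordinary least squares on small cross-sectional tables (one row per
individual), with AGE (3 levels, reference AGE1) and SEX (reference F) coded
as treatment contrasts so the male coefficient reads as an additive male
effect.  Candidate sets follow the study design: an intercept-only model, the
additive AGE + SEX model, the AGE x SEX interaction model, optionally a body
size covariate, and — for the fin-as-surrogate question — gonad ~ fin (+ SEX,
+ fin x SEX) regressions.  Selection uses AICc with the Gaussian ML
log-likelihood (residual variance counted as a parameter); term tests are
marginal (Type II) F tests; estimated means carry t-based 95% intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

# formula fragment per model term; interactions use ':' so main effects stay
# separately listed in the spec
_TERM_FORMULA = {
    "AGE": "C(age_group, Treatment('AGE1'))",
    "SEX": "C(sex, Treatment('F'))",
    "AGE×SEX": "C(age_group, Treatment('AGE1')):C(sex, Treatment('F'))",
    "body_size": "body_size_mm",
    "fin_value": "fin_value",
    "fin_value×SEX": "fin_value:C(sex, Treatment('F'))",
}

_MAIN_EFFECTS = {"AGE×SEX": ("AGE", "SEX"), "fin_value×SEX": ("fin_value", "SEX")}


@dataclass(frozen=True)
class ModelSpec:
    """An OLS model: response plus an ordered term list (intercept implied)."""

    response: str
    terms: tuple = ()
    name: str = ""

    def __post_init__(self):
        unknown = [t for t in self.terms if t not in _TERM_FORMULA]
        if unknown:
            raise ValueError(f"unknown terms: {unknown} (known: {sorted(_TERM_FORMULA)})")
        for t in self.terms:
            for main in _MAIN_EFFECTS.get(t, ()):
                if main not in self.terms:
                    raise ValueError(f"interaction {t} requires main effect {main}")
        if not self.name:
            object.__setattr__(self, "name", " + ".join(self.terms) or "intercept-only")

    @property
    def formula(self) -> str:
        rhs = " + ".join(_TERM_FORMULA[t] for t in self.terms) or "1"
        return f"{self.response} ~ {rhs}"

    def required_columns(self):
        cols = {self.response}
        for t in self.terms:
            if t in ("AGE", "AGE×SEX"):
                cols.add("age_group")
            if t in ("SEX", "AGE×SEX", "fin_value×SEX"):
                cols.add("sex")
            if t == "body_size":
                cols.add("body_size_mm")
            if t in ("fin_value", "fin_value×SEX"):
                cols.add("fin_value")
        return cols

    def drop_term(self, term: str) -> "ModelSpec":
        return ModelSpec(self.response, tuple(t for t in self.terms if t != term),
                         name=f"{self.name} - {term}")


@dataclass
class ModelFit:
    """OLS fit summary: coefficients, likelihood, AICc, adjusted R^2."""

    spec: ModelSpec
    nobs: int
    coef: pd.DataFrame  # estimate, se, t, p per coefficient
    df_resid: float
    rss: float
    llf: float
    aicc: float
    r_squared: float
    adj_r_squared: float
    result: object = field(repr=False)  # statsmodels RegressionResults
    data: pd.DataFrame = field(repr=False)

    @property
    def n_coef(self) -> int:
        return len(self.coef)


def welch_t_test(x, y):
    """Welch two-sample t-test: (t, Satterthwaite df, two-sided p).

    Requires >= 2 values per sample and positive variance in at least one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("degenerate: both samples have zero variance")
    res = scipy.stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def aicc(llf: float, n_coef: int, nobs: int) -> float:
    """Small-sample Akaike criterion: -2l + 2k + 2k(k+1)/(n-k-1).

    k counts the regression coefficients plus the residual variance.
    """
    k = n_coef + 1
    if nobs - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={nobs} <= k+1={k + 1}")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (nobs - k - 1)


def fit_linear_model(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Ordinary least squares for ``spec`` with listwise NA deletion.

    The Gaussian log-likelihood uses the ML variance RSS/n, the convention
    under which information criteria of fixed-effects models are compared.
    Rank-deficient designs raise, listing the aliased columns.
    """
    cols = sorted(spec.required_columns())
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks columns {missing}")
    sub = data[cols].dropna()
    if (dropped := len(data) - len(sub)) > 0:
        logger.info("dropped %d rows with missing values", dropped)
    model = smf.ols(spec.formula, data=sub)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        _, r = np.linalg.qr(model.exog)
        aliased = [model.exog_names[i] for i in np.where(np.abs(np.diag(r)) < 1e-10)[0]]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    res = model.fit()
    coef = pd.DataFrame(
        {"estimate": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues}
    )
    try:
        crit = aicc(float(res.llf), len(res.params), int(res.nobs))
    except ValueError:
        crit = float("nan")  # undefined below n = k + 2; selection refuses NaN
    return ModelFit(
        spec=spec,
        nobs=int(res.nobs),
        coef=coef,
        df_resid=float(res.df_resid),
        rss=float(res.ssr),
        llf=float(res.llf),
        aicc=crit,
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        result=res,
        data=sub,
    )


def select_model(candidates, data: pd.DataFrame):
    """Fit every candidate on identical rows and rank by AICc.

    Returns ``(table, fits)``: a DataFrame (name, terms, k, llf, aicc,
    delta_aicc) sorted ascending, ties (< 1e-8) broken by fewer parameters,
    and the fits keyed by name.  Candidates that would drop different rows
    raise — their likelihoods are not comparable.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate model")
    all_cols = sorted(set().union(*(c.required_columns() for c in candidates)))
    missing = [c for c in all_cols if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks columns {missing}")
    row_sets = [set(data[sorted(c.required_columns())].dropna().index) for c in candidates]
    if len({frozenset(s) for s in row_sets}) > 1:
        raise ValueError("candidates would be fitted on differing row subsets; "
                         "drop incomplete rows first")
    fits = {}
    rows = []
    for c in candidates:
        f = fit_linear_model(c, data)
        if np.isnan(f.aicc):
            raise ValueError(
                f"AICc undefined for candidate '{c.name}' "
                f"(n={f.nobs}, k={f.n_coef + 1}): too few observations"
            )
        fits[c.name] = f
        rows.append({"name": c.name, "terms": " + ".join(c.terms) or "1",
                     "k": f.n_coef + 1, "llf": f.llf, "aicc": f.aicc})
    table = pd.DataFrame(rows)
    # quantize so AICc ties within 1e-8 are broken by fewer parameters
    table["_aicc_q"] = np.round(table["aicc"] / 1e-8) * 1e-8
    table = (table.sort_values(["_aicc_q", "k"], kind="mergesort")
             .drop(columns="_aicc_q").reset_index(drop=True))
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    return table, fits


def estimated_means(fit: ModelFit, grid: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Model-estimated means with t-based confidence intervals on a factor grid.

    Grid rows must stay inside the fitted design space; unseen factor levels
    raise.
    """
    for col in grid.columns:
        if col in fit.data.columns and fit.data[col].dtype == object:
            seen = set(fit.data[col])
            bad = set(grid[col]) - seen
            if bad:
                raise ValueError(f"grid level(s) {sorted(bad)} for '{col}' "
                                 f"not in fitted data {sorted(seen)}")
    pred = fit.result.get_prediction(grid)
    frame = pred.summary_frame(alpha=alpha)
    out = grid.copy()
    out["mean"] = frame["mean"].to_numpy()
    out["se"] = frame["mean_se"].to_numpy()
    out["ci_low"] = frame["mean_ci_lower"].to_numpy()
    out["ci_high"] = frame["mean_ci_upper"].to_numpy()
    return out


def term_f_tests(fit: ModelFit) -> pd.DataFrame:
    """Marginal (Type II) F test per model term.

    Each term is tested by comparing the model with and without it.  A main
    effect whose interaction is present is tested with that interaction
    excluded from both models (marginality), which is logged.
    """
    rows = []
    for term in fit.spec.terms:
        interactions = [t for t in fit.spec.terms
                        if term in _MAIN_EFFECTS.get(t, ())]
        base_terms = tuple(t for t in fit.spec.terms if t not in interactions)
        if interactions:
            logger.info("testing %s with interaction(s) %s excluded from both models",
                        term, interactions)
        full_spec = ModelSpec(fit.spec.response, base_terms, name=f"{fit.spec.name}|{term}")
        full = fit_linear_model(full_spec, fit.data) if interactions else fit
        reduced = fit_linear_model(full_spec.drop_term(term), fit.data)
        df1 = reduced.df_resid - full.df_resid
        df2 = full.df_resid
        f_stat = ((reduced.rss - full.rss) / df1) / (full.rss / df2)
        p = float(scipy.stats.f.sf(f_stat, df1, df2))
        rows.append({"term": term, "F": float(f_stat), "df1": int(df1),
                     "df2": int(df2), "p": p})
    return pd.DataFrame(rows)


def qq_normality_check(fit: ModelFit) -> pd.DataFrame:
    """Ordered standardized residuals against Normal plotting positions.

    Returns a table (theoretical, sample) for a Q-Q plot; positions are
    (i - 0.5)/n.
    """
    resid = np.sort(np.asarray(fit.result.resid, dtype=float))
    n = len(resid)
    sd = resid.std(ddof=0)
    standardized = resid / sd if sd > 0 else np.zeros(n)
    positions = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {"theoretical": scipy.stats.norm.ppf(positions), "sample": standardized}
    )


# -- canonical candidate sets ------------------------------------------------


def tissue_model_candidates(response: str, include_body_size: bool = False):
    """Intercept-only, AGE+SEX, AGE*SEX (and optionally + body size) models."""
    cands = [
        ModelSpec(response, (), name="empty"),
        ModelSpec(response, ("AGE", "SEX"), name="AGE+SEX"),
        ModelSpec(response, ("AGE", "SEX", "AGE×SEX"), name="AGE*SEX"),
    ]
    if include_body_size:
        cands.append(
            ModelSpec(response, ("AGE", "SEX", "AGE×SEX", "body_size"),
                      name="AGE*SEX+body")
        )
    return cands


def fin_gonad_model_candidates(response: str):
    """Gonad ~ fin surrogate models: empty, fin+SEX, fin*SEX."""
    return [
        ModelSpec(response, (), name="empty"),
        ModelSpec(response, ("fin_value", "SEX"), name="fin+SEX"),
        ModelSpec(response, ("fin_value", "SEX", "fin_value×SEX"), name="fin*SEX"),
    ]
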