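"""Mortality-risk and lesion outcome models.

Two model families connect the early-life-stress proxy (the standardised
composite FA score) and lesion observations to life-course outcomes:

* linear regression of natural-log age-at-death (age distributions are
  right-skewed) — fit statistics are the overall F and adjusted R^2; a
  coefficient b on the log scale translates to a 100*(exp(b) - 1) percent
  change in age-at-death per unit of the predictor;
* binary logistic regression of lesion classes (presence, activity,
  laterality, collapsed PD severity) — fit statistics are the likelihood-
  ratio chi-square 2*(lnL - lnL0) and McFadden's pseudo-R^2 = 1 - lnL/lnL0;
  exp(b) is an odds ratio.

Confidence intervals are Wald (estimate +/- z * SE) on the coefficient
scale, transformed monotonically for effect summaries. Model selection is
bidirectional stepwise search on AIC from the intercept-only model.

Site groupings used by the lesion models partition the four cemeteries:
for PNBF, later-medieval York Barbican + Warwick vs Black Gate + South
Shields; for PD, post-medieval South Shields vs the three medieval sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ComputationError, ValidationError

#: site grouping for PNBF models: {YB, WS} (later-medieval) vs {BG, SS}
PNBF_SITE_GROUP = {"YB": 1, "WS": 1, "BG": 0, "SS": 0}
#: site grouping for the PD model: post-medieval {SS} vs medieval {BG, WS, YB}
PD_SITE_GROUP = {"SS": 1, "BG": 0, "WS": 0, "YB": 0}


@dataclass
class ModelSpec:
    """A response plus candidate predictors (statsmodels formula terms)."""

    response: str
    predictors: list[str] = field(default_factory=list)
    kind: str = "linear"  # "linear" | "logistic"

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.predictors) if self.predictors else "1"
        return f"{self.response} ~ {rhs}"


@dataclass
class ModelFit:
    """Coefficient table plus family-appropriate fit statistics."""

    kind: str
    formula: str
    n: int
    params: pd.DataFrame  # index: term; columns: coef, se, stat, p, ci_low, ci_high
    # linear
    adj_r2: float | None = None
    f_stat: float | None = None
    f_df: tuple[int, int] | None = None
    f_p: float | None = None
    # logistic
    chi2: float | None = None
    chi2_p: float | None = None
    mcfadden_r2: float | None = None
    aic: float | None = None

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "coef"])


@dataclass
class EffectSummary:
    term: str
    effect: float  # percent change (linear) or odds ratio (logistic)
    ci_low: float
    ci_high: float
    scale: str  # "percent_change" | "odds_ratio"


def _params_frame(res, stat_name: str) -> pd.DataFrame:
    ci = res.conf_int()
    return pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            stat_name: getattr(res, "tvalues"),
            "p": res.pvalues,
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    )


def _check_rank(res, formula: str) -> None:
    exog = res.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name the aliased columns for the error message
        _q, r = np.linalg.qr(exog)
        diag = np.abs(np.diag(r))
        aliased = [
            res.model.exog_names[j]
            for j in range(exog.shape[1])
            if j < len(diag) and diag[j] < 1e-10 * diag.max()
        ]
        raise ComputationError(
            f"rank-deficient design in {formula!r}; aliased terms: {aliased or 'unknown'}"
        )


def fit_linear_log_age(data: pd.DataFrame, spec: ModelSpec | str) -> ModelFit:
    """OLS of natural-log age-at-death.

    The response column must already hold log(age); use
    ``np.log(df["age_years"])`` upstream so the caller controls what is
    logged. Reports Wald CIs, the overall F and adjusted R^2.
    """
    formula = spec if isinstance(spec, str) else spec.formula
    df = data.dropna(subset=_formula_columns(formula, data))
    model = smf.ols(formula, data=df)
    if df.shape[0] < model.exog_names.__len__() + 2:
        raise ValidationError(
            f"too few complete cases ({df.shape[0]}) for {formula!r}"
        )
    res = model.fit()
    _check_rank(res, formula)
    params = _params_frame(res, "t").rename(columns={"t": "stat"})
    return ModelFit(
        kind="linear",
        formula=formula,
        n=int(res.nobs),
        params=params,
        adj_r2=float(res.rsquared_adj),
        f_stat=float(res.fvalue) if res.df_model > 0 else None,
        f_df=(int(res.df_model), int(res.df_resid)),
        f_p=float(res.f_pvalue) if res.df_model > 0 else None,
        aic=float(res.aic),
    )


def fit_logistic(data: pd.DataFrame, spec: ModelSpec | str) -> ModelFit:
    """Maximum-likelihood binary logit with Wald CIs, LR chi-square and
    McFadden pseudo-R^2 against the intercept-only model."""
    formula = spec if isinstance(spec, str) else spec.formula
    df = data.dropna(subset=_formula_columns(formula, data))
    y_name = formula.split("~")[0].strip()
    y = df[y_name]
    if y.nunique() < 2:
        raise ValidationError(f"response {y_name!r} has a single class")
    model = smf.logit(formula, data=df)
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import (
        ConvergenceWarning,
        PerfectSeparationWarning,
    )

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # overflow in exp
            _warnings.simplefilter("ignore", ConvergenceWarning)  # re-checked below
            _warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(disp=0, maxiter=200)
    except PerfectSeparationWarning as exc:
        term = _separating_term(model)
        raise ComputationError(
            f"complete separation in {formula!r}"
            + (f"; separating term: {term}" if term else "")
        ) from exc
    except Exception as exc:
        raise ComputationError(f"logit fit failed for {formula!r}: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        # near-separation shows up as non-convergence with huge coefficients
        big = res.params.abs()
        raise ComputationError(
            f"logit did not converge for {formula!r}; possible complete separation "
            f"by {big.idxmax()!r}"
        )
    _check_rank(res, formula)
    params = _params_frame(res, "z").rename(columns={"z": "stat"})
    llf, llnull = float(res.llf), float(res.llnull)
    chi2 = 2.0 * (llf - llnull)
    return ModelFit(
        kind="logistic",
        formula=formula,
        n=int(res.nobs),
        params=params,
        chi2=chi2,
        chi2_p=float(res.llr_pvalue),
        mcfadden_r2=float(1.0 - llf / llnull) if llnull != 0 else 0.0,
        aic=float(res.aic),
    )


def _separating_term(model) -> str | None:
    """Best-effort diagnostic: a predictor whose class-conditional ranges do
    not overlap separates the response completely."""
    y = np.asarray(model.endog)
    exog = np.asarray(model.exog)
    for j, name in enumerate(model.exog_names):
        if name == "Intercept":
            continue
        x0, x1 = exog[y == 0, j], exog[y == 1, j]
        if len(x0) and len(x1) and (x0.max() <= x1.min() or x1.max() <= x0.min()):
            return name
    return None


def _formula_columns(formula: str, data: pd.DataFrame) -> list[str]:
    """Data columns referenced by a formula (crude token scan, ':'/'*' aware)."""
    import re

    tokens = set(re.findall(r"[A-Za-z_][A-Za-z0-9_]*", formula))
    return [c for c in data.columns if c in tokens]


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------


def stepwise_select(
    data: pd.DataFrame,
    spec: ModelSpec,
    criterion: str = "aic",
) -> tuple[ModelSpec, list[str]]:
    """Bidirectional stepwise search from the intercept-only model.

    At each step every single-term addition and deletion is scored; the move
    that most improves the criterion (AIC) is taken; the search stops at a
    local optimum. Returns the selected spec and the decision path. With an
    empty candidate set (or no improving move) the intercept-only spec is
    returned.
    """
    if criterion != "aic":
        raise ValidationError("only AIC selection is implemented")
    fit = fit_linear_log_age if spec.kind == "linear" else fit_logistic

    def score(terms: list[str]) -> float:
        trial = ModelSpec(spec.response, terms, spec.kind)
        try:
            return fit(data, trial).aic
        except (ComputationError, ValidationError):
            return np.inf

    current: list[str] = []
    current_aic = score(current)
    path = [f"start: intercept-only, AIC={current_aic:.3f}"]
    candidates = list(spec.predictors)
    while True:
        moves: list[tuple[float, str, list[str]]] = []
        for term in candidates:
            if term not in current:
                moves.append((score(current + [term]), f"add {term}", current + [term]))
        for term in current:
            reduced = [t for t in current if t != term]
            moves.append((score(reduced), f"drop {term}", reduced))
        if not moves:
            break
        best_aic, best_desc, best_terms = min(moves, key=lambda m: m[0])
        if best_aic < current_aic - 1e-9:
            current, current_aic = best_terms, best_aic
            path.append(f"{best_desc}, AIC={best_aic:.3f}")
        else:
            break
    path.append(f"final: {current or ['(intercept only)']}, AIC={current_aic:.3f}")
    return ModelSpec(spec.response, current, spec.kind), path


# ---------------------------------------------------------------------------
# effect transforms
# ---------------------------------------------------------------------------


def percent_change(
    b: float, ci: tuple[float, float] | None = None, term: str = ""
) -> EffectSummary:
    """Percent change in the (unlogged) response per unit predictor:
    100 * (exp(b) - 1); CI endpoints transformed identically."""
    lo, hi = ci if ci is not None else (np.nan, np.nan)
    return EffectSummary(
        term=term,
        effect=100.0 * float(np.expm1(b)),
        ci_low=100.0 * float(np.expm1(lo)),
        ci_high=100.0 * float(np.expm1(hi)),
        scale="percent_change",
    )


def odds_ratio(
    b: float, ci: tuple[float, float] | None = None, term: str = ""
) -> EffectSummary:
    """Odds ratio per unit predictor: exp(b); CI endpoints likewise."""
    lo, hi = ci if ci is not None else (np.nan, np.nan)
    return EffectSummary(
        term=term,
        effect=float(np.exp(b)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        scale="odds_ratio",
    )


def effect_table(fit: ModelFit, drop_intercept: bool = True) -> pd.DataFrame:
    """Per-term effect summaries for a fitted model."""
    transform = percent_change if fit.kind == "linear" else odds_ratio
    rows = []
    for term, row in fit.params.iterrows():
        if drop_intercept and term == "Intercept":
            continue
        eff = transform(row["coef"], (row["ci_low"], row["ci_high"]), term=term)
        rows.append(
            {
                "term": term,
                "coef": row["coef"],
                eff.scale: eff.effect,
                "ci_low": eff.ci_low,
                "ci_high": eff.ci_high,
            }
        )
    return pd.DataFrame(rows)
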