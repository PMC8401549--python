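"""Case-control association statistics.

Odds ratios come in three flavours mirroring the usual epidemiological
reporting: crude 2x2-table ORs with Woolf (log-normal) 95% confidence
intervals, covariate-adjusted ORs from unconditional logistic regression
with Wald intervals, and combined-exposure 2x2x2 tables against a joint
reference cell. Trend across tertiles is tested by replacing the
category with its median exposure value as a single continuous
covariate; exposure-by-exposure interaction is tested with a
likelihood-ratio chi-square on the product term.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm

from dietmicrobe.errors import ConvergenceError, DegenerateDistributionError, SeparationError, UndefinedOrError

log = logging.getLogger(__name__)

__all__ = [
    "OrEstimate",
    "crude_or_ci",
    "adjusted_or",
    "trend_test",
    "combined_or_table",
    "interaction_lrt",
]

Z95 = float(norm.ppf(0.975))


@dataclass
class OrEstimate:
    exposure_level: str
    or_point: float
    ci_low: float
    ci_high: float
    n_cases: int | None = None
    n_controls: int | None = None
    model: str = "I"
    p_trend: float | None = None
    p_interaction: float | None = None
    extra: dict = field(default_factory=dict)

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """Report-style half-up rounding of (OR, CI low, CI high)."""

        def _round_half_up(x: float) -> float:
            return float(np.floor(x * 10**ndigits + 0.5) / 10**ndigits)

        return tuple(_round_half_up(v) for v in (self.or_point, self.ci_low, self.ci_high))


def crude_or_ci(
    cases_exposed: int,
    controls_exposed: int,
    cases_ref: int,
    controls_ref: int,
    level: str = "exposed",
) -> OrEstimate:
    """Crude odds ratio with Woolf 95% CI from a 2x2 table.

    OR = (a*d)/(b*c) for a=cases exposed, b=controls exposed, c=cases
    reference, d=controls reference; CI = exp(ln OR +/- 1.96*sqrt(sum of
    1/cell)). If any cell is zero, the Haldane-Anscombe 0.5 correction is
    added to every cell.
    """
    cells = [cases_exposed, controls_exposed, cases_ref, controls_ref]
    if any(c < 0 for c in cells):
        raise ValueError("cell counts must be non-negative")
    if cases_exposed == 0 and controls_exposed == 0:
        raise UndefinedOrError("no exposed observations; odds ratio undefined")
    if cases_ref == 0 and controls_ref == 0:
        raise UndefinedOrError("empty reference stratum; odds ratio undefined")
    a, b, c, d = (x + 0.5 for x in cells) if 0 in cells else cells
    or_point = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_point) - Z95 * se), np.exp(np.log(or_point) + Z95 * se)
    return OrEstimate(
        exposure_level=level,
        or_point=float(or_point),
        ci_low=float(lo),
        ci_high=float(hi),
        n_cases=cases_exposed,
        n_controls=controls_exposed,
        model="I",
    )


def _design_matrix(data: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric design columns: numeric covariates as-is, categoricals
    dummy-coded dropping the first level; constant columns dropped with a
    warning."""
    parts = []
    for cov in covariates:
        col = data[cov]
        if col.dtype.kind in "biufc":
            parts.append(col.astype(float).to_frame(cov))
        else:
            parts.append(pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float))
    if not parts:
        return pd.DataFrame(index=data.index)
    X = pd.concat(parts, axis=1)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        log.warning("dropping constant covariate column(s): %s", const)
        X = X.drop(columns=const)
    return X


def _fit_logit(y: pd.Series, X: pd.DataFrame):
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y.astype(float), Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        if "separat" in str(exc).lower():
            raise SeparationError(str(exc)) from exc
        raise ConvergenceError(str(exc)) from exc
    if not res.mle_retvals.get("converged", True):
        big = Xc.columns[np.argmax(np.abs(res.params.to_numpy()))]
        if np.abs(res.params).max() > 15:
            raise SeparationError(f"suspected separation on covariate {big!r}")
        raise ConvergenceError("logistic fit did not converge")
    return res


def adjusted_or(
    data: pd.DataFrame,
    exposure: pd.Series,
    covariates: list[str] | None = None,
    outcome: str = "case",
    model: str = "II",
) -> list[OrEstimate]:
    """Covariate-adjusted odds ratios for an ordinal/categorical exposure.

    The exposure is indicator-coded against its lowest level; ORs are
    exp(coefficient) with Wald 95% CIs. Rows with missing exposure or
    covariates are dropped (complete-case).
    """
    covariates = covariates or []
    df = data.copy()
    df["_exposure"] = exposure.reindex(df.index)
    df = df.dropna(subset=["_exposure", outcome] + covariates)
    n_param = df["_exposure"].nunique() - 1 + len(covariates) + 1
    if len(df) < 10 * n_param:
        log.warning("only %d complete cases for %d parameters", len(df), n_param)
    levels = sorted(df["_exposure"].unique())
    ref = levels[0]
    dummies = pd.get_dummies(df["_exposure"], prefix="exp", dtype=float).drop(
        columns=f"exp_{ref}"
    )
    X = pd.concat([dummies, _design_matrix(df, covariates)], axis=1)
    res = _fit_logit(df[outcome], X)
    out = [
        OrEstimate(
            exposure_level=str(ref),
            or_point=1.0,
            ci_low=1.0,
            ci_high=1.0,
            n_cases=int(df.loc[df["_exposure"] == ref, outcome].sum()),
            n_controls=int((df["_exposure"] == ref).sum() - df.loc[df["_exposure"] == ref, outcome].sum()),
            model=model,
        )
    ]
    ci = res.conf_int()
    for lev in levels[1:]:
        name = f"exp_{lev}"
        out.append(
            OrEstimate(
                exposure_level=str(lev),
                or_point=float(np.exp(res.params[name])),
                ci_low=float(np.exp(ci.loc[name, 0])),
                ci_high=float(np.exp(ci.loc[name, 1])),
                n_cases=int(df.loc[df["_exposure"] == lev, outcome].sum()),
                n_controls=int((df["_exposure"] == lev).sum() - df.loc[df["_exposure"] == lev, outcome].sum()),
                model=model,
            )
        )
    return out


def trend_test(
    data: pd.DataFrame,
    tertiles: pd.Series,
    scores: pd.Series | None = None,
    covariates: list[str] | None = None,
    outcome: str = "case",
    medians_from: str = "all",
) -> float:
    """P for linear trend across tertiles (median-coded continuous term).

    Each participant's tertile is replaced by the median exposure score
    within that tertile (computed over all participants by default, or
    controls only with ``medians_from="controls"``); the Wald p-value of
    that single continuous covariate in a logistic model is returned.
    """
    covariates = covariates or []
    df = data.copy()
    df["_tert"] = tertiles.reindex(df.index)
    df["_score"] = (scores.reindex(df.index) if scores is not None else df["_tert"].astype(float))
    df = df.dropna(subset=["_tert", "_score", outcome] + covariates)
    present = sorted(df["_tert"].unique())
    if len(present) < 3:
        raise DegenerateDistributionError("fewer than 3 tertiles present")
    if medians_from == "controls":
        base = df[df[outcome] == 0]
    else:
        base = df
    medians = base.groupby("_tert")["_score"].median()
    if medians.nunique() < len(medians):
        raise DegenerateDistributionError("tertile medians are not distinct")
    df["_trend"] = df["_tert"].map(medians).astype(float)
    X = pd.concat([df[["_trend"]], _design_matrix(df, covariates)], axis=1)
    res = _fit_logit(df[outcome], X)
    return float(res.pvalues["_trend"])


def combined_or_table(
    data: pd.DataFrame,
    pattern_high: pd.Series,
    mdi_high: pd.Series,
    covariates: list[str] | None = None,
    outcome: str = "case",
    model: str = "crude",
) -> list[OrEstimate]:
    """ORs for the four cells of a dichotomized pattern x MDI cross.

    Reference = (pattern low, MDI low). ``model="crude"`` forms three 2x2
    tables against the reference cell; otherwise a logistic model with
    three cell indicators (plus covariates) gives adjusted ORs.
    Cell order: ref, (high pattern, low MDI), (low pattern, high MDI),
    (high pattern, high MDI).
    """
    covariates = covariates or []
    df = data.copy()
    df["_p"] = pattern_high.reindex(df.index)
    df["_m"] = mdi_high.reindex(df.index)
    df = df.dropna(subset=["_p", "_m", outcome] + covariates)
    cells = [(0, 0), (1, 0), (0, 1), (1, 1)]
    labels = {
        (0, 0): "low_pattern_low_mdi",
        (1, 0): "high_pattern_low_mdi",
        (0, 1): "low_pattern_high_mdi",
        (1, 1): "high_pattern_high_mdi",
    }
    counts = {}
    for p, m in cells:
        sub = df[(df["_p"] == p) & (df["_m"] == m)]
        counts[(p, m)] = (int(sub[outcome].sum()), int(len(sub) - sub[outcome].sum()))
    ref_cases, ref_controls = counts[(0, 0)]
    out = [
        OrEstimate(
            exposure_level=labels[(0, 0)],
            or_point=1.0,
            ci_low=1.0,
            ci_high=1.0,
            n_cases=ref_cases,
            n_controls=ref_controls,
            model=model,
        )
    ]
    if model == "crude":
        for cell in cells[1:]:
            ca, co = counts[cell]
            if ca == 0 and co == 0:
                raise UndefinedOrError(f"empty stratum {labels[cell]}")
            est = crude_or_ci(ca, co, ref_cases, ref_controls, level=labels[cell])
            est.exposure_level = labels[cell]
            out.append(est)
        return out
    ind = pd.DataFrame(
        {
            labels[c]: ((df["_p"] == c[0]) & (df["_m"] == c[1])).astype(float)
            for c in cells[1:]
        },
        index=df.index,
    )
    X = pd.concat([ind, _design_matrix(df, covariates)], axis=1)
    res = _fit_logit(df[outcome], X)
    ci = res.conf_int()
    for cell in cells[1:]:
        name = labels[cell]
        ca, co = counts[cell]
        out.append(
            OrEstimate(
                exposure_level=name,
                or_point=float(np.exp(res.params[name])),
                ci_low=float(np.exp(ci.loc[name, 0])),
                ci_high=float(np.exp(ci.loc[name, 1])),
                n_cases=ca,
                n_controls=co,
                model=model,
            )
        )
    return out


def interaction_lrt(
    data: pd.DataFrame,
    pattern_high: pd.Series,
    mdi_high: pd.Series,
    covariates: list[str] | None = None,
    outcome: str = "case",
) -> float:
    """Likelihood-ratio p for a pattern x MDI product term.

    Full model = reduced (both main effects + covariates) + product term;
    p = chi-square(1) survival at 2*(loglik_full - loglik_reduced).
    """
    covariates = covariates or []
    df = data.copy()
    df["_p"] = pattern_high.reindex(df.index).astype(float)
    df["_m"] = mdi_high.reindex(df.index).astype(float)
    df = df.dropna(subset=["_p", "_m", outcome] + covariates)
    Xcov = _design_matrix(df, covariates)
    X_red = pd.concat([df[["_p", "_m"]], Xcov], axis=1)
    df["_pm"] = df["_p"] * df["_m"]
    X_full = pd.concat([df[["_p", "_m", "_pm"]], Xcov], axis=1)
    res_red = _fit_logit(df[outcome], X_red)
    res_full = _fit_logit(df[outcome], X_full)
    stat = max(2.0 * (res_full.llf - res_red.llf), 0.0)
    return float(chi2.sf(stat, df=1))
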