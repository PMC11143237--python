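"""Factorial ANOVA helpers shared by the coherency and rs-FC analyses."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


class DesignError(ValueError):
    pass


def _check_design(df: pd.DataFrame, factors) -> list:
    """Drop single-level factors (with a warning); error on empty cells."""
    kept = []
    for f in factors:
        levels = df[f].nunique()
        if levels < 2:
            warnings.warn(f"factor {f!r} has a single level; dropped")
        else:
            kept.append(f)
    if len(kept) >= 2:
        counts = df.groupby(list(kept), observed=True).size()
        full = np.prod([df[f].nunique() for f in kept])
        if len(counts) < full or (counts == 0).any():
            raise DesignError("empty cell in the factorial design")
    elif not kept:
        raise DesignError("no factor with two levels")
    return kept


def two_way_anova(df: pd.DataFrame, response: str,
                  factors=("condition", "subject"),
                  block: str = None) -> pd.DataFrame:
    """Type-II ANOVA with two crossed factors and their interaction.

    ``block`` adds a categorical blocking term (e.g. ROI pair), the
    classical fixed-effects equivalent of modeling it as a random effect
    in a balanced design.  Returns a table with sum_sq, df, F and p.
    """
    df = df.copy()
    kept = _check_design(df, factors)
    terms = [f"C({f})" for f in kept]
    formula = f"{response} ~ " + " + ".join(terms)
    if len(kept) == 2:
        formula += f" + C({kept[0]}):C({kept[1]})"
    if block is not None and df[block].nunique() > 1:
        formula += f" + C({block})"
    model = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(model, typ=2)
    table = table.rename(columns={"PR(>F)": "p"})
    return table


def fisher_z(r: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """Variance-stabilizing atanh transform, clipped away from |r| = 1."""
    return np.arctanh(np.clip(r, -1 + eps, 1 - eps))


def mixed_logistic(df: pd.DataFrame, response: str, fixed: str,
                   group: str) -> pd.DataFrame:
    """Logistic regression with a random intercept per group.

    Delegates to a variational Bayes binomial mixed GLM; the reported
    statistic is posterior mean / posterior SD with a normal reference.
    Falls back to an L2-penalized fixed-effects logit when the design is
    separated (a cell that is all-0 or all-1), flagged in the output.
    """
    from scipy.stats import norm

    y = df[response].astype(float)
    if y.nunique() < 2:
        raise DesignError("response is constant; model undefined")
    separated = False
    fe_formula = f"{response} ~ {fixed}"
    try:
        model = sm.BinomialBayesMixedGLM.from_formula(
            fe_formula, {"grp": f"0 + C({group})"}, df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit_vb()
        names = model.exog_names
        est = fit.fe_mean
        sd = fit.fe_sd
        if not np.all(np.isfinite(est)) or not np.all(sd > 0):
            raise RuntimeError("degenerate variational fit")
    except Exception:
        separated = True
        model = smf.logit(fe_formula, data=df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit_regularized(alpha=1.0, disp=False)
        names = model.exog_names
        est = np.asarray(fit.params)
        # crude SEs from the unpenalized information at the penalized estimate
        try:
            cov = fit.cov_params()
            sd = np.sqrt(np.diag(cov))
        except Exception:
            sd = np.full_like(est, np.nan)
    z = est / sd
    p = 2 * norm.sf(np.abs(z))
    out = pd.DataFrame({"term": names, "estimate": est, "T": z, "p": p})
    out.attrs["separated"] = separated
    return out
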