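"""Sequential (Type-I) ANOVA on RPM expression from a reciprocal cross.

The response is reads-per-million-mapped (RPM) for one TE family per
library/lane; the fixed-effect model, fitted in the stated order, is

    rpm ~ treatment + age + barcode + treatment:age

with treatment = dysgenic vs non-dysgenic cross direction, age = the F1
female age class, and barcode = the library index (a technical factor).
Lanes enter as replicate observations; no lane term is fitted.  Each
term is tested against the residual mean square.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

TERM_LABELS = ("Treat", "Age", "Barcode", "Treat X age", "Residuals")


def rpm(te_reads: float, total_mapped: float) -> float:
    """Reads per million mapped: 1e6 * te / total."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    return 1e6 * te_reads / total_mapped


def f_tail(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F distribution."""
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    if F < 0:
        raise ValueError("F must be >= 0")
    return float(stats.f.sf(F, df1, df2))


def sequential_anova(
    observations: pd.DataFrame,
    response: str = "rpm",
    treatment: str = "treatment",
    age: str = "age_class",
    barcode: str = "barcode",
) -> pd.DataFrame:
    """Fit the sequential ANOVA and return the term table.

    Returns a frame indexed by term (Treat, Age, Barcode, Treat X age,
    Residuals) with columns df, sum_sq, mean_sq, F, p.  Terms whose sum
    of squares is zero report F=0, p=1 (covers the degenerate constant-
    response case, where the residual mean square is also zero).
    """
    df = observations
    for col in (response, treatment, age, barcode):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    for col in (treatment, age, barcode):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs >= 2 observed levels")
    formula = (f"Q('{response}') ~ C(Q('{treatment}')) + C(Q('{age}')) "
               f"+ C(Q('{barcode}')) + C(Q('{treatment}')):C(Q('{age}'))")
    fit = ols(formula, data=df).fit()
    model_df = int(fit.df_model)
    expected = ((df[treatment].nunique() - 1) + (df[age].nunique() - 1)
                + (df[barcode].nunique() - 1)
                + (df[treatment].nunique() - 1) * (df[age].nunique() - 1))
    if model_df < expected:
        raise ValueError("singular design: some factors are confounded")
    with np.errstate(divide="ignore", invalid="ignore"):
        table = anova_lm(fit, typ=1)
    order = list(table.index)
    mapping = dict(zip(order, TERM_LABELS))
    table = table.rename(index=mapping)
    out = pd.DataFrame({
        "df": table["df"].astype(int),
        "sum_sq": table["sum_sq"],
    }, index=table.index)
    out["mean_sq"] = out["sum_sq"] / out["df"]
    resid_ms = out.at["Residuals", "mean_sq"]
    ss_floor = 1e-12 * max(float(out["sum_sq"].sum()), 1.0)
    F, p = [], []
    for term in out.index:
        if term == "Residuals":
            F.append(np.nan)
            p.append(np.nan)
        elif out.at[term, "sum_sq"] <= ss_floor:
            F.append(0.0)
            p.append(1.0)
        else:
            fval = (np.inf if resid_ms == 0
                    else out.at[term, "mean_sq"] / resid_ms)
            F.append(float(fval))
            p.append(0.0 if np.isinf(fval) else
                     f_tail(fval, int(out.at[term, "df"]),
                            int(out.at["Residuals", "df"])))
    out["F"] = F
    out["p"] = p
    out.index.name = "term"
    return out


def anova_from_components(
    sum_sq: Mapping[str, float], df: Mapping[str, int]
) -> pd.DataFrame:
    """Rebuild an ANOVA table from published sums of squares and df
    (mean squares, F against the residual mean square, and p)."""
    if "Residuals" not in sum_sq or "Residuals" not in df:
        raise ValueError("need a Residuals row")
    terms = [t for t in sum_sq if t != "Residuals"] + ["Residuals"]
    rows = []
    resid_ms = sum_sq["Residuals"] / df["Residuals"]
    for term in terms:
        ms = sum_sq[term] / df[term]
        if term == "Residuals":
            fval = pval = np.nan
        else:
            fval = ms / resid_ms
            pval = f_tail(fval, df[term], df["Residuals"])
        rows.append({"term": term, "df": df[term], "sum_sq": sum_sq[term],
                     "mean_sq": ms, "F": fval, "p": pval})
    return pd.DataFrame(rows).set_index("term")


def expression_report(
    tables: Mapping[str, pd.DataFrame],
    observations: Mapping[str, pd.DataFrame] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Combine per-TE ANOVA tables into conclusion flags.

    One row per TE with per-term significance at `alpha`, plus the two
    headline calls: a treatment (cross-direction) effect and a
    treatment-by-age interaction.  When raw observations are supplied,
    per-group mean RPM and replicate SD are appended (bar-plot data).
    """
    rows = []
    for te in sorted(tables):
        tab = tables[te]
        flags = {f"sig_{t.replace(' ', '_')}": bool(tab.at[t, "p"] < alpha)
                 for t in tab.index if t != "Residuals"}
        row = {"te": te, **flags,
               "treatment_effect": flags.get("sig_Treat", False),
               "treatment_age_interaction": flags.get("sig_Treat_X_age", False)}
        rows.append(row)
    report = pd.DataFrame(rows)
    if observations:
        means = []
        for te, obs in observations.items():
            g = (obs.groupby(["treatment", "age_class"])["rpm"]
                 .agg(["mean", "std"]).reset_index())
            g.insert(0, "te", te)
            means.append(g)
        report.attrs["group_means"] = pd.concat(means, ignore_index=True)
    return report
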