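"""Group x Timepoint inference for a two-group, pre/post repeated-measures
design, with Tukey-Kramer post hoc contrasts and clinical correlations.

The model is a linear mixed-effects model with Group, Timepoint and their
interaction as fixed effects and subject as a random effect (compound
symmetry).  For a complete two-timepoint design this model has an exact
stratum decomposition, which is how it is fit here:

* within-subject stratum — change scores ``d_i = post_i - pre_i`` carry the
  Timepoint main effect (mean of the group change means) and the
  Group x Timepoint interaction (difference of the group change means),
  each tested against the pooled within-group variance of ``d`` with
  ``n_subjects - 2`` error degrees of freedom;
* between-subject stratum — subject means ``(pre_i + post_i)/2`` carry the
  Group main effect.

This closed form is the generalized-least-squares solution under a
compound-symmetric within-subject covariance and, unlike an iterative
random-intercept fit, remains exact when the within-subject correlation is
negative.  For the target study design (15 + 15 subjects) every F statistic
has (1, 28) degrees of freedom, and the interaction F equals the squared
two-sample t comparing change scores between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OutcomeTable",
    "EffectTest",
    "ModelResult",
    "make_outcome_table",
    "fit_group_time",
    "posthoc_within_group",
    "clinical_correlations",
]

GROUPS = ("active", "sham")
TIMEPOINTS = ("pre", "post")


@dataclass
class OutcomeTable:
    """Long-format outcomes: one row per subject x timepoint x band x measure.

    Required columns: subject, group, timepoint, band, measure, value.
    Each subject must appear in exactly one group with both timepoints.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "group", "timepoint", "band", "measure", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"outcome table missing columns: {sorted(missing)}")
        groups_per_subject = self.data.groupby("subject")["group"].nunique()
        bad = groups_per_subject[groups_per_subject > 1]
        if len(bad):
            raise ValueError(f"subjects in more than one group: {list(bad.index)}")

    def select(self, measure: str, band: str) -> pd.DataFrame:
        sub = self.data[(self.data["measure"] == measure) & (self.data["band"] == band)]
        if sub.empty:
            raise ValueError(f"no rows for measure={measure!r}, band={band!r}")
        return sub


def make_outcome_table(rows) -> OutcomeTable:
    return OutcomeTable(pd.DataFrame(rows))


@dataclass
class EffectTest:
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class ModelResult:
    """Fixed-effect F tests plus the pieces post hoc contrasts need."""

    effects: dict[str, EffectTest]
    cell_means: pd.DataFrame  # columns: group, timepoint, mean, n
    change_means: dict[str, float]  # group -> mean(post - pre)
    mse_change: float  # pooled variance of change scores
    df_error: int
    measure: str = ""
    band: str = ""


def _paired_wide(sub: pd.DataFrame) -> pd.DataFrame:
    wide = sub.pivot_table(index=["subject", "group"], columns="timepoint",
                           values="value", aggfunc="first").reset_index()
    missing = wide[wide[list(TIMEPOINTS)].isna().any(axis=1)] if set(TIMEPOINTS) <= set(wide.columns) else wide
    if not set(TIMEPOINTS) <= set(wide.columns) or len(missing):
        subjects = list(missing["subject"]) if "subject" in getattr(missing, "columns", []) else []
        raise ValueError(f"incomplete pre/post pairs for subjects: {subjects or 'all'}")
    return wide


def fit_group_time(outcomes: OutcomeTable, measure: str, band: str) -> ModelResult:
    """Mixed-model F tests for Group, Timepoint and Group x Timepoint.

    Requires complete pre/post pairs; raises listing offending subjects
    otherwise.  P values come from the F distribution with (1, n_subjects -
    2) degrees of freedom.
    """
    sub = outcomes.select(measure, band)
    wide = _paired_wide(sub)
    if wide["group"].nunique() != 2:
        raise ValueError("need exactly 2 groups")
    g_names = [g for g in GROUPS if g in set(wide["group"])] or sorted(wide["group"].unique())
    d = {g: (wide.loc[wide.group == g, "post"] - wide.loc[wide.group == g, "pre"]).to_numpy()
         for g in g_names}
    s = {g: ((wide.loc[wide.group == g, "post"] + wide.loc[wide.group == g, "pre"]) / 2).to_numpy()
         for g in g_names}
    n = {g: len(d[g]) for g in g_names}
    n_tot = sum(n.values())
    dfe = n_tot - 2
    if dfe < 1:
        raise ValueError("not enough subjects")
    inv_n = 1.0 / n[g_names[0]] + 1.0 / n[g_names[1]]

    def stratum_tests(vals: dict[str, np.ndarray]) -> tuple[float, float, float]:
        """(MSE, F_intercept, F_difference) for a one-way two-group stratum."""
        sse = sum(((vals[g] - vals[g].mean()) ** 2).sum() for g in g_names)
        mse = sse / dfe
        means = [vals[g].mean() for g in g_names]
        est_int = (means[0] + means[1]) / 2.0  # unweighted (type III) intercept
        est_dif = means[0] - means[1]
        var_dif = mse * inv_n
        f_int = np.inf if var_dif == 0 and est_int != 0 else (
            0.0 if var_dif == 0 else est_int**2 / (var_dif / 4.0))
        f_dif = np.inf if var_dif == 0 and est_dif != 0 else (
            0.0 if var_dif == 0 else est_dif**2 / var_dif)
        return mse, f_int, f_dif

    mse_d, f_time, f_inter = stratum_tests(d)
    mse_s, _, f_group = stratum_tests(s)

    def p_of(F: float) -> float:
        return float(sps.f.sf(F, 1, dfe)) if np.isfinite(F) else 0.0

    effects = {
        "group": EffectTest(F=float(f_group), df1=1, df2=dfe, p=p_of(f_group)),
        "timepoint": EffectTest(F=float(f_time), df1=1, df2=dfe, p=p_of(f_time)),
        "group:timepoint": EffectTest(F=float(f_inter), df1=1, df2=dfe, p=p_of(f_inter)),
    }
    cells = []
    for g in g_names:
        for tp in TIMEPOINTS:
            vals = wide.loc[wide.group == g, tp]
            cells.append({"group": g, "timepoint": tp, "mean": float(vals.mean()), "n": len(vals)})
    return ModelResult(
        effects=effects,
        cell_means=pd.DataFrame(cells),
        change_means={g: float(d[g].mean()) for g in g_names},
        mse_change=float(mse_d),
        df_error=dfe,
        measure=measure,
        band=band,
    )


def posthoc_within_group(
    outcomes: OutcomeTable, measure: str, band: str, result: ModelResult | None = None
) -> pd.DataFrame:
    """Pre-vs-post contrast within each group, Tukey-Kramer adjusted.

    The family is the four Group x Timepoint cell means; adjusted P values
    use the studentized-range distribution with k = 4 means and the
    within-subject error degrees of freedom.  Columns: group, estimate, t,
    p_unadjusted, p_tukey.
    """
    res = result or fit_group_time(outcomes, measure, band)
    rows = []
    k = 4
    for g, est in res.change_means.items():
        n_g = int(res.cell_means.loc[res.cell_means.group == g, "n"].iloc[0])
        var = res.mse_change / n_g
        if var == 0:
            t = 0.0 if est == 0 else np.inf
        else:
            t = est / np.sqrt(var)
        if np.isfinite(t):
            p_un = float(2 * sps.t.sf(abs(t), res.df_error))
            p_adj = float(sps.studentized_range.sf(abs(t) * np.sqrt(2), k, res.df_error))
        else:
            p_un = p_adj = 0.0
        rows.append({
            "group": g, "estimate": float(est), "t": float(t),
            "p_unadjusted": min(p_un, 1.0), "p_tukey": float(np.clip(p_adj, 0.0, 1.0)),
        })
    return pd.DataFrame(rows)


def clinical_correlations(x, y, names: tuple[str, str] = ("x", "y")) -> dict:
    """Pearson correlation with two-sided P and a normality pre-check.

    Pairs with missing values are dropped; requires n >= 3.  Normality of
    each variable is reported via a Kolmogorov-Smirnov test against a
    normal with the sample mean/SD (reported alongside, never gating).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have matching length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    r, p = sps.pearsonr(x, y)

    def ks_norm(v: np.ndarray) -> float:
        sd = v.std(ddof=1)
        if sd == 0:
            return 0.0
        return float(sps.kstest(v, "norm", args=(v.mean(), sd)).pvalue)

    return {
        "pair": names,
        "n": int(len(x)),
        "r": float(r),
        "p": float(p),
        "ks_p": (ks_norm(x), ks_norm(y)),
    }
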