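"""Group-level inference: mixed ANOVA, Greenhouse-Geisser, FDR, regressions.

The central design is a 2 (group: typical vs dyslexic, between subjects)
x 2 (condition: baseline vs task, within subjects) mixed ANOVA applied to
each band-level outcome (mean total PLI, each MST metric, relative power).
The ANOVA is computed from explicit sums of squares with effect-specific
error terms, so the partial eta-squared denominators are unambiguous:
the between-subjects error for the group effect, the subject x condition
error for the condition and interaction effects. Sphericity corrections
(Greenhouse-Geisser) apply to within factors with more than two levels
(the task's time-on-task bins); at two levels sphericity is trivial and
epsilon = 1.

Multiple comparisons across network metrics are handled with the
Benjamini-Hochberg false discovery rate, at q = 0.10 (and a stricter
q = 0.05) because the metrics are correlated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "StepwiseStep",
    "StepwiseModel",
    "mixed_anova_2x2",
    "rm_anova_gg",
    "gg_epsilon",
    "bh_fdr",
    "per_condition_group_test",
    "regress_pli_on_power",
    "stepwise_regression",
]


@dataclass
class AnovaResult:
    """One effect row of an ANOVA table."""

    effect: str
    F: float
    df: tuple[float, float]
    p: float
    partial_eta_sq: float
    gg_epsilon: float = 1.0


def _to_wide(
    data: pd.DataFrame, dv: str, subject: str, within: str
) -> tuple[pd.DataFrame, list]:
    """Pivot long data to one row per subject, one column per within level."""
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    levels = list(wide.columns)
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} subject(s) with incomplete within-"
            f"subject data: {list(incomplete)}",
            UserWarning,
            stacklevel=3,
        )
        wide = wide.dropna()
    return wide, levels


def gg_epsilon(centered: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from subject x level data.

    ``centered`` holds one row per subject and one column per within level,
    already centered on its cell means (group x level means for a mixed
    design). Epsilon is computed from the double-centered covariance matrix
    and lies in (1/(k-1), 1]; 1 means perfect sphericity.
    """
    k = centered.shape[1]
    if k <= 2:
        return 1.0
    s = np.cov(centered, rowvar=False)
    c = np.eye(k) - np.ones((k, k)) / k
    scs = c @ s @ c
    num = np.trace(scs) ** 2
    den = (k - 1) * np.trace(scs @ scs)
    if den <= 0:
        return 1.0
    return float(min(num / den, 1.0))


def mixed_anova_2x2(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within: str = "condition",
    between: str = "group",
    within_label: str | None = None,
    gg: bool = True,
) -> list[AnovaResult]:
    """Mixed-design ANOVA: one within factor, one between factor.

    Accepts long-format data with one row per subject x within-level.
    Subjects missing any within level are dropped with a warning. Works for
    any number of within levels (k = 2 for baseline/task; k = 4 for the
    time-on-task bins); with k > 2 and ``gg=True`` the within and
    interaction p-values use Greenhouse-Geisser corrected degrees of
    freedom, and the reported epsilon is attached to those rows.

    Returns rows for the within main effect, the between main effect and
    their interaction, each with its effect-specific partial eta squared.
    """
    wide, levels = _to_wide(data, dv, subject, within)
    k = len(levels)
    if k < 2:
        raise ValueError("within factor needs at least 2 levels")
    group_of = (
        data.drop_duplicates(subject).set_index(subject)[between].loc[wide.index]
    )
    group_labels = sorted(group_of.unique())
    if len(group_labels) < 2:
        raise ValueError("between factor needs at least 2 groups")
    y = wide.to_numpy(dtype=float)  # subjects x k
    n_total = y.shape[0]
    g_idx = [np.flatnonzero((group_of == g).to_numpy()) for g in group_labels]
    n_g = np.array([len(ix) for ix in g_idx])
    if np.any(n_g < 2):
        raise ValueError("each group needs at least 2 complete subjects")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[ix].mean() for ix in g_idx])

    # ---- between-subjects stratum (on subject means, scaled by k)
    ss_group = k * float(np.sum(n_g * (group_means - subj_means.mean()) ** 2))
    ss_between_err = k * float(
        sum(np.sum((subj_means[ix] - gm) ** 2) for ix, gm in zip(g_idx, group_means))
    )
    df_group = len(group_labels) - 1
    df_between_err = n_total - len(group_labels)

    # ---- within-subjects stratum (subject-centered deviations)
    # d[g, c] = within-group condition effect; weighted orthogonal split
    # into a condition main effect and the group x condition interaction
    cell = np.stack([y[ix].mean(axis=0) for ix in g_idx])  # groups x k
    d = cell - group_means[:, None]
    cond_effect = (n_g[:, None] * d).sum(axis=0) / n_total  # weighted mean per level
    ss_cond = float(n_total * np.sum(cond_effect**2))
    ss_inter = float(np.sum(n_g[:, None] * (d - cond_effect[None, :]) ** 2))
    resid = y - subj_means[:, None]
    for ix, dg in zip(g_idx, d):
        resid[ix] -= dg[None, :]
    ss_within_err = float(np.sum(resid**2))
    df_cond = k - 1
    df_inter = (len(group_labels) - 1) * (k - 1)
    df_within_err = (n_total - len(group_labels)) * (k - 1)

    # GG epsilon from cell-mean-centered data (pooled within groups)
    centered = y.copy()
    for ix, row in zip(g_idx, cell):
        centered[ix] -= row[None, :]
    eps = gg_epsilon(centered) if (gg and k > 2) else 1.0

    def row(effect, ss_eff, df_eff, ss_err, df_err, use_eps) -> AnovaResult:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err if df_err > 0 else np.nan
        f = ms_eff / ms_err if ms_err > 0 else 0.0
        e = eps if use_eps else 1.0
        p = float(sps.f.sf(f, df_eff * e, df_err * e)) if df_err > 0 else np.nan
        peta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        return AnovaResult(
            effect=effect,
            F=float(f),
            df=(df_eff, df_err),
            p=p,
            partial_eta_sq=float(peta),
            gg_epsilon=e,
        )

    wlabel = within_label or within
    return [
        row(wlabel, ss_cond, df_cond, ss_within_err, df_within_err, True),
        row(between, ss_group, df_group, ss_between_err, df_between_err, False),
        row(f"{wlabel} x {between}", ss_inter, df_inter, ss_within_err, df_within_err, True),
    ]


def rm_anova_gg(
    values: np.ndarray | pd.DataFrame,
    groups: pd.Series | np.ndarray | None = None,
    within_label: str = "bin",
) -> list[AnovaResult]:
    """Repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``values`` is subject x k (one column per within level, e.g. the four
    time-on-task bins). Rows with missing cells are dropped listwise with a
    warning. Without ``groups``, returns the within main effect only; with
    ``groups``, delegates to the mixed ANOVA and returns within, between
    and interaction rows. At k = 2 the test is the paired contrast and
    epsilon is exactly 1.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("values must be subjects x k with k >= 2")
    keep = ~np.isnan(arr).any(axis=1)
    if not keep.all():
        warnings.warn(
            f"listwise deletion of {int((~keep).sum())} subject(s) with "
            "missing cells",
            UserWarning,
            stacklevel=2,
        )
    arr = arr[keep]
    n, k = arr.shape

    if groups is not None:
        groups = np.asarray(groups)[keep]
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "level": np.tile(np.arange(k), n),
                "group": np.repeat(groups, k),
                "value": arr.ravel(),
            }
        )
        return mixed_anova_2x2(
            long, dv="value", subject="subject", within="level",
            between="group", within_label=within_label,
        )

    grand = arr.mean()
    subj_means = arr.mean(axis=1)
    level_means = arr.mean(axis=0)
    ss_level = float(n * np.sum((level_means - grand) ** 2))
    ss_err = float(
        np.sum((arr - subj_means[:, None] - level_means[None, :] + grand) ** 2)
    )
    df_level, df_err = k - 1, (n - 1) * (k - 1)
    eps = gg_epsilon(arr - level_means[None, :]) if k > 2 else 1.0
    ms_level, ms_err = ss_level / df_level, ss_err / df_err
    f = ms_level / ms_err if ms_err > 0 else 0.0
    p = float(sps.f.sf(f, df_level * eps, df_err * eps))
    return [
        AnovaResult(
            effect=within_label,
            F=float(f),
            df=(df_level, df_err),
            p=p,
            partial_eta_sq=float(ss_level / (ss_level + ss_err)) if ss_level + ss_err > 0 else 0.0,
            gg_epsilon=eps,
        )
    ]


def bh_fdr(pvals, q: float = 0.10) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``q``."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def per_condition_group_test(values, groups) -> AnovaResult:
    """One-way group comparison (F test) of per-subject scalars.

    For two groups this F equals the squared two-sample (pooled-variance)
    t statistic. Used as the follow-up contrast after a significant
    condition x group interaction, separately per condition.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least 2 subjects")
    f, p = sps.f_oneway(*samples)
    grand = values.mean()
    ss_b = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_w = sum(((s - s.mean()) ** 2).sum() for s in samples)
    return AnovaResult(
        effect="group",
        F=float(f),
        df=(len(labels) - 1, len(values) - len(labels)),
        p=float(p),
        partial_eta_sq=float(ss_b / (ss_b + ss_w)) if ss_b + ss_w > 0 else 0.0,
    )


def regress_pli_on_power(pli, relpow) -> tuple[float, float, float]:
    """OLS regression of per-subject PLI on relative power.

    Returns ``(R, R2, p)``: the signed correlation, its square and the
    two-sided p-value of the slope test.
    """
    pli = np.asarray(pli, dtype=float)
    relpow = np.asarray(relpow, dtype=float)
    if len(pli) != len(relpow) or len(pli) < 3:
        raise ValueError("need matched samples with n >= 3")
    if np.std(relpow) == 0:
        raise ValueError("zero-variance predictor")
    res = sps.linregress(relpow, pli)
    return float(res.rvalue), float(res.rvalue**2), float(res.pvalue)


@dataclass
class StepwiseStep:
    """One action of the stepwise procedure (Table-of-models row)."""

    action: str  # "add" or "remove"
    predictor: str
    adj_r2: float
    delta_r2: float
    f_change: float
    p_change: float


@dataclass
class StepwiseModel:
    """Final stepwise regression model and its step history."""

    steps: list[StepwiseStep]
    predictors: list[str]
    adj_r2: float
    se_estimate: float


def _ols(y: np.ndarray, X: np.ndarray):
    import statsmodels.api as sm

    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_regression(
    y,
    X: pd.DataFrame,
    p_in: float = 0.05,
    p_out: float = 0.10,
    max_steps: int = 50,
) -> StepwiseModel:
    """Forward-entry / backward-removal stepwise multiple linear regression.

    At each forward step the candidate with the smallest partial-F p-value
    enters if p < ``p_in``; after each entry, any retained predictor whose
    p-value exceeds ``p_out`` is removed (largest first). Iterates to a
    fixed point. The partial F for a single added predictor equals the
    squared t statistic of its coefficient. An empty model (no candidate
    ever passes entry) is a valid result.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X)
    if len(y) != len(X):
        raise ValueError("y and X must have equal length")
    if len(y) <= X.shape[1] + 1:
        warnings.warn(
            "fewer observations than candidates + 2; stepwise selection is "
            "unstable",
            UserWarning,
            stacklevel=2,
        )

    included: list[str] = []
    steps: list[StepwiseStep] = []
    r2_prev = 0.0

    def fit(cols):
        if cols:
            return _ols(y, X[cols].to_numpy())
        return _ols(y, np.empty((len(y), 0)))

    ss_total = float(np.sum((y - y.mean()) ** 2))
    for _ in range(max_steps):
        changed = False
        # stop once the fit is numerically perfect; further partial-F tests
        # on near-zero residuals are meaningless
        if included and fit(included).ssr <= 1e-12 * max(ss_total, 1e-300):
            break
        # forward
        candidates = [c for c in X.columns if c not in included]
        best = None
        for c in candidates:
            m = fit(included + [c])
            pv = m.pvalues[-1]
            if np.isnan(pv):
                continue
            if best is None or pv < best[1]:
                best = (c, float(pv), m)
        if best is not None and best[1] < p_in:
            c, pv, m = best
            included.append(c)
            tstat = m.tvalues[-1]
            steps.append(
                StepwiseStep(
                    action="add",
                    predictor=c,
                    adj_r2=float(m.rsquared_adj),
                    delta_r2=float(m.rsquared - r2_prev),
                    f_change=float(tstat**2),
                    p_change=pv,
                )
            )
            r2_prev = float(m.rsquared)
            changed = True
        # backward
        while included:
            m = fit(included)
            pvals = m.pvalues[1:]  # skip intercept
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_out:
                c = included.pop(worst)
                m2 = fit(included)
                steps.append(
                    StepwiseStep(
                        action="remove",
                        predictor=c,
                        adj_r2=float(m2.rsquared_adj),
                        delta_r2=float(m2.rsquared - r2_prev),
                        f_change=float(m.tvalues[1 + worst] ** 2),
                        p_change=float(pvals[worst]),
                    )
                )
                r2_prev = float(m2.rsquared)
                changed = True
            else:
                break
        if not changed:
            break

    final = fit(included)
    resid_df = max(int(final.df_resid), 1)
    se = float(np.sqrt(np.sum(final.resid**2) / resid_df))
    return StepwiseModel(
        steps=steps,
        predictors=list(included),
        adj_r2=float(final.rsquared_adj) if included else 0.0,
        se_estimate=se,
    )
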