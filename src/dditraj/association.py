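"""Trajectory-group versus mortality association analyses.

Covers the downstream statistics once patients carry a trajectory-group
label: univariate screening of baseline covariates against in-hospital
death, collinearity screening (VIF and pairwise rank correlation), the
multivariable logistic model with group 1 as reference, a sensitivity refit
swapping abdominal AIS for ISS, contingency-table odds ratios with Wald
intervals, rank-based AUC, and group-comparison summary tables with
Benjamini-Hochberg-adjusted pairwise tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

from dditraj.errors import ValidationError

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054


@dataclass
class AssociationResult:
    """Bundle of screening, model and discrimination outputs."""

    screened: pd.DataFrame
    collinearity: pd.DataFrame
    univariate_or: pd.DataFrame
    multivariable_or: pd.DataFrame
    sensitivity_or: pd.DataFrame | None = None
    auc_trajectory: float | None = None
    auc_triss: float | None = None
    warnings: list[str] = field(default_factory=list)


def _is_categorical(s: pd.Series) -> bool:
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) \
            or s.dtype == bool:
        return True
    vals = s.dropna().unique()
    return len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


def univariate_screen(covariates: pd.DataFrame, outcome: pd.Series,
                      alpha: float = 0.1) -> pd.DataFrame:
    """Per-variable association with the binary outcome.

    Continuous variables use a single-predictor logistic regression (Wald
    p); categorical variables use a chi-square test, or Fisher's exact test
    for 2x2 tables with any expected cell below 5.  Variables with p below
    ``alpha`` are flagged as candidates; constant variables are excluded
    with a warning.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    rows = []
    for col in covariates.columns:
        s = covariates[col]
        if s.nunique(dropna=True) <= 1:
            warnings.warn(f"covariate {col!r} is constant; excluded",
                          RuntimeWarning, stacklevel=2)
            rows.append({"variable": col, "kind": "constant",
                         "p": np.nan, "candidate": False})
            continue
        if _is_categorical(s):
            table = pd.crosstab(s, outcome)
            expected = stats.contingency.expected_freq(table.to_numpy())
            if table.shape == (2, 2) and (expected < 5).any():
                _, p = stats.fisher_exact(table.to_numpy())
                kind = "fisher"
            else:
                _, p, _, _ = stats.chi2_contingency(table.to_numpy())
                kind = "chi2"
        else:
            X = sm.add_constant(np.asarray(s, dtype=float))
            fit = sm.Logit(y, X).fit(disp=0)
            p = float(fit.pvalues[1])
            kind = "logistic"
        rows.append({"variable": col, "kind": kind, "p": float(p),
                     "candidate": bool(p < alpha)})
    out = pd.DataFrame(rows)
    logger.info("univariate screen kept %d of %d covariates at alpha=%.2f",
                int(out["candidate"].sum()), len(out), alpha)
    return out


def collinearity_screen(candidates: pd.DataFrame,
                        univariate_p: dict[str, float] | None = None,
                        vif_threshold: float = 10.0,
                        r_threshold: float = 0.5) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop collinear candidates; return retained set + report.

    A pair is flagged when |Spearman r| exceeds ``r_threshold`` with p<0.05;
    the member with the larger univariate p (weaker outcome association) is
    dropped.  Any variable whose VIF on the remaining design reaches
    ``vif_threshold`` is likewise dropped (largest first).  Repeats until
    the design is clean.
    """
    if candidates.shape[1] < 2:
        report = pd.DataFrame(columns=["variable", "vif", "dropped", "reason"])
        return list(candidates.columns), report
    univariate_p = univariate_p or {}
    kept = list(candidates.columns)
    dropped: list[tuple[str, str]] = []

    def weaker(a: str, b: str) -> str:
        return a if univariate_p.get(a, 0.5) >= univariate_p.get(b, 0.5) else b

    changed = True
    while changed and len(kept) > 1:
        changed = False
        X = candidates[kept].astype(float)
        # pairwise rank correlations
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                r, p = stats.spearmanr(X.iloc[:, i], X.iloc[:, j])
                if abs(r) > r_threshold and p < 0.05:
                    victim = weaker(kept[i], kept[j])
                    dropped.append((victim, f"|r|={abs(r):.2f} with "
                                    f"{kept[j] if victim == kept[i] else kept[i]}"))
                    kept.remove(victim)
                    changed = True
                    break
            if changed:
                break
        if changed or len(kept) < 2:
            continue
        design = sm.add_constant(candidates[kept].astype(float).to_numpy())
        try:
            vifs = np.array([variance_inflation_factor(design, k + 1)
                             for k in range(len(kept))])
        except np.linalg.LinAlgError:
            vifs = np.full(len(kept), np.inf)
        if np.any(~np.isfinite(vifs)) or vifs.max() >= vif_threshold:
            worst = int(np.nanargmax(np.where(np.isfinite(vifs), vifs, np.inf)))
            dropped.append((kept[worst], f"VIF={vifs[worst]:.1f}"))
            warnings.warn(f"dropping {kept[worst]!r}: {dropped[-1][1]}",
                          RuntimeWarning, stacklevel=2)
            kept.pop(worst)
            changed = True

    final_vif = np.full(len(kept), np.nan)
    if len(kept) >= 2:
        design = sm.add_constant(candidates[kept].astype(float).to_numpy())
        final_vif = np.array([variance_inflation_factor(design, k + 1)
                              for k in range(len(kept))])
    report = pd.DataFrame({
        "variable": kept + [d[0] for d in dropped],
        "vif": list(final_vif) + [np.nan] * len(dropped),
        "dropped": [False] * len(kept) + [True] * len(dropped),
        "reason": [""] * len(kept) + [d[1] for d in dropped],
    })
    return kept, report


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> dict:
    """Odds ratio with Wald 95% CI and p from a 2x2 table.

    Layout: exposed events a, exposed non-events b, reference events c,
    reference non-events d.  Zero cells trigger a 0.5 continuity correction
    applied to all four cells, flagged in the result.
    """
    counts = np.array([a, b, c, d], dtype=float)
    if np.any(counts < 0):
        raise ValidationError("cell counts must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValidationError("empty exposure margin")
    corrected = bool(np.any(counts == 0))
    if corrected:
        counts = counts + 0.5
    a_, b_, c_, d_ = counts
    or_ = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    lo, hi = np.exp(np.log(or_) + np.array([-1, 1]) * Z975 * se)
    z = np.log(or_) / se
    p = 2 * stats.norm.sf(abs(z))
    return {"or": float(or_), "ci_lo": float(lo), "ci_hi": float(hi),
            "p": float(p), "continuity_corrected": corrected}


def univariate_group_ors(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-group odds ratios versus group 1 from a deaths/total count table."""
    ref = counts[counts["group"] == 1].iloc[0]
    rows = [{"group": 1, "or": 1.0, "ci_lo": np.nan, "ci_hi": np.nan,
             "p": np.nan}]
    for _, row in counts[counts["group"] != 1].iterrows():
        res = odds_ratio_2x2(row["deaths"], row["total"] - row["deaths"],
                             ref["deaths"], ref["total"] - ref["deaths"])
        rows.append({"group": int(row["group"]), **{k: res[k] for k in
                                                    ("or", "ci_lo", "ci_hi", "p")}})
    return pd.DataFrame(rows)


def fit_multivariable(outcome: pd.Series, group: pd.Series,
                      adjusters: pd.DataFrame | None = None
                      ) -> tuple[pd.DataFrame, object]:
    """Multivariable logistic model of death on trajectory group.

    Group enters as a categorical factor with group 1 as reference;
    adjusters enter linearly.  Returns per-group odds ratios with Wald 95%
    CIs and the statsmodels results object.  Complete-separation symptoms
    (huge coefficients or non-convergence) flag the affected CI as
    unreliable rather than raising.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome is single-class; logistic fit undefined")
    g = np.asarray(group)
    levels = np.unique(g)
    dummies = pd.DataFrame(
        {f"group_{lv}": (g == lv).astype(float) for lv in levels[1:]})
    X = dummies
    if adjusters is not None and adjusters.shape[1] > 0:
        X = pd.concat([dummies.reset_index(drop=True),
                       adjusters.reset_index(drop=True).astype(float)], axis=1)
    X = sm.add_constant(X)
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    separation = any("separation" in str(w.message).lower() for w in wrec) \
        or not fit.mle_retvals.get("converged", True) \
        or np.any(np.abs(fit.params.to_numpy()) > 15)
    if separation:
        warnings.warn("possible separation: Wald CIs unreliable",
                      RuntimeWarning, stacklevel=2)
    ci = fit.conf_int()
    rows = [{"group": int(levels[0]), "or": 1.0, "ci_lo": np.nan,
             "ci_hi": np.nan, "p": np.nan, "unreliable": False}]
    for lv in levels[1:]:
        name = f"group_{lv}"
        rows.append({
            "group": int(lv),
            "or": float(np.exp(fit.params[name])),
            "ci_lo": float(np.exp(ci.loc[name, 0])),
            "ci_hi": float(np.exp(ci.loc[name, 1])),
            "p": float(fit.pvalues[name]),
            "unreliable": bool(separation),
        })
    return pd.DataFrame(rows), fit


def sensitivity_swap(outcome: pd.Series, group: pd.Series,
                     adjusters: pd.DataFrame, swap_out: str = "ais_abdomen",
                     swap_in_col: pd.Series | None = None,
                     swap_in: str = "iss") -> dict[str, pd.DataFrame]:
    """Refit the multivariable model replacing one adjuster with another.

    Default: abdominal AIS out, ISS in.  Returns both fitted tables side by
    side under keys ``primary`` and ``sensitivity``.
    """
    if swap_out not in adjusters.columns:
        raise ValidationError(f"adjuster {swap_out!r} not present")
    if swap_in_col is None:
        raise ValidationError(f"replacement column {swap_in!r} not supplied")
    primary, _ = fit_multivariable(outcome, group, adjusters)
    swapped = adjusters.drop(columns=[swap_out]).copy()
    swapped[swap_in] = np.asarray(swap_in_col, dtype=float)
    sens, _ = fit_multivariable(outcome, group, swapped)
    return {"primary": primary, "sensitivity": sens}


def auc(scores, outcome) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Ties between an event and a non-event score receive half credit, which
    matches the trapezoidal area under the empirical ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs at least one event and one non-event")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def group_comparison_table(covariates: pd.DataFrame, labels: pd.Series,
                           pairwise_alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable group comparison summary.

    Continuous variables: median (IQR) per group, Shapiro-Wilk normality p,
    Kruskal-Wallis omnibus p.  Categorical variables: n (%) per group,
    chi-square omnibus (Fisher for 2x2 with small expected counts).  When
    the omnibus is significant, all pairwise tests are run and adjusted by
    Benjamini-Hochberg; the smallest adjusted pairwise p is reported.
    """
    g = np.asarray(labels)
    groups = np.unique(g)
    if len(groups) < 2:
        raise ValidationError("need at least two groups to compare")
    rows = []
    for col in covariates.columns:
        s = covariates[col]
        empty = [lv for lv in groups if (g == lv).sum() == 0]
        use_groups = [lv for lv in groups if lv not in empty]
        row: dict = {"variable": col}
        if _is_categorical(s):
            sn = s.astype(str)
            pos = None
            if sn.nunique() == 2:
                lv_set = set(sn.unique())
                pos = "1" if "1" in lv_set else (
                    "True" if "True" in lv_set else sorted(lv_set)[-1])
            for lv in use_groups:
                sub = sn[g == lv]
                if pos is not None:
                    n_hit = int((sub == pos).sum())
                    row[f"group_{lv}"] = f"{n_hit} ({100 * n_hit / len(sub):.2f})"
                else:
                    row[f"group_{lv}"] = f"n={len(sub)}"
            table = pd.crosstab(sn, pd.Series(g, index=s.index))
            expected = stats.contingency.expected_freq(table.to_numpy())
            if table.shape == (2, 2) and (expected < 5).any():
                _, p = stats.fisher_exact(table.to_numpy())
                row["test"] = "fisher"
            else:
                _, p, _, _ = stats.chi2_contingency(table.to_numpy())
                row["test"] = "chi2"
            row["p"] = float(p)
            if p < pairwise_alpha and len(use_groups) > 2:
                pair_p = []
                pairs = [(i, j) for k, i in enumerate(use_groups)
                         for j in use_groups[k + 1:]]
                for i, j in pairs:
                    sub_mask = (g == i) | (g == j)
                    t = pd.crosstab(sn[sub_mask].to_numpy(), g[sub_mask])
                    if t.shape == (2, 2):
                        _, pp = stats.fisher_exact(t.to_numpy())
                    else:
                        _, pp, _, _ = stats.chi2_contingency(t.to_numpy())
                    pair_p.append(pp)
                row["min_pairwise_p_bh"] = float(bh_adjust(pair_p).min())
        else:
            x = s.astype(float)
            for lv in use_groups:
                sub = x[g == lv]
                q1, q2, q3 = np.percentile(sub, [25, 50, 75])
                row[f"group_{lv}"] = f"{q2:.2f} ({q1:.2f}, {q3:.2f})"
            samples = [x[g == lv].to_numpy() for lv in use_groups]
            _, p = stats.kruskal(*samples)
            row["test"] = "kruskal"
            row["p"] = float(p)
            sw = stats.shapiro(x.sample(min(len(x), 500), random_state=0))
            row["shapiro_p"] = float(sw.pvalue)
            if p < pairwise_alpha:
                pair_p = []
                pairs = [(i, j) for k, i in enumerate(use_groups)
                         for j in use_groups[k + 1:]]
                for i, j in pairs:
                    _, pp = stats.mannwhitneyu(x[g == i], x[g == j])
                    pair_p.append(pp)
                row["min_pairwise_p_bh"] = float(bh_adjust(pair_p).min())
        if empty:
            row["note"] = f"empty groups excluded: {empty}"
            warnings.warn(f"{col}: empty groups excluded {empty}",
                          RuntimeWarning, stacklevel=2)
        rows.append(row)
    return pd.DataFrame(rows)
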