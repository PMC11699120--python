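"""Descriptive and univariable inferential statistics for resorption cohorts.

Patient-level associations use ordinary logistic regression; condyle-level
associations (two condyles nested per patient) use generalized estimating
equations with an independent working correlation, whose point estimates
coincide with the ordinary fit while variances come from the cluster-robust
sandwich estimator. Confidence intervals are Wald (exp(beta +/- 1.96 SE)),
which for a categorical predictor reproduce the classic contingency-table
cross-product ratios and their log-scale standard errors exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "LogisticFit",
    "GroupComparison",
    "describe",
    "univariable_logistic",
    "univariable_logistic_from_counts",
    "gee_logistic",
    "gee_logistic_from_counts",
    "compare_groups",
]

Z95 = sps.norm.ppf(0.975)


@dataclass
class LogisticFit:
    """Per-level (or per-unit) odds ratios with Wald 95% CIs and p-values."""

    table: pd.DataFrame  # index: level or variable name; columns: odds_ratio, ci_low, ci_high, se_log, p_value
    reference: str | None = None
    clustering: str = "none"
    separated_levels: list = field(default_factory=list)

    def odds_ratio(self, level=None) -> float:
        if level is None:
            level = self.table.index[0]
        return float(self.table.loc[level, "odds_ratio"])

    def ci(self, level=None) -> tuple[float, float]:
        if level is None:
            level = self.table.index[0]
        row = self.table.loc[level]
        return float(row["ci_low"]), float(row["ci_high"])


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test_used: str  # "anova" | "kruskal_wallis"
    p_value: float
    normality_p: dict


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

def describe(records: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary: mean (sd) and median [IQR] for continuous variables,
    n (%) for categoricals. Quartiles use linear interpolation."""
    if len(records) == 0:
        raise ValueError("empty input")
    rows = []
    n = len(records)
    for col in records.columns:
        s = records[col]
        if pd.api.types.is_numeric_dtype(s) and not pd.api.types.is_bool_dtype(s):
            q1, med, q3 = np.percentile(s.dropna(), [25, 50, 75])
            rows.append(
                {
                    "variable": col, "type": "continuous",
                    "mean": s.mean(), "sd": s.std(ddof=1) if n > 1 else 0.0,
                    "median": med, "q1": q1, "q3": q3,
                    "summary": f"{s.mean():.1f} ({(s.std(ddof=1) if n > 1 else 0.0):.1f}) | "
                               f"{med:.1f} [{q1:.1f}, {q3:.1f}]",
                }
            )
        else:
            for level, count in s.value_counts().items():
                rows.append(
                    {
                        "variable": f"{col}={level}", "type": "categorical",
                        "count": int(count), "pct": 100.0 * count / n,
                        "summary": f"{count} ({100.0 * count / n:.1f}%)",
                    }
                )
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# univariable logistic regression
# ---------------------------------------------------------------------------

def _design(predictor: pd.Series, reference: str | None):
    """Design matrix with intercept; categorical predictors are dummy-coded."""
    if pd.api.types.is_numeric_dtype(predictor) and not pd.api.types.is_bool_dtype(predictor):
        X = pd.DataFrame({"const": 1.0, str(predictor.name or "x"): predictor.astype(float)})
        return X, None, [str(predictor.name or "x")]
    cat = predictor.astype("category")
    levels = list(cat.cat.categories)
    if reference is None:
        reference = predictor.value_counts().idxmax()
    others = [l for l in levels if l != reference]
    X = pd.DataFrame({"const": np.ones(len(predictor))}, index=predictor.index)
    for l in others:
        X[str(l)] = (predictor == l).astype(float)
    return X, reference, [str(l) for l in others]


def _zero_cells(outcome: pd.Series, predictor: pd.Series, levels) -> dict:
    """Levels with an empty event or non-event cell (complete separation)."""
    out = {}
    for l in levels:
        sel = predictor.astype(str) == str(l)
        ev = int(outcome[sel].sum())
        ne = int(sel.sum()) - ev
        if ev == 0:
            out[str(l)] = "zero_events"
        elif ne == 0:
            out[str(l)] = "zero_nonevents"
    return out


def _fit_table(params, se, names) -> pd.DataFrame:
    or_ = np.exp(params)
    lo = np.exp(params - Z95 * se)
    hi = np.exp(params + Z95 * se)
    p = 2 * sps.norm.sf(np.abs(params / se))
    return pd.DataFrame(
        {"odds_ratio": or_, "ci_low": lo, "ci_high": hi, "se_log": se, "p_value": p},
        index=names,
    )


def univariable_logistic(
    outcome,
    predictor,
    reference: str | None = None,
    freq_weights=None,
) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome on one
    predictor (IRLS, tolerance 1e-10), with Wald 95% intervals.

    Completely separated categorical levels are reported as OR 0 (or inf)
    with an infinite confidence interval instead of failing.
    """
    outcome = pd.Series(outcome).astype(int).reset_index(drop=True)
    predictor = pd.Series(predictor).reset_index(drop=True)
    if outcome.nunique() < 2:
        raise ValueError("both outcome classes must be present")
    X, ref, names = _design(predictor, reference)

    separated = {}
    if ref is not None:
        w = np.ones(len(outcome)) if freq_weights is None else np.asarray(freq_weights, float)
        separated = _zero_cells_weighted(outcome, predictor, names + [ref], w)
        if str(ref) in separated:
            raise ValueError("reference level is completely separated; choose another reference")

    fit_names = [n for n in names if n not in separated]
    cols = ["const"] + fit_names
    keep = ~predictor.astype(str).isin(separated).to_numpy() if separated else np.ones(len(outcome), bool)
    w = None if freq_weights is None else np.asarray(freq_weights, float)[keep]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(
            outcome.to_numpy()[keep],
            X[cols].to_numpy()[keep],
            family=sm.families.Binomial(),
            freq_weights=w,
        )
        result = model.fit(tol=1e-10, maxiter=200)

    params = result.params[1:]
    se = result.bse[1:]
    table = _fit_table(params, se, fit_names)
    for l, kind in separated.items():
        table.loc[l] = {
            "odds_ratio": 0.0 if kind == "zero_events" else np.inf,
            "ci_low": 0.0,
            "ci_high": np.inf,
            "se_log": np.inf,
            "p_value": 1.0,
        }
    table = table.reindex(names) if names else table
    return LogisticFit(table=table, reference=ref, clustering="none",
                       separated_levels=sorted(separated))


def _zero_cells_weighted(outcome, predictor, levels, w) -> dict:
    out = {}
    pred = predictor.astype(str)
    for l in levels:
        sel = (pred == str(l)).to_numpy()
        ev = float((outcome.to_numpy() * w)[sel].sum())
        tot = float(w[sel].sum())
        if ev == 0:
            out[str(l)] = "zero_events"
        elif tot - ev == 0:
            out[str(l)] = "zero_nonevents"
    return out


def _expand_counts(levels, events, nonevents):
    """Long outcome/predictor/weight vectors from contingency counts."""
    ys, ls, ws = [], [], []
    for lvl, ev, ne in zip(levels, events, nonevents):
        if ev > 0:
            ys.append(1); ls.append(lvl); ws.append(ev)
        if ne > 0:
            ys.append(0); ls.append(lvl); ws.append(ne)
    return pd.Series(ys), pd.Series(ls, dtype="object"), np.asarray(ws, dtype=float)


def univariable_logistic_from_counts(levels, events, nonevents, reference) -> LogisticFit:
    """Fit from contingency counts (events / non-events per predictor level).

    For a saturated categorical model the ML odds ratios equal the
    cross-product ratios of the table.
    """
    y, pred, w = _expand_counts(levels, events, nonevents)
    return univariable_logistic(y, pred, reference=reference, freq_weights=w)


def gee_logistic(outcome, predictor, cluster_id, reference: str | None = None) -> LogisticFit:
    """Marginal logistic regression for clustered condyle-level outcomes.

    Independent working correlation: point estimates solve the ordinary
    estimating equations; standard errors come from the cluster-robust
    sandwich estimator.
    """
    outcome = pd.Series(outcome).astype(int).reset_index(drop=True)
    predictor = pd.Series(predictor).reset_index(drop=True)
    cluster_id = pd.Series(cluster_id).reset_index(drop=True)
    if outcome.nunique() < 2:
        raise ValueError("both outcome classes must be present")
    if cluster_id.nunique() < 2:
        raise ValueError("need at least two clusters")
    X, ref, names = _design(predictor, reference)

    separated = {}
    if ref is not None:
        separated = _zero_cells(outcome, predictor, names + [ref])
        if str(ref) in separated:
            raise ValueError("reference level is completely separated; choose another reference")
    fit_names = [n for n in names if n not in separated]
    cols = ["const"] + fit_names
    keep = ~predictor.astype(str).isin(separated).to_numpy() if separated else np.ones(len(outcome), bool)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(
            outcome.to_numpy()[keep],
            X[cols].to_numpy()[keep],
            groups=cluster_id.to_numpy()[keep],
            family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Independence(),
        )
        result = model.fit(maxiter=200, ctol=1e-10)

    table = _fit_table(result.params[1:], result.bse[1:], fit_names)
    for l, kind in separated.items():
        table.loc[l] = {
            "odds_ratio": 0.0 if kind == "zero_events" else np.inf,
            "ci_low": 0.0, "ci_high": np.inf, "se_log": np.inf, "p_value": 1.0,
        }
    table = table.reindex(names) if names else table
    return LogisticFit(table=table, reference=ref, clustering="patient",
                       separated_levels=sorted(separated))


def gee_logistic_from_counts(levels, events, nonevents, reference) -> LogisticFit:
    """GEE fit from condyle-level contingency counts.

    Cluster membership is not recoverable from a printed table, so each
    condyle is its own cluster; under the independence working correlation
    the point estimates are unaffected by the clustering.
    """
    y, pred, w = _expand_counts(levels, events, nonevents)
    rows_y, rows_p = [], []
    for yi, pi, wi in zip(y, pred, w):
        rows_y.extend([yi] * int(wi))
        rows_p.extend([pi] * int(wi))
    clusters = np.arange(len(rows_y))
    return gee_logistic(pd.Series(rows_y), pd.Series(rows_p, dtype="object"), clusters,
                        reference=reference)


# ---------------------------------------------------------------------------
# group comparison with a normality gate
# ---------------------------------------------------------------------------

def compare_groups(values, group_labels, variable: str = "value", alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA if every group passes Shapiro-Wilk at ``alpha``,
    otherwise Kruskal-Wallis."""
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = [values[group_labels == g] for g in np.unique(group_labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 3 for g in groups):
        raise ValueError("each group needs at least 3 values")
    if any(np.ptp(g) == 0 for g in groups):
        raise ValueError("degenerate (constant) group")
    normality = {}
    for g, label in zip(groups, np.unique(group_labels)):
        normality[str(label)] = float(sps.shapiro(g).pvalue)
    if all(p > alpha for p in normality.values()):
        res = sps.f_oneway(*groups)
        p = float(res.pvalue)
        if np.isnan(p) and res.statistic <= 0:
            p = 1.0  # between-group variance vanished to rounding error
        test = "anova"
    else:
        test, p = "kruskal_wallis", float(sps.kruskal(*groups).pvalue)
    return GroupComparison(variable=variable, test_used=test, p_value=p, normality_p=normality)
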