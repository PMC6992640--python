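"""Expression summaries by intrinsic subtype, clinical correlation panels,
median-split quadrant grouping, and Kaplan-Meier / log-rank outcome comparison.

The cohort container pairs a samples-by-genes expression frame (TPM or
log-intensity) with per-sample subtype labels and clinical covariates.
Stratification crosses two genes' strict median splits into hh/hl/lh/ll
quadrants, whose time-to-event outcomes are compared by the product-limit
estimator and the log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DegenerateTestError, InsufficientDataError, ValidationError

SUBTYPES = ("Basal", "Claudin", "LumA", "LumB", "Her2", "Normal")

QUADRANTS = ("hh", "hl", "lh", "ll")


@dataclass(frozen=True)
class ExpressionCohort:
    """Expression values with subtype labels and clinical covariates.

    ``expression`` is samples x genes (non-negative); ``subtype`` a
    per-sample label series; ``clinical`` a per-sample covariate frame
    (binary status variables encoded 0/1).
    """

    expression: pd.DataFrame
    subtype: pd.Series
    clinical: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.expression.index.duplicated().any():
            raise ValidationError("duplicate sample labels in expression matrix")
        missing = self.expression.index.difference(self.subtype.index)
        if len(missing):
            raise ValidationError(f"samples missing subtype labels: {list(missing[:5])}")

    @property
    def samples(self) -> pd.Index:
        return self.expression.index

    def gene(self, name: str) -> pd.Series:
        if name not in self.expression.columns:
            raise ValidationError(f"unknown gene {name!r}")
        return self.expression[name]


def subtype_summary(cohort: ExpressionCohort, gene: str) -> pd.DataFrame:
    """Per-subtype mean, min and max expression of *gene*.

    Matches the marker-and-range presentation of subtype-averaged
    expression: mean is the marker, (min, max) the bars.
    """
    values = cohort.gene(gene)
    df = pd.DataFrame({"value": values, "subtype": cohort.subtype.loc[values.index]})
    out = (
        df.groupby("subtype", sort=False)["value"]
        .agg(mean="mean", min="min", max="max", n="size")
        .reset_index()
    )
    order = [s for s in SUBTYPES if s in set(out["subtype"])]
    extra = [s for s in out["subtype"] if s not in SUBTYPES]
    return out.set_index("subtype").loc[order + extra].reset_index()


def tukey_all_pairs(values: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Tukey HSD adjusted p-values for all group pairs.

    Uses the studentized-range distribution; symmetric in pair order.
    """
    if len(values) < 2:
        raise InsufficientDataError("Tukey comparison needs >= 2 groups")
    for g, v in values.items():
        if len(v) < 2:
            raise InsufficientDataError(f"group {g!r} has fewer than 2 samples")
    data = np.concatenate([np.asarray(v, dtype=float) for v in values.values()])
    groups = np.concatenate([[g] * len(v) for g, v in values.items()])
    res = pairwise_tukeyhsd(data, groups)
    labels = list(res.groupsunique)
    pairs = [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    return pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "mean_diff": res.meandiffs,
            "p_adj": res.pvalues,
            "lower": res.confint[:, 0],
            "upper": res.confint[:, 1],
            "reject": res.reject,
        }
    )


def correlation_panel(
    cohort: ExpressionCohort,
    genes: Sequence[str],
    params: Sequence[str] = (),
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix over genes and covariates.

    Binary clinical covariates are consumed as 0/1, making the gene-status
    cells point-biserial correlations.  Cells where either variable is
    constant (or fewer than 3 complete pairs exist) are NaN.
    """
    cols = {}
    for g in genes:
        cols[g] = cohort.gene(g).astype(float)
    if params:
        if cohort.clinical is None:
            raise ValidationError("cohort has no clinical covariates")
        for p in params:
            if p not in cohort.clinical.columns:
                raise ValidationError(f"unknown clinical parameter {p!r}")
            cols[p] = cohort.clinical[p].astype(float)
    frame = pd.DataFrame(cols)
    labels = list(frame.columns)
    n = len(labels)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            pair = frame.iloc[:, [i, j]].dropna()
            if len(pair) < 3:
                continue
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r = float(stats.pearsonr(x, y).statistic)
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=labels, columns=labels)


def median_split(values: pd.Series) -> pd.Series:
    """Strict top-half / bottom-half split: 'high' for the top floor(N/2) samples.

    Samples are ordered by (value, label); ties at the median resolve to the
    low group, deterministically.  For even N the split is exactly N/2 each.
    """
    order = values.to_frame("v").assign(label=values.index.astype(str))
    order = order.sort_values(["v", "label"], kind="mergesort")
    n_high = len(order) // 2
    labels = pd.Series("low", index=values.index, dtype=object)
    labels.loc[order.index[len(order) - n_high:]] = "high"
    return labels


def median_split_quadrants(
    cohort: ExpressionCohort, gene1: str, gene2: str
) -> pd.Series:
    """Cross the two genes' median splits into hh/hl/lh/ll quadrants."""
    if len(cohort.samples) < 4:
        raise InsufficientDataError("quadrant split needs >= 4 samples")
    s1 = median_split(cohort.gene(gene1))
    s2 = median_split(cohort.gene(gene2))
    code = {"high": "h", "low": "l"}
    return pd.Series(
        [code[s1[s]] + code[s2[s]] for s in cohort.samples],
        index=cohort.samples,
        name="quadrant",
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def _validate_survival(times: Sequence[float], events: Sequence[bool]) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise InsufficientDataError("no subjects")
    if t.size != e.size:
        raise ValidationError("times and events must align")
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValidationError("times must be finite and non-negative")
    return t, e


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate for one group.

    Returns a step function as a frame with columns ``time`` and
    ``survival``; right-continuous, non-increasing, S(0) = 1.
    """
    t, e = _validate_survival(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank_test(
    groups: Mapping[str, tuple[Sequence[float], Sequence[bool]]]
) -> tuple[float, int, float]:
    """K-sample log-rank test; returns (chi-square, df, p).

    Invariant under group relabeling; undefined (raises) with zero events.
    """
    if len(groups) < 2:
        raise InsufficientDataError("log-rank test needs >= 2 groups")
    all_t, all_e, all_g = [], [], []
    for label in sorted(groups):
        t, e = _validate_survival(*groups[label])
        all_t.append(t)
        all_e.append(e)
        all_g.append(np.repeat(label, t.size))
    t = np.concatenate(all_t)
    e = np.concatenate(all_e)
    g = np.concatenate(all_g)
    if not e.any():
        raise DegenerateTestError("log-rank test undefined with zero events")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), int(res.degrees_of_freedom), float(res.p_value)


def pairwise_logrank(
    groups: Mapping[str, tuple[Sequence[float], Sequence[bool]]],
    adjust: str | None = None,
) -> pd.DataFrame:
    """Log-rank test for every group pair; unadjusted p-values by default.

    ``adjust='holm'`` adds a Holm-corrected column for users who want
    family-wise control across the quadrant pairs.
    """
    labels = sorted(groups)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            try:
                chi2, df, p = logrank_test({a: groups[a], b: groups[b]})
            except DegenerateTestError:
                chi2, df, p = float("nan"), 1, float("nan")
            rows.append({"group1": a, "group2": b, "chi2": chi2, "df": df, "p_value": p})
    out = pd.DataFrame(rows)
    if adjust == "holm" and len(out):
        from statsmodels.stats.multitest import multipletests

        mask = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(out.loc[mask, "p_value"], method="holm")[1]
        out["p_holm"] = adj
    return out


def quadrant_survival(
    quadrants: pd.Series,
    survival: pd.DataFrame,
    endpoint: str,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Group a survival-schema frame by quadrant label for one endpoint."""
    sub = survival[survival["endpoint"] == endpoint]
    if sub.empty:
        raise ValidationError(f"no rows for endpoint {endpoint!r}")
    sub = sub.set_index("sample")
    groups: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for q in QUADRANTS:
        samples = quadrants.index[quadrants == q]
        present = [s for s in samples if s in sub.index]
        if not present:
            continue
        rows = sub.loc[present]
        groups[q] = (
            rows["time_months"].to_numpy(dtype=float),
            rows["event"].to_numpy(dtype=bool),
        )
    return groups
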