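"""Single-dose supra-additivity screen: the delta statistic and cross-model summary.

For an anchor+partner pair tested at fixed single doses, the departure from
effect-sum additivity is

    delta = (percent inhibition of combination)
            - [(percent inhibition of drug 1 alone) + (percent inhibition of drug 2 alone)]

delta > 0 is a supra-additive trend, delta = 0 additive, delta < 0
sub-additive.  Inhibition values outside [0, 100] are retained — the
formula is closed under them and negative inhibition carries reporter
artifact information.  Note this reference is the plain effect sum, not
Bliss independence: a Bliss-independent pair scores delta = -100·i1·i2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InsufficientDataError, ValidationError


@dataclass(frozen=True)
class ComboScreenRecord:
    """One anchor+partner combination in one tumor model."""

    model_id: str
    anchor_drug: str
    partner_drug: str
    inhib_combo: float
    inhib_anchor: float
    inhib_partner: float

    @property
    def delta(self) -> float:
        return self.inhib_combo - (self.inhib_anchor + self.inhib_partner)

    @property
    def trend(self) -> str:
        d = self.delta
        return "supra" if d > 0 else ("sub" if d < 0 else "additive")


@dataclass(frozen=True)
class CrossModelSummary:
    """Delta aggregated over tumor models for one drug pair.

    ``degenerate_variance`` marks an all-identical delta vector, for which
    the one-sample t-test is undefined; ``t_stat``/``p_value`` are then
    ``nan`` rather than fabricated.
    """

    anchor_drug: str
    partner_drug: str
    n_models: int
    mean_delta: float
    sd: float
    ci95: tuple[float, float]
    t_stat: float
    p_value: float
    prop_supra: float
    prop_supra_ci95: tuple[float, float]
    degenerate_variance: bool = False


def supra_additivity_score(
    inhib_combo: float, inhib_1: float, inhib_2: float
) -> tuple[float, str]:
    """Delta and its sign-based trend classification."""
    for v in (inhib_combo, inhib_1, inhib_2):
        if not math.isfinite(v):
            raise ValidationError(f"inhibition values must be finite, got {v}")
    delta = inhib_combo - (inhib_1 + inhib_2)
    trend = "supra" if delta > 0 else ("sub" if delta < 0 else "additive")
    return delta, trend


def summarize_across_models(
    deltas: Mapping[str, float], anchor: str = "", partner: str = ""
) -> CrossModelSummary:
    """One-sample two-sided t-test of mean delta against 0, with 95% CIs.

    The t-based CI covers the mean delta; the Wilson score interval covers
    the proportion of models with a supra-additive trend (delta > 0), which
    behaves sensibly at the screen's typical n = 4.
    """
    if not deltas:
        raise InsufficientDataError("no models supplied")
    vals = np.asarray([deltas[m] for m in sorted(deltas)], dtype=float)
    n = vals.size
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n > 1 else float("nan")
    n_supra = int((vals > 0).sum())
    prop = n_supra / n
    lo_p, hi_p = proportion_confint(n_supra, n, alpha=0.05, method="wilson")

    if n < 2:
        return CrossModelSummary(
            anchor_drug=anchor, partner_drug=partner, n_models=n,
            mean_delta=mean, sd=float("nan"), ci95=(float("nan"), float("nan")),
            t_stat=float("nan"), p_value=float("nan"),
            prop_supra=prop, prop_supra_ci95=(float(lo_p), float(hi_p)),
        )
    if sd == 0:
        return CrossModelSummary(
            anchor_drug=anchor, partner_drug=partner, n_models=n,
            mean_delta=mean, sd=0.0, ci95=(mean, mean),
            t_stat=float("nan"), p_value=float("nan"),
            prop_supra=prop, prop_supra_ci95=(float(lo_p), float(hi_p)),
            degenerate_variance=True,
        )
    t_stat, p_value = stats.ttest_1samp(vals, popmean=0.0)
    half = stats.t.ppf(0.975, df=n - 1) * sd / math.sqrt(n)
    return CrossModelSummary(
        anchor_drug=anchor, partner_drug=partner, n_models=n,
        mean_delta=mean, sd=sd, ci95=(mean - half, mean + half),
        t_stat=float(t_stat), p_value=float(p_value),
        prop_supra=prop, prop_supra_ci95=(float(lo_p), float(hi_p)),
    )


def score_combo_table(
    viability: pd.DataFrame,
    anchor: str,
    combo_label: str = "+",
) -> pd.DataFrame:
    """Delta records for every partner of *anchor* present in a viability frame.

    Combination rows are identified by drug labels of the form
    ``f"{anchor}{combo_label}{partner}"`` (or partner first); single-agent
    rows by the bare labels.  Returns one row per (model, partner) with the
    three inhibition values and delta.
    """
    rows = []
    for model, grp in viability.groupby("model", sort=True):
        inhib = {
            str(r.drug): 100.0 - float(r.viability_pct)
            for r in grp.itertuples(index=False)
        }
        if anchor not in inhib:
            continue
        for drug, combo_inhib in inhib.items():
            if combo_label not in drug:
                continue
            a, _, b = drug.partition(combo_label)
            if anchor == a:
                partner = b
            elif anchor == b:
                partner = a
            else:
                continue
            if partner not in inhib:
                continue
            delta, trend = supra_additivity_score(
                combo_inhib, inhib[anchor], inhib[partner]
            )
            rows.append(
                {
                    "model": str(model),
                    "anchor": anchor,
                    "partner": partner,
                    "inhib_combo": combo_inhib,
                    "inhib_anchor": inhib[anchor],
                    "inhib_partner": inhib[partner],
                    "delta": delta,
                    "trend": trend,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "model", "anchor", "partner",
            "inhib_combo", "inhib_anchor", "inhib_partner", "delta", "trend",
        ],
    )


def build_delta_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot delta records into a partner-by-model matrix; absent cells are NaN."""
    required = {"model", "partner", "delta"}
    if not required.issubset(records.columns):
        raise ValidationError(f"records need columns {sorted(required)}")
    dup = records.duplicated(subset=["partner", "model"])
    if dup.any():
        raise ValidationError("multiple records per (partner, model); average replicates first")
    return records.pivot(index="partner", columns="model", values="delta")


def summarize_delta_matrix(matrix: pd.DataFrame, anchor: str = "") -> pd.DataFrame:
    """Cross-model summary row per partner drug from a delta matrix."""
    rows = []
    for partner, series in matrix.iterrows():
        vals = series.dropna()
        if vals.empty:
            continue
        s = summarize_across_models(vals.to_dict(), anchor=anchor, partner=str(partner))
        rows.append(
            {
                "anchor": anchor,
                "partner": partner,
                "n_models": s.n_models,
                "mean_delta": s.mean_delta,
                "sd": s.sd,
                "ci95_lo": s.ci95[0],
                "ci95_hi": s.ci95[1],
                "t_stat": s.t_stat,
                "p_value": s.p_value,
                "prop_supra": s.prop_supra,
                "prop_supra_ci95_lo": s.prop_supra_ci95[0],
                "prop_supra_ci95_hi": s.prop_supra_ci95[1],
                "degenerate_variance": s.degenerate_variance,
            }
        )
    return pd.DataFrame(rows)
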