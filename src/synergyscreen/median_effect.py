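"""Median-effect dose-response fitting and combination-index / dose-reduction-index synergy.

The mass-action median-effect model relates dose D to fraction affected Fa:

    Fa / Fu = (D / Dm)^m,      Fu = 1 - Fa

so that log(Fa/Fu) is linear in log D with slope m (sigmoidicity) and the
median-effect dose Dm (the dose giving Fa = 0.5) recoverable from the
intercept.  Inverting a fit gives the dose needed for any effect level:

    Dx(Fa) = Dm * (Fa / (1 - Fa))^(1/m)

For a two-drug mixture tested at a constant dose ratio (p1, p2), the
combination index at effect Fa is the classic mutually-exclusive form

    CI(Fa) = d1 / Dx1(Fa) + d2 / Dx2(Fa),   d_j = p_j * D_mix(Fa)

with CI < 1 synergism, CI = 1 additivity, CI > 1 antagonism; the per-drug
dose-reduction index is DRI_j(Fa) = Dx_j(Fa) / d_j, the fold reduction in
drug j's dose achievable in the mixture at equal effect.  The identity
CI = 1/DRI1 + 1/DRI2 holds by construction.

A combination is called promising when CI < 1 and both DRI > 1 at every
grid point with Fa above a high-effect threshold (default 0.75), where a
cancer therapy must perform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidFitError, ValidationError
from .viability import FaValue

#: default Fa evaluation grid: 0.05..0.95 step 0.05, plus 0.97
DEFAULT_FA_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2)) + (0.97,)

DEFAULT_FA_THRESHOLD = 0.75


@dataclass(frozen=True)
class DoseSeries:
    """A dose ladder with averaged Fa values, for one drug or a fixed-ratio mixture."""

    series_id: str
    drugs: tuple[str, ...]
    doses: tuple[float, ...]  # ascending total doses, µM
    fa_values: tuple[FaValue, ...]
    ratio: tuple[float, float] | None = None  # dose fractions, mixtures only
    n_reps_averaged: int = 1

    def __post_init__(self) -> None:
        if len(self.drugs) not in (1, 2):
            raise ValidationError("a series covers one drug or a two-drug mixture")
        if len(self.doses) != len(self.fa_values):
            raise ValidationError("doses and fa_values must align")
        d = np.asarray(self.doses, dtype=float)
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValidationError("doses must be positive and strictly increasing")
        if len(self.drugs) == 2:
            if self.ratio is None:
                raise ValidationError("mixture series requires a dose ratio")
            p1, p2 = self.ratio
            if not (p1 > 0 and p2 > 0 and math.isclose(p1 + p2, 1.0, abs_tol=1e-9)):
                raise ValidationError(f"ratio fractions must be positive and sum to 1, got {self.ratio}")


@dataclass(frozen=True)
class MedianEffectFit:
    """Fitted median-effect parameters for one dose series."""

    series_id: str
    m: float
    dm: float  # µM
    r: float  # correlation of the linearized fit
    n_points: int
    excluded_points: tuple[tuple[float, str], ...] = ()  # (dose, reason)

    def fa_at_dose(self, dose: float) -> float:
        """Forward model: Fa = 1 / (1 + (Dm/D)^m)."""
        if dose <= 0:
            raise ValidationError(f"dose must be positive, got {dose}")
        return 1.0 / (1.0 + (self.dm / dose) ** self.m)


def fit_median_effect(series: DoseSeries) -> MedianEffectFit:
    """Unweighted OLS of log10(Fa/Fu) on log10(dose).

    Clamped Fa points (viability at/over 100% or at/below 0%) are excluded
    — the linearization is undefined there — and logged with reasons.
    Raises for under-determined input or a non-positive slope (a
    non-cytotoxic series has no meaningful Dm).
    """
    usable_d, usable_fa, excluded = [], [], []
    for dose, fav in zip(series.doses, series.fa_values):
        if fav.clamped:
            excluded.append((float(dose), "clamped Fa (viability outside (0,100)%)"))
            continue
        if not 0.0 < fav.fa < 1.0:
            excluded.append((float(dose), f"Fa {fav.fa} outside open unit interval"))
            continue
        usable_d.append(dose)
        usable_fa.append(fav.fa)
    if len(usable_d) < 2:
        raise InsufficientDataError(
            f"series {series.series_id!r}: {len(usable_d)} usable point(s), need >= 2"
        )
    x = np.log10(np.asarray(usable_d, dtype=float))
    fa = np.asarray(usable_fa, dtype=float)
    y = np.log10(fa / (1.0 - fa))
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise InvalidFitError(
            f"series {series.series_id!r}: non-positive median-effect slope {m:.4g}"
        )
    dm = float(10.0 ** (-res.intercept / m))
    # two-point fits have r = +/-1 by construction; linregress returns rvalue
    r = float(res.rvalue) if len(usable_d) > 2 else (1.0 if m > 0 else -1.0)
    return MedianEffectFit(
        series_id=series.series_id,
        m=m,
        dm=dm,
        r=r,
        n_points=len(usable_d),
        excluded_points=tuple(excluded),
    )


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Invert the fit: Dx = Dm * (Fa/Fu)^(1/m); strictly increasing in Fa."""
    if not 0.0 < fa < 1.0:
        raise ValidationError(f"fa must lie strictly inside (0, 1), got {fa}")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def _check_ratio(ratio: tuple[float, float]) -> tuple[float, float]:
    p1, p2 = ratio
    if not (p1 > 0 and p2 > 0 and math.isclose(p1 + p2, 1.0, abs_tol=1e-9)):
        raise ValidationError(f"ratio fractions must be positive and sum to 1, got {ratio}")
    return float(p1), float(p2)


def combination_index(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    fit_mix: MedianEffectFit,
    ratio: tuple[float, float],
    fa_grid: Sequence[float] = DEFAULT_FA_GRID,
) -> np.ndarray:
    """CI at each grid Fa, mutually-exclusive (no cross-term) form."""
    p1, p2 = _check_ratio(ratio)
    ci = np.empty(len(fa_grid), dtype=float)
    for i, fa in enumerate(fa_grid):
        d_mix = dose_for_effect(fit_mix, fa)
        ci[i] = p1 * d_mix / dose_for_effect(fit1, fa) + p2 * d_mix / dose_for_effect(fit2, fa)
    return ci


def dose_reduction_index(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    fit_mix: MedianEffectFit,
    ratio: tuple[float, float],
    fa_grid: Sequence[float] = DEFAULT_FA_GRID,
) -> np.ndarray:
    """Per-drug DRI at each grid Fa; shape (len(grid), 2).

    DRI_j = Dx_j(Fa) / (p_j * D_mix(Fa)); the identity CI = sum_j 1/DRI_j
    holds exactly.
    """
    p1, p2 = _check_ratio(ratio)
    dri = np.empty((len(fa_grid), 2), dtype=float)
    for i, fa in enumerate(fa_grid):
        d_mix = dose_for_effect(fit_mix, fa)
        dri[i, 0] = dose_for_effect(fit1, fa) / (p1 * d_mix)
        dri[i, 1] = dose_for_effect(fit2, fa) / (p2 * d_mix)
    return dri


@dataclass(frozen=True)
class SynergyProfile:
    """Fa-grid CI/DRI profile with the promising/not-promising call."""

    drugs: tuple[str, str]
    ratio: tuple[float, float]
    fa_grid: tuple[float, ...]
    ci_values: tuple[float, ...]
    dri_values: tuple[tuple[float, float], ...]
    fa_threshold: float
    call: str  # "promising" | "not_promising"
    violations: tuple[tuple[float, str], ...] = ()  # (fa, reason)


def synergy_rule_violations(
    fa_grid: Sequence[float],
    ci_values: Sequence[float],
    dri_values: Sequence[tuple[float, float]],
    fa_threshold: float = DEFAULT_FA_THRESHOLD,
) -> list[tuple[float, str]]:
    """Apply the high-effect decision rule to an explicit CI/DRI profile.

    Returns the list of (fa, reason) violations among grid points with
    Fa above the threshold; an empty list means the combination passes
    (CI < 1 and both DRI > 1 wherever it matters).  Note that for
    profiles derived from one consistent set of fits the DRI clause is
    implied by CI < 1 (CI is the sum of the positive DRI reciprocals);
    it bites only for externally supplied or averaged profiles.
    """
    if not any(f > fa_threshold for f in fa_grid):
        raise ValidationError(
            f"no grid points above the Fa threshold {fa_threshold}; extend the grid"
        )
    violations: list[tuple[float, str]] = []
    for fa, c, (d1, d2) in zip(fa_grid, ci_values, dri_values):
        if fa <= fa_threshold:
            continue
        if not c < 1.0:
            violations.append((fa, f"CI={c:.4g} >= 1"))
        if not d1 > 1.0:
            violations.append((fa, f"DRI1={d1:.4g} <= 1"))
        if not d2 > 1.0:
            violations.append((fa, f"DRI2={d2:.4g} <= 1"))
    return violations


def call_synergy(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    fit_mix: MedianEffectFit,
    ratio: tuple[float, float],
    fa_grid: Sequence[float] = DEFAULT_FA_GRID,
    fa_threshold: float = DEFAULT_FA_THRESHOLD,
    drugs: tuple[str, str] | None = None,
) -> SynergyProfile:
    """Full profile plus the decision rule.

    Promising iff CI < 1 and both DRI > 1 at every grid point with
    Fa > fa_threshold; otherwise the violating points are reported.
    """
    grid = tuple(float(f) for f in fa_grid)
    ci = combination_index(fit1, fit2, fit_mix, ratio, grid)
    dri = dose_reduction_index(fit1, fit2, fit_mix, ratio, grid)
    violations = synergy_rule_violations(grid, ci, [tuple(d) for d in dri], fa_threshold)
    return SynergyProfile(
        drugs=drugs or (fit1.series_id, fit2.series_id),
        ratio=_check_ratio(ratio),
        fa_grid=grid,
        ci_values=tuple(float(c) for c in ci),
        dri_values=tuple((float(a), float(b)) for a, b in dri),
        fa_threshold=fa_threshold,
        call="promising" if not violations else "not_promising",
        violations=tuple(violations),
    )


def loewe_mixture_dm(
    dm1: float, dm2: float, ratio: tuple[float, float], kappa: float = 1.0
) -> float:
    """Median-effect dose of a constant-ratio mixture under scaled Loewe additivity.

    With equal slopes, the additive (kappa = 1) mixture satisfies
    1/Dm_mix = p1/Dm1 + p2/Dm2; multiplying by the interaction multiplier
    kappa yields a mixture whose CI equals kappa at every Fa.  This is the
    synthetic-truth construction used by the generators and oracle tests.
    """
    p1, p2 = _check_ratio(ratio)
    if kappa <= 0:
        raise ValidationError(f"interaction multiplier must be positive, got {kappa}")
    return kappa / (p1 / dm1 + p2 / dm2)
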