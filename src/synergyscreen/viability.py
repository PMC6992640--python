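"""Percent-of-vehicle viability, replicate aggregation, artifact flagging, Fa conversion.

The screen's viability measure is treated-well signal as a percentage of the
mean vehicle-control (DMSO) signal of the same tumor model.  Values above
100% are preserved: reporter-construct artifacts (e.g. HDAC inhibitors
boosting the CMV promoter that drives luciferase) show up as apparent
viability well above vehicle and are flagged, not clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateControlError, ValidationError

#: default apparent-viability cutoff (percent of vehicle) above which a drug
#: is treated as a reporter artifact rather than a growth promoter
DEFAULT_ARTIFACT_THRESHOLD = 120.0

#: default open-interval clamp for fraction-affected values
DEFAULT_EPSILON = 1e-4


@dataclass(frozen=True)
class ViabilityRecord:
    """Replicate-aggregated viability of one (model, drug, dose) condition."""

    model_id: str
    drug_id: str
    dose: float  # µM
    viability_pct: float
    n_reps: int
    sd: float
    artifact_flag: bool = False

    @property
    def inhibition_pct(self) -> float:
        return 100.0 - self.viability_pct


@dataclass(frozen=True)
class FaValue:
    """Fraction affected on the open unit interval.

    ``clamped`` records that the raw value fell outside ``(0, 1)`` (viability
    at or above 100%, or at or below 0%) and was pulled to the boundary;
    such points are excluded from median-effect fits because the
    log(Fa/Fu) linearization is undefined there.
    """

    fa: float
    clamped: bool = False

    @property
    def fu(self) -> float:
        return 1.0 - self.fa


def percent_of_vehicle(
    treated_signal: float, vehicle_signals: Iterable[float]
) -> float:
    """Viability of one treated well as a percent of the mean vehicle signal.

    Not clamped: values above 100 are meaningful (artifact territory).
    """
    vehicle = np.asarray(list(vehicle_signals), dtype=float)
    if vehicle.size == 0:
        raise DegenerateControlError("no vehicle-control signals supplied")
    mean_vehicle = vehicle.mean()
    if not mean_vehicle > 0:
        raise DegenerateControlError(
            f"mean vehicle signal must be positive, got {mean_vehicle}"
        )
    if treated_signal < 0:
        raise ValidationError(f"treated signal must be non-negative, got {treated_signal}")
    return 100.0 * treated_signal / mean_vehicle


def aggregate_replicates(values: Sequence[float]) -> tuple[float, float, int]:
    """Arithmetic mean, sample SD (ddof=1; 0 for a singleton) and n."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot aggregate an empty replicate set")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd, int(arr.size)


def flag_artifacts(
    records: Sequence[ViabilityRecord],
    threshold: float = DEFAULT_ARTIFACT_THRESHOLD,
) -> list[ViabilityRecord]:
    """Set ``artifact_flag`` on records whose mean viability exceeds *threshold*.

    Flagged drugs are kept in the table (they sink to the bottom of efficacy
    rankings downstream) so list lengths stay reproducible.
    """
    if not threshold > 100:
        raise ValidationError(f"artifact threshold must exceed 100%, got {threshold}")
    return [replace(r, artifact_flag=r.viability_pct > threshold) for r in records]


def fa_from_viability(
    viability_pct: float, epsilon: float = DEFAULT_EPSILON
) -> FaValue:
    """Convert percent viability to fraction affected, Fa = 1 − viability/100.

    The result is clamped into ``[epsilon, 1 − epsilon]``; a fired clamp is
    flagged so median-effect fitting can exclude the point.
    """
    if not math.isfinite(viability_pct):
        raise ValidationError(f"viability must be finite, got {viability_pct}")
    if not 0 < epsilon < 0.5:
        raise ValidationError(f"epsilon must lie in (0, 0.5), got {epsilon}")
    fa = 1.0 - viability_pct / 100.0
    if fa < epsilon:
        return FaValue(fa=epsilon, clamped=True)
    if fa > 1.0 - epsilon:
        return FaValue(fa=1.0 - epsilon, clamped=True)
    return FaValue(fa=fa, clamped=False)


# ---------------------------------------------------------------------------
# table-level normalization
# ---------------------------------------------------------------------------


def normalize_wells(
    wells: pd.DataFrame,
    artifact_threshold: float = DEFAULT_ARTIFACT_THRESHOLD,
) -> pd.DataFrame:
    """Turn a wells table into a replicate-aggregated viability table.

    For each tumor model the vehicle wells (role ``vehicle``) define the
    100% reference; every treated well becomes percent of that mean, then
    replicates of each (model, drug, dose) are averaged.  Returns a frame in
    the ``viability`` schema layout.
    """
    out_rows = []
    for model, grp in wells.groupby("model", sort=True):
        vehicle = grp.loc[grp["role"] == "vehicle", "signal"]
        if vehicle.empty:
            raise DegenerateControlError(f"model {model!r} has no vehicle wells")
        mean_vehicle = float(vehicle.mean())
        if not mean_vehicle > 0:
            raise DegenerateControlError(
                f"model {model!r}: mean vehicle signal {mean_vehicle} is not positive"
            )
        treated = grp[grp["role"] == "treated"]
        for (drug, dose), cond in treated.groupby(["drug", "dose_uM"], sort=True):
            viab = 100.0 * cond["signal"].to_numpy(dtype=float) / mean_vehicle
            mean, sd, n = aggregate_replicates(viab)
            out_rows.append(
                {
                    "model": model,
                    "drug": drug,
                    "dose_uM": float(dose),
                    "viability_pct": mean,
                    "n_reps": n,
                    "sd": sd,
                    "artifact_flag": mean > artifact_threshold,
                }
            )
    return pd.DataFrame(
        out_rows,
        columns=[
            "model",
            "drug",
            "dose_uM",
            "viability_pct",
            "n_reps",
            "sd",
            "artifact_flag",
        ],
    )


def viability_frame_to_records(df: pd.DataFrame) -> list[ViabilityRecord]:
    """Typed records from a viability-schema frame."""
    return [
        ViabilityRecord(
            model_id=str(r.model),
            drug_id=str(r.drug),
            dose=float(r.dose_uM),
            viability_pct=float(r.viability_pct),
            n_reps=int(r.n_reps),
            sd=float(r.sd),
            artifact_flag=bool(r.artifact_flag),
        )
        for r in df.itertuples(index=False)
    ]
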