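"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the experimental designs the pipeline analyzes:

* a plate-luminescence drug screen (per-well photon flux, vehicle wells,
  replicate noise, a subset of reporter-artifact drugs whose apparent
  viability exceeds 100%),
* single-agent dose responses following the median-effect model with known
  slope m and median-effect dose Dm,
* constant-ratio two-drug mixtures built under Loewe additivity with a
  tunable interaction multiplier kappa, so the true combination index is
  known (CI = kappa at every Fa for equal slopes),
* an expression/clinical/survival cohort with subtype-dependent gene means
  and exponential event times whose hazard depends on the realized
  high/low expression quadrant.

Every generator draws from a named substream of a single integer seed, so
adding a generator never perturbs the others' draws, and identical
(truth, seed) pairs yield bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .median_effect import DoseSeries, loewe_mixture_dm
from .viability import FaValue

# fixed substream ids: appending new generators must not renumber these
_STREAMS = {"screen": 1, "dose_response": 2, "combination": 3, "cohort": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenTruth:
    """Design of the synthetic plate screen.

    Defaults mirror the screen being emulated: 1,363 drugs across 10 tumor
    models in duplicate, with plate noise of a few percent of vehicle.
    ``hit_fraction`` drugs are strongly cytotoxic (true viability 5-50% of
    vehicle), ``artifact_fraction`` are reporter artifacts (130-200%), and
    the remainder are weakly responsive (60-100%).
    """

    n_drugs: int = 1363
    n_models: int = 10
    hit_fraction: float = 0.15
    artifact_fraction: float = 0.05
    noise_sd: float = 5.0  # percent-of-vehicle units
    model_effect_sd: float = 5.0  # per-model jitter of a drug's true viability
    n_reps: int = 2
    n_vehicle_wells: int = 8
    vehicle_flux: float = 1.0e7  # photons/s
    dose_um: float = 10.0

    def __post_init__(self) -> None:
        if not (0 <= self.hit_fraction <= 1 and 0 <= self.artifact_fraction <= 1):
            raise ValidationError("fractions must lie in [0, 1]")
        if self.hit_fraction + self.artifact_fraction > 1:
            raise ValidationError("hit and artifact fractions overlap")


@dataclass(frozen=True)
class CohortTruth:
    """Design of the synthetic expression/outcome cohort.

    Defaults mirror an 855-patient compendium with a basal-like fraction of
    ~16% and Basal-elevated EGFR/BIRC5; survival is exponential with the
    hazard set by the sample's realized expression quadrant (hh/hl/lh/ll)
    for the two stratification genes.
    """

    n_samples: int = 855
    subtype_props: tuple[tuple[str, float], ...] = (
        ("Basal", 0.164),
        ("Claudin", 0.100),
        ("LumA", 0.300),
        ("LumB", 0.180),
        ("Her2", 0.130),
        ("Normal", 0.126),
    )
    genes: tuple[str, ...] = ("EGFR", "BIRC5", "ESR1", "ERBB2")
    # per-gene log-scale mean by subtype; unlisted subtypes use the default
    gene_means: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = (
        ("EGFR", (("Basal", 3.0), ("Claudin", 2.2), ("default", 1.0))),
        ("BIRC5", (("Basal", 2.8), ("default", 2.2))),
        ("ESR1", (("LumA", 3.0), ("LumB", 2.8), ("default", 0.5))),
        ("ERBB2", (("Her2", 3.2), ("default", 1.5))),
    )
    log_noise_sd: float = 0.5
    quadrant_hazards: tuple[tuple[str, float], ...] = (
        ("hh", 0.030),
        ("hl", 0.012),
        ("lh", 0.012),
        ("ll", 0.010),
    )  # events per month
    censor_hazard: float = 0.008  # independent exponential censoring
    stratify_genes: tuple[str, str] = ("EGFR", "BIRC5")
    endpoint: str = "MFS"

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.subtype_props)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"subtype proportions must sum to 1, got {total}")
        if any(h <= 0 for _, h in self.quadrant_hazards):
            raise ValidationError("hazards must be positive")


# ---------------------------------------------------------------------------
# screen generator
# ---------------------------------------------------------------------------


def gen_screen(truth: ScreenTruth, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wells table plus per-(drug, model) truth record.

    Vehicle wells fluctuate around the set flux with the same relative
    noise as treated wells; treated signals are
    ``vehicle_flux * (true viability + noise)/100``, floored at zero.
    With ``noise_sd = 0`` percent-of-vehicle normalization recovers the
    planted viabilities exactly.
    """
    rng = _rng(seed, "screen")
    n_hit = round(truth.n_drugs * truth.hit_fraction)
    n_art = round(truth.n_drugs * truth.artifact_fraction)
    classes = np.array(
        ["hit"] * n_hit + ["artifact"] * n_art + ["neutral"] * (truth.n_drugs - n_hit - n_art)
    )
    rng.shuffle(classes)
    width = len(str(truth.n_drugs))
    drugs = [f"drug{idx:0{width}d}" for idx in range(1, truth.n_drugs + 1)]
    base = np.where(
        classes == "hit",
        rng.uniform(5.0, 50.0, truth.n_drugs),
        np.where(
            classes == "artifact",
            rng.uniform(130.0, 200.0, truth.n_drugs),
            rng.uniform(60.0, 100.0, truth.n_drugs),
        ),
    )
    models = [f"model{j:02d}" for j in range(1, truth.n_models + 1)]
    # per-model jitter of each drug's true viability (tumor-model heterogeneity)
    jitter = rng.normal(0.0, truth.model_effect_sd, size=(truth.n_drugs, truth.n_models))
    true_viab = np.clip(base[:, None] + jitter, 0.5, None)

    rows = []
    truth_rows = []
    for j, model in enumerate(models):
        for rep in range(1, truth.n_vehicle_wells + 1):
            noise = rng.normal(0.0, truth.noise_sd)
            rows.append(
                {
                    "model": model,
                    "drug": "DMSO",
                    "dose_uM": 0.0,
                    "replicate": rep,
                    "signal": truth.vehicle_flux * max(100.0 + noise, 0.0) / 100.0,
                    "role": "vehicle",
                }
            )
        for i, drug in enumerate(drugs):
            for rep in range(1, truth.n_reps + 1):
                noise = rng.normal(0.0, truth.noise_sd)
                signal = truth.vehicle_flux * max(true_viab[i, j] + noise, 0.0) / 100.0
                rows.append(
                    {
                        "model": model,
                        "drug": drug,
                        "dose_uM": truth.dose_um,
                        "replicate": rep,
                        "signal": signal,
                        "role": "treated",
                    }
                )
            truth_rows.append(
                {
                    "model": model,
                    "drug": drug,
                    "drug_class": classes[i],
                    "true_viability_pct": true_viab[i, j],
                }
            )
    wells = pd.DataFrame(rows)
    truth_df = pd.DataFrame(truth_rows)
    return wells, truth_df


# ---------------------------------------------------------------------------
# dose-response generators
# ---------------------------------------------------------------------------


def _median_effect_fa(doses: np.ndarray, m: float, dm: float) -> np.ndarray:
    return 1.0 / (1.0 + (dm / doses) ** m)


def gen_dose_response(
    seed: int,
    drug: str,
    m: float,
    dm: float,
    doses: Sequence[float],
    noise_sd_log: float = 0.0,
    n_reps: int = 3,
    series_id: str | None = None,
) -> DoseSeries:
    """Single-agent series: Fa from the median-effect model plus log-space noise.

    Noise is Gaussian on log10(Fa/Fu) — the scale on which the model is
    linear — and replicate Fa values are averaged, matching the analysis
    path.  Noiseless output inverts exactly to (m, Dm).
    """
    if m <= 0 or dm <= 0:
        raise ValidationError("m and Dm must be positive")
    rng = _rng(seed, "dose_response")
    d = np.asarray(sorted(doses), dtype=float)
    if np.any(d <= 0):
        raise ValidationError("doses must be positive")
    y = m * np.log10(d / dm)  # log10(Fa/Fu)
    if noise_sd_log > 0:
        y = y[:, None] + rng.normal(0.0, noise_sd_log, size=(d.size, n_reps))
        fa = (1.0 / (1.0 + 10.0 ** (-y))).mean(axis=1)
    else:
        fa = 1.0 / (1.0 + 10.0 ** (-y))
    return DoseSeries(
        series_id=series_id or drug,
        drugs=(drug,),
        doses=tuple(d),
        fa_values=tuple(FaValue(float(f)) for f in fa),
        n_reps_averaged=n_reps if noise_sd_log > 0 else 1,
    )


def gen_combination(
    seed: int,
    drug1: str,
    drug2: str,
    m: float,
    dm1: float,
    dm2: float,
    ratio: tuple[float, float],
    kappa: float,
    doses: Sequence[float],
    noise_sd_log: float = 0.0,
    n_reps: int = 3,
) -> DoseSeries:
    """Constant-ratio mixture under scaled Loewe additivity.

    Equal slopes are assumed (the constant-kappa guarantee); the mixture's
    median-effect dose is kappa / (p1/Dm1 + p2/Dm2), so the downstream
    combination index evaluates to kappa at every grid Fa.
    """
    dm_mix = loewe_mixture_dm(dm1, dm2, ratio, kappa)
    rng = _rng(seed, "combination")
    d = np.asarray(sorted(doses), dtype=float)
    if np.any(d <= 0):
        raise ValidationError("doses must be positive")
    y = m * np.log10(d / dm_mix)
    if noise_sd_log > 0:
        y = y[:, None] + rng.normal(0.0, noise_sd_log, size=(d.size, n_reps))
        fa = (1.0 / (1.0 + 10.0 ** (-y))).mean(axis=1)
    else:
        fa = 1.0 / (1.0 + 10.0 ** (-y))
    return DoseSeries(
        series_id=f"{drug1}+{drug2}",
        drugs=(drug1, drug2),
        doses=tuple(d),
        fa_values=tuple(FaValue(float(f)) for f in fa),
        ratio=(float(ratio[0]), float(ratio[1])),
        n_reps_averaged=n_reps if noise_sd_log > 0 else 1,
    )


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


def gen_cohort(
    truth: CohortTruth, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression, clinical, survival and truth tables for a synthetic cohort.

    Expression is log-normal with subtype-specific log-means; the survival
    hazard of each sample is looked up from its *realized* quadrant (strict
    median split of the two stratification genes across the whole cohort),
    so the planted hazard contrast is exactly what quadrant stratification
    should recover.  Censoring is independent exponential.
    """
    rng = _rng(seed, "cohort")
    subtypes_labels = [s for s, _ in truth.subtype_props]
    props = np.array([p for _, p in truth.subtype_props])
    counts = np.floor(props * truth.n_samples).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    remainder = truth.n_samples - counts.sum()
    frac = props * truth.n_samples - counts
    for idx in np.argsort(-frac)[:remainder]:
        counts[idx] += 1
    subtype = np.repeat(subtypes_labels, counts)
    rng.shuffle(subtype)
    samples = [f"S{i:04d}" for i in range(1, truth.n_samples + 1)]

    means = {g: dict(m) for g, m in truth.gene_means}
    expr = {}
    for gene in truth.genes:
        gmeans = means.get(gene, {"default": 1.0})
        mu = np.array([gmeans.get(s, gmeans.get("default", 1.0)) for s in subtype])
        expr[gene] = np.exp(rng.normal(mu, truth.log_noise_sd))
    expression = pd.DataFrame(expr, index=pd.Index(samples, name="sample"))

    subtype_series = pd.Series(subtype, index=expression.index, name="subtype")
    er = np.isin(subtype, ["LumA", "LumB", "Normal"]).astype(int)
    pr = np.isin(subtype, ["LumA", "LumB"]).astype(int)
    her2 = (subtype == "Her2").astype(int)
    clinical = pd.DataFrame(
        {
            "sample": samples,
            "subtype": subtype,
            "er": er,
            "pr": pr,
            "her2": her2,
            "age": rng.normal(58.0, 11.0, truth.n_samples).round(1),
            "ln_status": rng.binomial(1, 0.4, truth.n_samples),
            "diff_score": rng.normal(0.0, 1.0, truth.n_samples) + 0.8 * (er == 1),
            "prolif_score": 0.4 * np.log(expression["BIRC5"].to_numpy())
            + rng.normal(0.0, 0.3, truth.n_samples),
        }
    )

    # realized quadrants drive the hazards
    from .expression_outcomes import ExpressionCohort, median_split_quadrants

    cohort = ExpressionCohort(expression=expression, subtype=subtype_series)
    g1, g2 = truth.stratify_genes
    quadrants = median_split_quadrants(cohort, g1, g2)
    hazards = dict(truth.quadrant_hazards)
    lam = quadrants.map(hazards).to_numpy(dtype=float)
    event_t = rng.exponential(1.0 / lam)
    censor_t = rng.exponential(1.0 / truth.censor_hazard, truth.n_samples)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    survival = pd.DataFrame(
        {
            "sample": samples,
            "endpoint": truth.endpoint,
            "time_months": time,
            "event": event,
        }
    )
    truth_df = pd.DataFrame(
        {
            "sample": samples,
            "subtype": subtype,
            "quadrant": quadrants.to_numpy(),
            "hazard": lam,
        }
    )
    return expression, clinical, survival, truth_df
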