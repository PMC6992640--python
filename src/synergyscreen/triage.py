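"""Hit triage: per-model drug ranking, top-N selection, multiway overlap, clustering.

The screen's follow-up list is built by ranking drugs within each tumor
model by mean percent-of-vehicle viability (most cytotoxic first), taking
the top N per model, partitioning the union by how many models share each
drug (the Venn analysis), and assembling the chosen overlap cells plus any
manually nominated drugs into a final set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

from .errors import ValidationError

VALID_DISTANCES = ("centered-correlation", "euclidean")
VALID_LINKAGES = ("average", "complete", "single")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the top-N + overlap drug selection."""

    per_model_topn: dict[str, list[str]]
    overlap_partition: dict[int, frozenset[str]]
    manual_additions: list[str]
    final_set: frozenset[str]
    included_k: frozenset[int]

    @property
    def counts_by_k(self) -> dict[int, int]:
        return {k: len(v) for k, v in sorted(self.overlap_partition.items(), reverse=True)}


@dataclass(frozen=True)
class ClusterResult:
    """Deterministic agglomerative clustering of a labelled matrix."""

    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray  # scipy linkage matrix
    col_linkage: np.ndarray
    distance: str
    linkage: str


def rank_drugs(
    viability: pd.DataFrame,
    artifact_policy: str = "sink",
) -> list[str]:
    """Rank one model's drugs by ascending mean viability (most cytotoxic first).

    *viability* is a viability-schema frame restricted to one model with one
    row per drug.  Ties break lexicographically on the drug label so top-N
    cutoffs are deterministic.  Artifact-flagged drugs either ``sink`` to
    the bottom of the list (default, preserving list length) or are
    ``drop``-ped.
    """
    if artifact_policy not in ("sink", "drop"):
        raise ValidationError(f"unknown artifact policy {artifact_policy!r}")
    if viability["drug"].duplicated().any():
        dupes = viability.loc[viability["drug"].duplicated(), "drug"].unique().tolist()
        raise ValidationError(f"duplicate drug entries: {dupes}")
    df = viability
    if "artifact_flag" in df.columns:
        flags = df["artifact_flag"].astype(bool)
    else:
        flags = pd.Series(False, index=df.index)
    if artifact_policy == "drop":
        df = df[~flags]
        flags = flags[~flags]
    order = df.assign(_flag=flags.to_numpy()).sort_values(
        by=["_flag", "viability_pct", "drug"], ascending=[True, True, True], kind="mergesort"
    )
    return order["drug"].tolist()


def top_n(ranked: Sequence[str], n: int) -> frozenset[str]:
    """First *n* drugs of a ranked list, as a set."""
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    if n > len(ranked):
        raise ValidationError(f"n={n} exceeds list length {len(ranked)}")
    return frozenset(ranked[:n])


def multiway_overlap(sets: Mapping[str, frozenset[str] | set[str]]) -> dict[int, frozenset[str]]:
    """Partition the union of per-model drug sets by occupancy count.

    A drug lands in cell *k* iff it appears in exactly *k* of the input
    sets; the cells partition the union (the Venn-diagram counts).
    """
    if len(sets) < 2:
        raise ValidationError("multiway overlap requires at least two sets")
    counts: dict[str, int] = {}
    for s in sets.values():
        for d in s:
            counts[d] = counts.get(d, 0) + 1
    out: dict[int, set[str]] = {}
    for d, k in counts.items():
        out.setdefault(k, set()).add(d)
    return {k: frozenset(v) for k, v in sorted(out.items(), reverse=True)}


def assemble_selection(
    partition: Mapping[int, frozenset[str] | set[str]],
    include_k: Sequence[int],
    manual_additions: Sequence[str] = (),
    per_model_topn: Mapping[str, Sequence[str]] | None = None,
) -> SelectionResult:
    """Union the chosen overlap cells with manual additions into the final set."""
    if not include_k:
        raise ValidationError("include_k must be non-empty")
    chosen: set[str] = set()
    for k in include_k:
        chosen |= set(partition.get(k, frozenset()))
    additions = list(dict.fromkeys(manual_additions))  # dedupe, keep order
    final = frozenset(chosen | set(additions))
    return SelectionResult(
        per_model_topn={m: list(v) for m, v in (per_model_topn or {}).items()},
        overlap_partition={k: frozenset(v) for k, v in partition.items()},
        manual_additions=additions,
        final_set=final,
        included_k=frozenset(include_k),
    )


def select_hits(
    viability: pd.DataFrame,
    n: int,
    include_k: Sequence[int],
    manual_additions: Sequence[str] = (),
    artifact_policy: str = "sink",
) -> SelectionResult:
    """End-to-end triage: rank per model, take top-N, overlap, assemble."""
    topn: dict[str, list[str]] = {}
    for model, grp in viability.groupby("model", sort=True):
        ranked = rank_drugs(grp, artifact_policy=artifact_policy)
        topn[str(model)] = ranked[:n] if n <= len(ranked) else ranked
        if n > len(ranked):
            raise ValidationError(f"model {model!r} has only {len(ranked)} drugs (< n={n})")
    partition = multiway_overlap({m: frozenset(v) for m, v in topn.items()})
    return assemble_selection(partition, include_k, manual_additions, per_model_topn=topn)


# ---------------------------------------------------------------------------
# hierarchical clustering (heatmap ordering)
# ---------------------------------------------------------------------------


def _distances(mat: np.ndarray, distance: str, labels: Sequence[str]) -> np.ndarray:
    if distance == "euclidean":
        return pdist(mat, metric="euclidean")
    # centered Pearson correlation distance 1 - r
    sd = mat.std(axis=1)
    if np.any(sd == 0):
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(
            f"constant row(s) {bad} undefined under correlation distance"
        )
    return pdist(mat, metric="correlation")


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance: str = "centered-correlation",
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of rows and columns of a labelled matrix.

    Defaults (centered Pearson distance, average linkage) follow the
    customary settings for expression/drug-response heatmaps.  Scipy's
    agglomerative implementation is deterministic for fixed input order, so
    leaf orders are reproducible.
    """
    if distance not in VALID_DISTANCES:
        raise ValidationError(f"distance must be one of {VALID_DISTANCES}")
    if linkage not in VALID_LINKAGES:
        raise ValidationError(f"linkage must be one of {VALID_LINKAGES}")
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValidationError("matrix must be at least 2x2 to cluster both axes")
    if matrix.isna().any().any():
        raise ValidationError("matrix contains missing values; impute or drop first")

    def _axis(mat: np.ndarray, labels: Sequence[str]) -> tuple[list[str], np.ndarray]:
        d = _distances(mat, distance, labels)
        z = sch.linkage(d, method=linkage)
        order = sch.leaves_list(z)
        return [labels[i] for i in order], z

    row_order, row_z = _axis(matrix.to_numpy(dtype=float), list(matrix.index))
    col_order, col_z = _axis(matrix.to_numpy(dtype=float).T, list(matrix.columns))
    return ClusterResult(
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_z,
        col_linkage=col_z,
        distance=distance,
        linkage=linkage,
    )


def ordered_matrix(matrix: pd.DataFrame, result: ClusterResult) -> pd.DataFrame:
    """Reindex *matrix* into the clustered leaf order (values untouched)."""
    return matrix.loc[result.row_order, result.col_order]


def selection_report(result: SelectionResult) -> pd.DataFrame:
    """Tabular selection report: one row per selected drug with its source."""
    rows = []
    for k in sorted(result.overlap_partition, reverse=True):
        if k not in result.included_k:
            continue
        for drug in sorted(result.overlap_partition[k]):
            rows.append({"drug": drug, "category": f"overlap_k{k}", "k": k})
    listed = {r["drug"] for r in rows}
    for drug in result.manual_additions:
        if drug not in listed:
            rows.append({"drug": drug, "category": "manual", "k": 0})
    return pd.DataFrame(rows, columns=["drug", "category", "k"])
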