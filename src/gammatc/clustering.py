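"""Temporal Venn-membership clustering of DEGs and z-scored profiles.

A DEG's temporal pattern is the exact set of post-irradiation time
points at which it is significant. Eight of the fifteen possible
non-empty patterns are named clusters:

====== ====================== =========================================
label  pattern (h)            interpretation
====== ====================== =========================================
Cl1    {1}                    early, single time point
Cl2    {2.5}                  single time point
Cl3    {4}                    single time point
Cl4    {6}                    single time point
Cl5    {4, 6}                 sustained from 4 h
Cl6    {2.5, 6}               on at 2.5 h, off at 4 h, on again at 6 h
Cl7    {2.5, 4, 6}            sustained from 2.5 h
Cl8    {1, 2.5, 4, 6}         sustained from 1 h
====== ====================== =========================================

Genes with any other pattern are "ungrouped" (the remaining Venn
regions). Each cluster is split into an up (u) and a down (d) subcluster
by the sign of the mean log2 fold change over the pattern's time points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .counts_io import CountMatrix
from .diffexpr import DEResult, size_factors
from .errors import DataError

UNGROUPED = "ungrouped"

CLUSTER_PATTERNS: dict[str, frozenset[float]] = {
    "Cl1": frozenset({1.0}),
    "Cl2": frozenset({2.5}),
    "Cl3": frozenset({4.0}),
    "Cl4": frozenset({6.0}),
    "Cl5": frozenset({4.0, 6.0}),
    "Cl6": frozenset({2.5, 6.0}),
    "Cl7": frozenset({2.5, 4.0, 6.0}),
    "Cl8": frozenset({1.0, 2.5, 4.0, 6.0}),
}

_PATTERN_TO_CLUSTER = {v: k for k, v in CLUSTER_PATTERNS.items()}


def assign_clusters(degs: dict[str, dict]) -> pd.DataFrame:
    """Map each DEG's DE-time-point set onto a named cluster or "ungrouped".

    Returns a frame with columns gene_id, cluster, pattern (comma-joined
    time points). Assignment is exact set equality, so the clusters
    partition the DEG set.
    """
    rows = []
    for gene, entry in sorted(degs.items()):
        pattern = frozenset(float(t) for t in entry["times"])
        if not pattern:
            raise DataError(f"gene {gene} has an empty DE pattern")
        cluster = _PATTERN_TO_CLUSTER.get(pattern, UNGROUPED)
        rows.append({
            "gene_id": gene,
            "cluster": cluster,
            "pattern": ",".join(f"{t:g}" for t in sorted(pattern)),
        })
    return pd.DataFrame(rows, columns=["gene_id", "cluster", "pattern"])


def split_up_down(assignment: pd.DataFrame, result: DEResult) -> pd.DataFrame:
    """Suffix each clustered gene with u/d by mean log2FC over its pattern.

    Adds columns ``direction`` (u/d), ``mean_log2fc``, ``signs`` (the
    per-time-point signs, for audit) and ``mixed`` (True when the signs
    disagree; the mean-sign rule still decides). Ungrouped genes keep
    their label with no suffix.
    """
    lfc = result.table.set_index(["gene_id", "timepoint"])["log2fc"]
    out = assignment.copy()
    directions, means, signs_col, mixed_col, labels = [], [], [], [], []
    for _, row in out.iterrows():
        times = [float(t) for t in row["pattern"].split(",")]
        vals = [float(lfc.loc[(row["gene_id"], t)]) for t in times]
        mean = float(np.mean(vals))
        d = "u" if mean > 0 else "d"
        signs = "".join("+" if v > 0 else "-" for v in vals)
        directions.append(d)
        means.append(mean)
        signs_col.append(signs)
        mixed_col.append(len(set(signs)) > 1)
        labels.append(row["cluster"] + d if row["cluster"] != UNGROUPED else UNGROUPED)
    out["direction"] = directions
    out["mean_log2fc"] = means
    out["signs"] = signs_col
    out["mixed"] = mixed_col
    out["label"] = labels
    return out


def zscore_profiles(counts: CountMatrix, genes: list[str],
                    dose_gy: float | None = None) -> pd.DataFrame:
    """Genes x time-points z-score matrix of normalized pseudocounts.

    Per gene: size-factor-normalize, average replicates within each time
    point, then center/scale across the time points with the population
    (n-denominator) standard deviation. Constant profiles map to all
    zeros so heatmaps render.
    """
    missing = sorted(set(genes) - set(counts.gene_ids))
    if missing:
        raise DataError(f"genes absent from count matrix: {missing[:10]}")
    factors = size_factors(counts)
    norm = counts.values / factors
    times = counts.time_points()
    prof = pd.DataFrame(index=genes, columns=times, dtype=float)
    for t in times:
        ids = counts.samples_at(t, dose_gy) or counts.samples_at(t)
        prof[t] = norm.loc[genes, ids].mean(axis=1)
    mat = prof.to_numpy()
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)  # population sd
    z = np.where(sd > 0, (mat - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    return pd.DataFrame(z, index=genes, columns=times)


def cluster_sizes(split: pd.DataFrame) -> pd.Series:
    """Gene counts per up/down subcluster label (ungrouped included)."""
    return split["label"].value_counts().sort_index()


def grouped_fraction(assignment: pd.DataFrame) -> float:
    """Fraction of DEGs falling into one of the eight named clusters."""
    if len(assignment) == 0:
        return float("nan")
    return float((assignment["cluster"] != UNGROUPED).mean())
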