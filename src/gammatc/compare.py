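"""Literature overlap, dose-comparison PCA, fold summaries and qPCR folds.

The low-dose (0.2 Gy) arm of the study has no replicates, so the dose
comparison aggregates whole clusters (mean z-profiles per dose) rather
than testing individual genes, and the sample structure is summarized
by PCA of all libraries.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .counts_io import CountMatrix
from .diffexpr import size_factors
from .errors import ConfigurationError, DataError

FOLD_EPSILON = 0.5  # offset in fold ratios, guards division by zero

#: PCA feature transform (not stated by upstream conventions; recorded
#: in output metadata): log2(size-factor-normalized pseudocount + 1),
#: gene-centered, no unit-variance scaling.
PCA_TRANSFORM = "log2(normalized+1), gene-centered"


def read_gene_list(path: str | Path) -> set[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    symbols = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.add(line)
    return symbols


def overlap(a: set[str], b: set[str]) -> tuple[set[str], int]:
    """Case-normalized intersection of two symbol lists.

    Symbols are upper-cased before intersecting so mouse (Pmaip1) and
    human (PMAIP1) spellings of the same gene meet.
    """
    au = {s.upper() for s in a}
    bu = {s.upper() for s in b}
    inter = au & bu
    return inter, len(inter)


def pca_variance(counts: CountMatrix, genes: list[str] | None = None,
                 n_components: int | None = None) -> dict:
    """PCA of samples over gene features; returns coords and variance fractions.

    Samples are observations and genes features; the feature matrix is
    log2(normalized pseudocount + 1) centered per gene. Variance
    fractions are the normalized squared singular values, non-increasing
    and summing to 1.
    """
    if counts.values.shape[1] < 3:
        raise DataError("PCA needs at least 3 samples")
    sub = counts.values if genes is None else counts.values.loc[genes]
    factors = size_factors(counts)
    feats = np.log2(sub.to_numpy(dtype=float) / factors.to_numpy() + 1.0).T
    feats = feats - feats.mean(axis=0, keepdims=True)
    n_max = min(feats.shape[0] - 1, feats.shape[1])
    k = n_max if n_components is None else min(n_components, n_max)
    u, s, _ = np.linalg.svd(feats, full_matrices=False)
    lam = s**2
    total = lam.sum()
    frac = lam / total if total > 0 else np.zeros_like(lam)
    coords = u[:, :k] * s[:k]
    return {
        "coordinates": pd.DataFrame(
            coords, index=counts.sample_ids,
            columns=[f"PC{i+1}" for i in range(k)]),
        "variance_fraction": frac[: len(lam)],
        "transform": PCA_TRANSFORM,
    }


def fold_summary(counts: CountMatrix, genes: list[str],
                 t_num: float, t_den: float,
                 dose_gy: float | None = None) -> pd.DataFrame:
    """Per-gene fold between two time points plus the arithmetic mean fold.

    fold = (mean normalized pseudocount at t_num + 0.5) /
           (mean at t_den + 0.5); the mean fold over the gene list is in
    the ``mean_fold`` attribute-row (last row, gene_id "__mean__").
    """
    missing = sorted(set(genes) - set(counts.gene_ids))
    if missing:
        raise DataError(f"genes absent from count matrix: {missing}")
    for t in (t_num, t_den):
        if not counts.samples_at(t, dose_gy) and not counts.samples_at(t):
            raise DataError(f"time point {t} absent from the design")
    factors = size_factors(counts)
    norm = counts.values / factors
    num_ids = counts.samples_at(t_num, dose_gy) or counts.samples_at(t_num)
    den_ids = counts.samples_at(t_den, dose_gy) or counts.samples_at(t_den)
    m_num = norm.loc[genes, num_ids].mean(axis=1)
    m_den = norm.loc[genes, den_ids].mean(axis=1)
    fold = (m_num + FOLD_EPSILON) / (m_den + FOLD_EPSILON)
    out = pd.DataFrame({"gene_id": genes, "fold": fold.to_numpy()})
    out.loc[len(out)] = {"gene_id": "__mean__", "fold": float(fold.mean())}
    return out


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns sample_id, gene, ct, replicate (biological set)."""
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "gene", "ct", "replicate"}
    if not need <= set(df.columns):
        raise ConfigurationError(f"Ct table lacks columns: {sorted(need - set(df.columns))}")
    return df


def ddct_fold(ct: pd.DataFrame, target: str, reference: str,
              calibrator: str) -> pd.DataFrame:
    """Relative qPCR quantification by the 2^-ddCt method.

    Per sample s: dCt_s = Ct(target, s) - Ct(reference, s);
    ddCt_s = dCt_s - dCt of that biological replicate's calibrator
    sample; fold_s = 2^-ddCt_s (so the calibrator itself is 1 by
    construction). Samples with a missing Ct are dropped with a
    ``dropped`` marker in the returned metadata columns. The mean fold
    and sd over biological replicates per sample label are appended as
    a second frame attribute via groupby in the caller; here each
    per-sample fold is returned.
    """
    wide = ct.pivot_table(index=["replicate", "sample_id"], columns="gene",
                          values="ct", aggfunc="mean")
    for g in (target, reference):
        if g not in wide.columns:
            raise DataError(f"gene {g} absent from Ct table")
    rows = []
    for rep, sub in wide.groupby(level="replicate"):
        sub = sub.droplevel("replicate")
        if calibrator not in sub.index:
            raise DataError(f"calibrator sample {calibrator} missing in replicate {rep}")
        dct = sub[target] - sub[reference]
        if np.isnan(dct.loc[calibrator]):
            raise DataError(f"calibrator Ct missing in replicate {rep}")
        ddct = dct - dct.loc[calibrator]
        for s, v in ddct.items():
            if np.isnan(v):
                continue  # missing Ct: sample dropped
            rows.append({"replicate": rep, "sample_id": s,
                         "ddct": float(v), "fold": float(2.0 ** (-v))})
    out = pd.DataFrame(rows, columns=["replicate", "sample_id", "ddct", "fold"])
    return out


def mean_fold_induction(folds: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of 2^-ddCt folds over biological replicates per sample."""
    g = folds.groupby("sample_id")["fold"]
    return pd.DataFrame({"mean_fold": g.mean(), "sd": g.std(ddof=1),
                         "n": g.size()}).reset_index()


def cluster_dose_profiles(counts: CountMatrix, split: pd.DataFrame,
                          doses: tuple[float, float]) -> pd.DataFrame:
    """Mean z-profile of each up/down subcluster, per dose arm.

    The kinetic dose comparison aggregates clusters, not genes: for each
    subcluster label the per-gene z-profiles (replicate-averaged within
    each dose) are averaged. Returns a long frame with columns label,
    dose_gy, time_h, mean_z.
    """
    from .clustering import zscore_profiles

    rows = []
    for dose in doses:
        have = {float(t) for t in counts.samples.loc[
            counts.samples["dose_gy"] == dose, "time_h"]} | {0.0}
        for label, sub in split[split["label"] != "ungrouped"].groupby("label"):
            genes = [g for g in sub["gene_id"] if g in counts.values.index]
            if not genes:
                continue
            prof = zscore_profiles(counts, genes, dose_gy=dose)
            mean_prof = prof.mean(axis=0)
            for t, v in mean_prof.items():
                if float(t) in have:
                    rows.append({"label": label, "dose_gy": dose,
                                 "time_h": float(t), "mean_z": float(v)})
    return pd.DataFrame(rows, columns=["label", "dose_gy", "time_h", "mean_z"])
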