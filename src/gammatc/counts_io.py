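"""Count-table I/O, transcript-to-gene aggregation and correlation QC.

The quantifier emits fractional *pseudocounts* per transcript and sample.
This module reads those tables together with a sample sheet describing the
time-course design (time point in hours, dose in Gy, replicate id),
collapses splice variants onto genes, and computes the pairwise Pearson
correlation matrix used as a replicate/time-point quality check.

Pseudocounts are kept as reals throughout; rounding to integers happens
only inside the negative-binomial moment stage of :mod:`gammatc.diffexpr`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnnotationError, ConfigurationError, DataError

SHEET_COLUMNS = ["sample_id", "time_h", "dose_gy", "replicate"]

#: correlations are computed on log2(pseudocount + 1); recorded in output
#: metadata because the transformation is a package convention.
PEARSON_TRANSFORM = "log2(pseudocount+1)"


@dataclass
class CountMatrix:
    """Genes (or transcripts) x samples pseudocount matrix with design metadata.

    Parameters
    ----------
    values
        DataFrame of non-negative reals; index = feature ids, columns =
        sample ids (both unique).
    samples
        Sample sheet with columns ``sample_id, time_h, dose_gy, replicate``,
        one row per column of ``values``, in column order.
    biotype
        Per-feature biotype tag. When the annotation lacks one, every
        feature is treated as ``protein_coding`` (the downstream DEG call
        is restricted to protein-coding genes).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    biotype: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise DataError("duplicate feature ids in count matrix")
        if self.values.columns.has_duplicates:
            raise DataError("duplicate sample ids in count matrix")
        if (self.values.to_numpy() < 0).any():
            bad = self.values.index[(self.values < 0).any(axis=1)]
            raise DataError(f"negative pseudocounts for: {', '.join(map(str, bad[:5]))}")
        sheet = self.samples
        missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
        if missing:
            raise ConfigurationError(f"sample sheet lacks columns: {missing}")
        if sheet["sample_id"].duplicated().any():
            raise ConfigurationError("duplicate sample_id in sample sheet")
        if list(sheet["sample_id"]) != list(self.values.columns):
            raise ConfigurationError(
                "sample sheet order/content does not match count-table columns"
            )
        if not (sheet["time_h"] == 0).any():
            raise ConfigurationError("no 0 h reference sample in the design")
        if self.biotype is None:
            self.biotype = pd.Series("protein_coding", index=self.values.index)
        else:
            self.biotype = self.biotype.reindex(self.values.index).fillna("protein_coding")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def time_points(self) -> list[float]:
        return sorted(self.samples["time_h"].unique())

    def samples_at(self, time_h: float, dose_gy: float | None = None) -> list[str]:
        """Sample ids measured at a time point (optionally one dose arm)."""
        mask = self.samples["time_h"] == time_h
        if dose_gy is not None:
            mask &= self.samples["dose_gy"] == dose_gy
        return list(self.samples.loc[mask, "sample_id"])


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ConfigurationError(f"sample sheet {path} lacks columns: {missing}")
    return sheet


def read_counts(table_path: str | Path, sheet_path: str | Path) -> CountMatrix:
    """Read a TSV count table (first column ids, header = sample ids) plus sheet.

    Every sample in the sheet must be a column of the table; extra table
    columns are an error too, so a run never silently drops data. An
    optional ``biotype`` column in the table is split off as the per-gene
    tag.
    """
    sheet = read_sample_sheet(sheet_path)
    table = pd.read_csv(table_path, sep="\t", index_col=0)
    biotype = None
    if "biotype" in table.columns:
        biotype = table.pop("biotype").astype(str)
    want = list(sheet["sample_id"])
    missing = sorted(set(want) - set(table.columns))
    extra = sorted(set(table.columns) - set(want))
    if missing or extra:
        raise ConfigurationError(
            f"count table vs sheet mismatch: missing={missing} extra={extra}"
        )
    table = table[want].astype(float)
    return CountMatrix(values=table, samples=sheet, biotype=biotype)


def write_counts(cm: CountMatrix, table_path: str | Path, sheet_path: str | Path,
                 with_biotype: bool = False) -> None:
    """Write a CountMatrix back to the same two-file TSV layout."""
    out = cm.values.copy()
    if with_biotype:
        out.insert(0, "biotype", cm.biotype)
    out.index.name = "feature_id"
    out.to_csv(table_path, sep="\t", float_format="%.6g")
    cm.samples.to_csv(sheet_path, sep="\t", index=False)


def read_tx2gene(path: str | Path) -> dict[str, str]:
    """Two-column TSV transcript_id -> gene_id (many-to-one)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["transcript_id", "gene_id"],
                     dtype=str, comment="#")
    if df["transcript_id"].duplicated().any():
        dup = df.loc[df["transcript_id"].duplicated(), "transcript_id"].tolist()
        raise AnnotationError(f"transcripts mapped to more than one gene: {dup[:5]}")
    return dict(zip(df["transcript_id"], df["gene_id"]))


def aggregate_transcripts(tx_counts: CountMatrix, tx2gene: dict[str, str]) -> CountMatrix:
    """Sum splice-variant pseudocounts onto their annotated gene.

    Column sums are conserved exactly: every transcript must be mapped,
    and a gene's value is the plain per-sample sum over its transcripts.
    """
    unmapped = [t for t in tx_counts.values.index if t not in tx2gene]
    if unmapped:
        raise AnnotationError(f"unmapped transcripts: {', '.join(unmapped[:10])}"
                              + (" ..." if len(unmapped) > 10 else ""))
    genes = tx_counts.values.index.map(tx2gene.get)
    agg = tx_counts.values.groupby(genes, sort=True).sum()
    agg.index.name = "gene_id"
    # biotype of a gene = biotype of its transcripts (first seen)
    bt = tx_counts.biotype.groupby(genes, sort=True).first()
    return CountMatrix(values=agg, samples=tx_counts.samples, biotype=bt)


def pairwise_pearson(counts: CountMatrix) -> pd.DataFrame:
    """Samples x samples Pearson correlation on log2(pseudocount+1).

    A sample that is constant in log space has undefined correlations;
    those entries are reported as NaN rather than raising, so the QC
    table always renders.
    """
    if counts.values.shape[1] < 2 or counts.values.shape[0] < 3:
        raise DataError("pairwise_pearson needs >=2 samples and >=3 genes")
    logx = np.log2(counts.values.to_numpy(dtype=float) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(logx, rowvar=False)
    sd = logx.std(axis=0)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=counts.sample_ids, columns=counts.sample_ids)
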