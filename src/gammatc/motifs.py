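"""Promoter extraction and PWM similarity scanning.

Promoters are the 4 kb windows 2 kb up- and downstream of each TSS.
Each window is scanned on both strands with p53-family position-weight
matrices; a match is reported when its min--max-normalized log-odds
score (the "similarity") reaches the threshold, 0.85 by default.

Coordinates: input TSS tables are 1-based inclusive (genome-browser
dialect); internally everything is 0-based half-open; reported hit
offsets are 0-based within the extracted promoter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .errors import DataError

MIN_SIMILARITY = 0.85
HALF_WINDOW = 2000
PROB_FLOOR = 1e-3  # pseudo-probability per PWM cell before log-odds
_BACKGROUND = 0.25  # uniform background per base

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position-probability matrix over A, C, G, T."""

    name: str
    matrix: np.ndarray  # L x 4 probabilities

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 4:
            raise DataError(f"PWM {self.name}: need an Lx4 matrix with L >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise DataError(f"PWM {self.name}: columns must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """L x 4 log-odds vs the uniform background, probability-floored."""
        probs = np.clip(self.matrix, PROB_FLOOR, None)
        return np.log(probs / _BACKGROUND)

    def reverse_complement(self) -> "PWM":
        return PWM(name=self.name, matrix=self.matrix[::-1, ::-1])


def read_pwms(path: str | Path) -> list[PWM]:
    """Minimal PPM text format: '>name' line, then L rows of 4 frequencies."""
    pwms: list[PWM] = []
    name, rows = None, []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if name is not None:
                pwms.append(PWM(name=name, matrix=np.array(rows)))
            name, rows = line[1:].strip(), []
        else:
            rows.append([float(v) for v in line.split()])
    if name is not None:
        pwms.append(PWM(name=name, matrix=np.array(rows)))
    if not pwms:
        raise DataError(f"no PWMs found in {path}")
    return pwms


def write_pwms(pwms: list[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene_id, chromosome, tss (1-based), strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    need = {"gene_id", "chromosome", "tss", "strand"}
    if not need <= set(df.columns):
        raise DataError(f"TSS table lacks columns: {sorted(need - set(df.columns))}")
    if (df["tss"] < 1).any() or not df["strand"].isin(["+", "-"]).all():
        raise DataError("TSS table: tss must be >= 1 and strand one of +/-")
    return df


def extract_promoters(tss: pd.DataFrame, genome: str | Path | Fasta,
                      half_window: int = HALF_WINDOW) -> pd.DataFrame:
    """Gene -> promoter sequence: [tss - hw, tss + hw) around each TSS.

    The 1-based TSS is converted to 0-based; windows are clipped at the
    chromosome ends (flagged ``truncated``); minus-strand promoters are
    reverse-complemented so the sequence reads 5'->3' on the gene's
    strand. Columns: gene_id, chromosome, start (0-based), end, strand,
    truncated, sequence.
    """
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    missing = sorted({c for c in tss["chromosome"] if c not in fa})
    if missing:
        genes = tss.loc[tss["chromosome"].isin(missing), "gene_id"].tolist()
        raise DataError(f"chromosomes {missing} absent from genome "
                        f"(genes: {genes[:10]})")
    rows = []
    for _, row in tss.iterrows():
        chrom_len = len(fa[row["chromosome"]])
        tss0 = int(row["tss"]) - 1
        start = max(0, tss0 - half_window)
        end = min(chrom_len, tss0 + half_window)
        seq = str(fa[row["chromosome"]][start:end]).upper()
        if row["strand"] == "-":
            seq = reverse_complement(seq)
        rows.append({
            "gene_id": row["gene_id"], "chromosome": row["chromosome"],
            "start": start, "end": end, "strand": row["strand"],
            "truncated": (end - start) < 2 * half_window, "sequence": seq,
        })
    return pd.DataFrame(rows)


def _scores_one_strand(seq: str, lods: np.ndarray) -> np.ndarray:
    """Sliding log-odds score at every offset; N scores the column minimum."""
    L = lods.shape[0]
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0)
    col_min = lods.min(axis=1)
    # per-position contribution lookup: row = position in seq, col = PWM column
    idx = np.fromiter((_BASE_INDEX.get(b, -1) for b in seq), dtype=np.int64,
                      count=len(seq))
    contrib = np.empty((len(seq), L))
    for j in range(L):
        vals = np.where(idx >= 0, lods[j, np.clip(idx, 0, 3)], col_min[j])
        contrib[:, j] = vals
    scores = np.zeros(n)
    for j in range(L):
        scores += contrib[j : j + n, j]
    return scores


def pwm_similarity_scan(sequence: str, pwm: PWM,
                        min_sim: float = MIN_SIMILARITY) -> pd.DataFrame:
    """Both-strand scan returning offsets with similarity >= min_sim.

    similarity = (score - min_score) / (max_score - min_score), where
    min/max are the worst/best scores attainable by any sequence, so
    the consensus scores exactly 1 and the anti-consensus exactly 0.
    Offsets are 0-based positions of the match's leftmost base on the
    forward (input) sequence for both strands. Columns: offset, strand,
    similarity; sorted by offset then strand.
    """
    if not 0.0 <= min_sim <= 1.0:
        raise DataError("min_sim must be in [0,1]")
    seq = sequence.upper()
    lods = pwm.log_odds()
    smin, smax = lods.min(axis=1).sum(), lods.max(axis=1).sum()
    span = smax - smin
    rows = []
    for strand, mat in (("+", lods), ("-", pwm.reverse_complement().log_odds())):
        scores = _scores_one_strand(seq, mat)
        sims = (scores - smin) / span
        for off in np.nonzero(sims >= min_sim - 1e-12)[0]:
            rows.append({"offset": int(off), "strand": strand,
                         "similarity": float(sims[off])})
    out = pd.DataFrame(rows, columns=["offset", "strand", "similarity"])
    return out.sort_values(["offset", "strand"]).reset_index(drop=True)


def scan_promoters(promoters: pd.DataFrame, pwms: list[PWM],
                   min_sim: float = MIN_SIMILARITY) -> pd.DataFrame:
    """Scan every promoter with every PWM; long table of hits."""
    rows = []
    for _, prom in promoters.iterrows():
        for pwm in pwms:
            hits = pwm_similarity_scan(prom["sequence"], pwm, min_sim)
            for _, h in hits.iterrows():
                rows.append({"gene_id": prom["gene_id"], "motif": pwm.name,
                             "offset": int(h["offset"]), "strand": h["strand"],
                             "similarity": h["similarity"]})
    return pd.DataFrame(rows, columns=["gene_id", "motif", "offset",
                                       "strand", "similarity"])
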