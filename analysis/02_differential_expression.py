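#!/usr/bin/env python
"""Differential expression of every post-irradiation time point vs 0 h.

Reads the simulated counts from step 01, runs the sample-correlation QC
and the NB Wald stage (size factors, trended dispersions, per-contrast
BH), and calls DEGs at |log2FC| > 1 and adjusted p < 0.05. Writes the
QC matrix, the full DE table and the DEG list under results/02_de/.
"""

import argparse
from pathlib import Path

from gammatc import counts_io, diffexpr


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fixtures", type=Path,
                    default=Path("results") / "fixtures")
    ap.add_argument("--out", type=Path, default=Path("results") / "02_de")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cm = counts_io.read_counts(args.fixtures / "counts.tsv",
                               args.fixtures / "samples.tsv")
    corr = counts_io.pairwise_pearson(cm)
    corr.to_csv(args.out / "pearson.tsv", sep="\t", float_format="%.4f")
    off_diag = corr.where(~(corr == 1.0)).stack()
    print(f"pairwise Pearson (log2 scale): min {off_diag.min():.3f}, "
          f"median {off_diag.median():.3f} over {len(cm.sample_ids)} samples")

    # DE runs on the high-dose arm; the low-dose singletons are compared
    # cluster-wise in step 05
    result = diffexpr.run_de(cm, dose_gy=0.5)
    result.table.to_csv(args.out / "de_results.tsv", sep="\t", index=False,
                        float_format="%.6g")
    degs = diffexpr.call_degs(result, biotype=cm.biotype)
    with open(args.out / "deg_list.tsv", "w") as fh:
        fh.write("gene_id\ttimes\n")
        for g in sorted(degs):
            fh.write(f"{g}\t{','.join(f'{t:g}' for t in degs[g]['times'])}\n")
    print(f"{len(degs)} protein-coding DEGs at |log2FC|>1, padj<0.05 "
          f"({ (result.table['is_de']).sum() } significant gene x time tests)")


if __name__ == "__main__":
    main()
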