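#!/usr/bin/env python
"""Generate the synthetic study-condition inputs for the downstream steps.

Emulates the irradiated-oocyte time-course design: five time points
(0, 1, 2.5, 4, 6 h), duplicates at 0/1/4 h and singletons at 2.5/6 h,
NB pseudocounts with 8-fold cluster-shaped planted effects, plus the toy
GO DAG, toy genome with planted p53-family motifs, and a qPCR plate.
Writes everything under results/fixtures/.
"""

import argparse
from pathlib import Path

import numpy as np

from gammatc import counts_io, motifs
from gammatc.simulate import (SimConfig, generate_counts, generate_ct,
                              generate_genome, generate_go,
                              write_genome_fasta)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path,
                    default=Path("results") / "fixtures")
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(seed=args.seed, n_genes=600,
                    baseline_log_mean=float(np.log(200.0)),
                    baseline_log_sd=0.3, dispersion=0.05,
                    with_low_dose=True)
    cm, truth = generate_counts(cfg)
    counts_io.write_counts(cm, out / "counts.tsv", out / "samples.tsv")
    truth.to_csv(out / "truth_counts.tsv", sep="\t", index=False)

    bundle = generate_go(cfg)
    bundle["terms"].to_csv(out / "go_terms.tsv", sep="\t", index=False)
    bundle["edges"].to_csv(out / "go_edges.tsv", sep="\t", index=False)
    with open(out / "go_annotation.tsv", "w") as fh:
        for g in sorted(bundle["direct"]):
            for t in sorted(bundle["direct"][g]):
                fh.write(f"{g}\t{t}\n")
    with open(out / "umbrella_map.tsv", "w") as fh:
        for t in sorted(bundle["umbrella_map"]):
            fh.write(f"{t}\t{bundle['umbrella_map'][t]}\n")
    (out / "truth_keyword_genes.txt").write_text(
        "\n".join(sorted(bundle["keyword_genes"])) + "\n")

    gen = generate_genome(cfg)
    write_genome_fasta(gen["genome"], out / "genome.fa")
    gen["tss"].to_csv(out / "tss.tsv", sep="\t", index=False)
    motifs.write_pwms(gen["pwms"], out / "pwms.txt")
    gen["truth"].to_csv(out / "truth_motifs.tsv", sep="\t", index=False)

    ct = generate_ct(cfg)
    ct["table"].to_csv(out / "ct_table.tsv", sep="\t", index=False,
                       float_format="%.4f")

    print(f"wrote fixtures for {cfg.n_genes} genes "
          f"({len(truth)} planted DE, {len(bundle['keyword_genes'])} keyword, "
          f"{len(gen['truth'])} planted motifs) to {out}")


if __name__ == "__main__":
    main()
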