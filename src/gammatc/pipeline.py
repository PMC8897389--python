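"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes counts -> differential expression -> temporal
clustering -> GO enrichment -> comparisons -> motif scan from a single
config, writing each stage's TSV outputs plus a machine-readable JSON
summary into the output directory. Every decision flag (BH family, PCA
transform, keyword set) is recorded in the report so a run is fully
auditable. Intermediates are sufficient to resume: each stage reads only
files written before it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, compare, counts_io, diffexpr, go as go_mod, motifs
from .errors import ConfigurationError, GammatcError

log = logging.getLogger("gammatc")

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    counts: str
    sample_sheet: str
    out_dir: str
    go_terms: str | None = None
    go_edges: str | None = None
    go_annotation: str | None = None
    umbrella_map: str | None = None
    gene_lists: dict[str, str] = field(default_factory=dict)
    genome: str | None = None
    tss_table: str | None = None
    pwms: str | None = None
    ct_table: str | None = None
    ct_target: str | None = None
    ct_reference: str | None = None
    ct_calibrator: str | None = None
    lfc_min: float = 1.0
    alpha: float = 0.05
    bh_family: str = "per_contrast"
    keywords: tuple[str, ...] = go_mod.DEFAULT_KEYWORDS
    min_similarity: float = motifs.MIN_SIMILARITY
    pca_genes: str | None = None  # optional path: restrict PCA to these genes
    dose_gy: float | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "keywords" in raw:
            raw["keywords"] = tuple(raw["keywords"])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("counts", "sample_sheet"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, **kw)


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage in order; return the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "flags": {
            "bh_family": config.bh_family,
            "pearson_transform": counts_io.PEARSON_TRANSFORM,
            "pca_transform": compare.PCA_TRANSFORM,
            "keywords": list(config.keywords),
            "min_similarity": config.min_similarity,
            "lfc_min": config.lfc_min,
            "alpha": config.alpha,
            "seed": config.seed,
        },
        "stages": [],
    }

    def stage(name):
        report["stages"].append(name)
        log.info("stage: %s", name)

    try:
        stage("counts_io")
        cm = counts_io.read_counts(config.counts, config.sample_sheet)
        corr = counts_io.pairwise_pearson(cm)
        corr.to_csv(out / "pearson.tsv", sep="\t", float_format=FLOAT_FMT)
        report["n_genes"] = len(cm.gene_ids)
        report["n_samples"] = len(cm.sample_ids)
        report["min_pearson"] = float(pd.DataFrame(corr).min().min())

        stage("diffexpr")
        thresholds = diffexpr.DEThresholds(config.lfc_min, config.alpha)
        de = diffexpr.run_de(cm, thresholds, dose_gy=config.dose_gy,
                             bh_family=config.bh_family)
        _write(de.table, out / "de_results.tsv")
        degs = diffexpr.call_degs(de, biotype=cm.biotype)
        report["n_deg"] = len(degs)

        stage("temporal_clustering")
        assignment = clustering.assign_clusters(degs)
        split = clustering.split_up_down(assignment, de) if len(assignment) \
            else assignment.assign(direction=[], mean_log2fc=[], signs=[],
                                   mixed=[], label=[])
        _write(split, out / "clusters.tsv")
        deg_list = sorted(degs)
        profiles = clustering.zscore_profiles(cm, deg_list)
        profiles.index.name = "gene_id"
        profiles.to_csv(out / "zscore_profiles.tsv", sep="\t",
                        float_format=FLOAT_FMT)
        gf = clustering.grouped_fraction(assignment)
        report["grouped_fraction"] = None if pd.isna(gf) else gf
        report["cluster_sizes"] = ({} if len(split) == 0 else
                                   clustering.cluster_sizes(split).to_dict())

        if config.go_terms and config.go_edges and config.go_annotation \
                and config.umbrella_map:
            stage("go_enrichment")
            gograph = go_mod.GOGraph.read(config.go_terms, config.go_edges)
            annotation = go_mod.read_annotations(config.go_annotation)
            annotation = go_mod.annotate_genes(annotation, gograph)
            umbrella = go_mod.read_umbrella_map(config.umbrella_map)
            background = {g for g in cm.gene_ids
                          if cm.biotype[g] == "protein_coding"
                          and (cm.values.loc[g] > 0).any()}
            enr_frames = []
            enriched = {}
            for label, sub in split.groupby("cluster"):
                if label == clustering.UNGROUPED:
                    continue
                cluster_genes = set(sub["gene_id"]) & background
                if not cluster_genes:
                    continue
                res = go_mod.overrepresentation(cluster_genes, background,
                                                annotation, umbrella,
                                                alpha=config.alpha)
                res.insert(0, "cluster", label)
                enr_frames.append(res)
                enriched[label] = res.loc[res["overrepresented"],
                                          "umbrella"].tolist()
            if enr_frames:
                _write(pd.concat(enr_frames, ignore_index=True),
                       out / "enrichment.tsv")
            else:
                _write(pd.DataFrame(columns=["cluster", "umbrella", "k", "n",
                                             "K", "N", "enrichment_factor",
                                             "p", "padj", "overrepresented"]),
                       out / "enrichment.tsv")
            report["enriched_umbrellas"] = enriched
            mined = go_mod.word_mine(
                {g: annotation.get(g, set()) for g in degs},
                gograph, config.keywords)
            (out / "word_mined_genes.txt").write_text(
                "\n".join(sorted(mined)) + ("\n" if mined else ""))
            report["n_word_mined"] = len(mined)

        stage("compare")
        overlaps = {}
        deg_symbols = set(degs)
        for label, path in config.gene_lists.items():
            other = compare.read_gene_list(path)
            inter, size = compare.overlap(deg_symbols, other)
            overlaps[label] = {"size": size, "genes": sorted(inter)}
        report["overlaps"] = overlaps
        pca_genes = None
        if config.pca_genes:
            pca_genes = sorted(compare.read_gene_list(config.pca_genes)
                               & set(cm.gene_ids))
        pca = compare.pca_variance(cm, genes=pca_genes)
        coords = pca["coordinates"].copy()
        coords.insert(0, "sample_id", coords.index)
        _write(coords, out / "pca.tsv")
        report["pc_variance_fractions"] = [
            round(float(v), 6) for v in pca["variance_fraction"][:5]]
        if config.ct_table:
            ct = compare.read_ct_table(config.ct_table)
            folds = compare.ddct_fold(ct, config.ct_target,
                                      config.ct_reference,
                                      config.ct_calibrator)
            _write(folds, out / "qpcr_folds.tsv")
            summary = compare.mean_fold_induction(folds)
            _write(summary, out / "qpcr_summary.tsv")
            report["qpcr_mean_folds"] = {
                r["sample_id"]: round(float(r["mean_fold"]), 6)
                for _, r in summary.iterrows()}

        if config.genome and config.tss_table and config.pwms:
            stage("motif_scan")
            tss = motifs.read_tss_table(config.tss_table)
            promoters = motifs.extract_promoters(tss, config.genome)
            pwms = motifs.read_pwms(config.pwms)
            hits = motifs.scan_promoters(promoters, pwms,
                                         min_sim=config.min_similarity)
            _write(hits, out / "motif_hits.tsv")
            report["n_motif_hits"] = len(hits)
            report["genes_with_motif"] = sorted(hits["gene_id"].unique())
    except GammatcError as err:
        err.stage = report["stages"][-1] if report["stages"] else "config"
        raise

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
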