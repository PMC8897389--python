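"""Synthetic fixtures emulating the irradiated-oocyte time-course study.

Everything the pipeline consumes can be generated here, deterministically
from a seed:

* negative-binomial pseudocount matrices over the study design — five
  time points (0, 1, 2.5, 4, 6 h) with duplicates at 0, 1 and 4 h and
  single libraries at 2.5 and 6 h — with cluster-shaped planted fold
  changes and deliberate library-size heterogeneity (so size-factor
  correctness is load-bearing end to end);
* a toy GO DAG containing the canonical level chain (root ->
  signaling -> cytokine production -> type I interferon production),
  gene annotations with a designated keyword-bearing truth subset, and
  a level-3 -> umbrella map;
* a toy genome (random ~50 kb chromosomes) with TSSs on both strands,
  p53-family position-probability matrices, and exact consensus
  insertions planted into a known promoter subset;
* qPCR Ct tables with planted fold inductions against a housekeeping
  reference;
* synthetic stand-ins for the study's summary tables
  (:func:`generate_study_tables`) that plant the study's headline
  structure — 167 protein-coding DEGs, 151 of them grouped, 19 keyword
  genes, the 1.33x / 1.6x fold groups, the 3/8 literature overlaps and
  a ~80% PC1–3 sample structure — so the downstream arithmetic can be
  exercised without the real deposited data.

All generators are pure functions of their config (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import CLUSTER_PATTERNS
from .counts_io import CountMatrix
from .errors import ConfigurationError
from .go import GOGraph
from .motifs import PWM, reverse_complement

STUDY_TIMES = (0.0, 1.0, 2.5, 4.0, 6.0)
STUDY_REPLICATES = (2, 2, 1, 2, 1)
HIGH_DOSE_GY = 0.5
LOW_DOSE_GY = 0.2


@dataclass
class SimConfig:
    """Study-condition parameters of the count simulator.

    Defaults are the study's own design where it states one (time grid,
    replicate scheme, doses); effect sizes default to 8-fold (log2fc 3)
    on a log-normal baseline with median ~100 and NB dispersion 0.05.
    """

    seed: int
    n_genes: int = 2000
    n_de_per_pattern: int = 4
    baseline_log_mean: float = float(np.log(100.0))  # log-normal median 100
    baseline_log_sd: float = 1.0
    dispersion: float = 0.05
    effect_log2fc: float = 3.0
    times: tuple[float, ...] = STUDY_TIMES
    replicates: tuple[int, ...] = STUDY_REPLICATES
    dose_gy: float = HIGH_DOSE_GY
    with_low_dose: bool = False
    low_dose_gy: float = LOW_DOSE_GY
    low_dose_effect_scale: float = 0.6
    libsize_range: tuple[float, float] = (0.7, 1.4)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.replicates):
            raise ConfigurationError("times and replicates must align")
        n_planted = self.n_de_per_pattern * len(CLUSTER_PATTERNS)
        if n_planted > self.n_genes:
            raise ConfigurationError(
                f"{n_planted} planted DE genes exceed n_genes={self.n_genes}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             alpha: float) -> np.ndarray:
    """NB with variance mu + alpha mu^2 (Poisson when alpha == 0)."""
    mean = np.clip(mean, 1e-8, None)
    if alpha <= 0:
        return rng.poisson(mean).astype(float)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def generate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """NB time-course counts with planted cluster-shaped effects + truth table.

    Null genes draw NB(baseline x library factor, dispersion) in every
    sample. Each of the eight cluster patterns receives
    ``n_de_per_pattern`` planted genes (directions alternating up/down)
    whose mean is multiplied by 2**(+/- effect_log2fc) exactly at the
    pattern's time points. With ``with_low_dose`` an unreplicated 0.2 Gy
    arm is added whose planted effects are scaled down
    (``low_dose_effect_scale``), emulating the attenuated low-dose
    response. Truth columns: gene_id, pattern, direction, log2fc.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    baseline = np.exp(rng.normal(config.baseline_log_mean,
                                 config.baseline_log_sd, config.n_genes))

    # planted genes: contiguous ids at the front, pattern by pattern
    truth_rows = []
    plan: dict[int, tuple[frozenset[float], float]] = {}
    gi = 0
    for label in sorted(CLUSTER_PATTERNS):
        pattern = CLUSTER_PATTERNS[label]
        for j in range(config.n_de_per_pattern):
            sign = 1.0 if j % 2 == 0 else -1.0
            lfc = sign * config.effect_log2fc
            plan[gi] = (pattern, lfc)
            truth_rows.append({
                "gene_id": genes[gi], "pattern": ",".join(
                    f"{t:g}" for t in sorted(pattern)),
                "direction": "u" if sign > 0 else "d",
                "log2fc": lfc, "cluster": label,
            })
            gi += 1
    truth = pd.DataFrame(truth_rows,
                         columns=["gene_id", "pattern", "direction",
                                  "log2fc", "cluster"])

    arms = [(config.dose_gy, config.replicates, 1.0)]
    if config.with_low_dose:
        arms.append((config.low_dose_gy, (1,) * len(config.times),
                     config.low_dose_effect_scale))

    sample_rows, columns = [], {}
    for dose, reps, scale in arms:
        for t, n_rep in zip(config.times, reps):
            for r in range(1, n_rep + 1):
                sid = f"d{dose:g}_t{t:g}_r{r}"
                sample_rows.append({"sample_id": sid, "time_h": t,
                                    "dose_gy": dose, "replicate": r})
                sf = rng.uniform(*(np.log(config.libsize_range)))
                sf = float(np.exp(sf))
                mu = baseline.copy()
                for idx, (pattern, lfc) in plan.items():
                    if t in pattern:
                        mu[idx] = baseline[idx] * 2.0 ** (lfc * scale)
                columns[sid] = _nb_draw(rng, mu * sf, config.dispersion)

    sheet = pd.DataFrame(sample_rows)
    values = pd.DataFrame(columns, index=genes)
    cm = CountMatrix(values=values, samples=sheet,
                     biotype=pd.Series("protein_coding", index=genes))
    return cm, truth


# --- toy GO DAG -----------------------------------------------------------

_LEVEL2 = ["signaling", "metabolic process", "developmental process",
           "cell death", "response to stimulus", "biological regulation",
           "biological adhesion", "cellular component organization"]

#: level-3 terms with their level-2 parent and umbrella label; the
#: keyword-bearing names feed the word-mining truth subset.
_LEVEL3 = [
    ("cytokine production", "signaling", "signaling"),
    ("signal transduction", "signaling", "signaling"),
    ("apoptosis", "cell death", "cell death"),
    ("regulation of apoptosis", "cell death", "cell death"),
    ("necroptosis", "cell death", "cell death"),
    ("programmed necrosis", "cell death", "cell death"),
    ("DNA repair", "response to stimulus", "DNA damage and repair"),
    ("cellular response to DNA damage stimulus", "response to stimulus",
     "DNA damage and repair"),
    ("stress response", "response to stimulus", "stress response"),
    ("response to radiation", "response to stimulus", "stress response"),
    ("lipid metabolic process", "metabolic process", "metabolism"),
    ("carbohydrate metabolic process", "metabolic process", "metabolism"),
    ("tissue development", "developmental process", "development"),
    ("organ morphogenesis", "developmental process", "development"),
    ("regulation of transcription", "biological regulation", "regulation"),
    ("regulation of cell cycle", "biological regulation", "regulation"),
    ("cell adhesion", "biological adhesion", "adhesion"),
    ("cell-matrix adhesion", "biological adhesion", "adhesion"),
    ("organelle organization", "cellular component organization",
     "organization"),
    ("cytoskeleton organization", "cellular component organization",
     "organization"),
]

_LEVEL4 = [
    ("type I interferon production", ["cytokine production"]),
    ("double-strand break repair", ["DNA repair"]),
    # two parents at levels 2 and 3: shortest path puts it at level 3
    ("intrinsic apoptotic signaling pathway", ["apoptosis", "cell death"]),
]

#: level-3 term names whose genes are word-mining hits under the
#: default keyword set.
KEYWORD_TERMS = ("apoptosis", "regulation of apoptosis", "necroptosis",
                 "programmed necrosis", "DNA repair",
                 "cellular response to DNA damage stimulus")


def generate_go(config: SimConfig, gene_ids: list[str] | None = None,
                n_keyword_genes: int = 19) -> dict:
    """Toy GO bundle: graph, closed annotations, umbrella map, truth subset.

    The DAG contains the worked level chain (signaling level 2, cytokine
    production level 3, type I interferon production level 4). The first
    ``n_keyword_genes`` gene ids form the keyword truth subset: each is
    annotated with at least one death/damage keyword term; all other
    genes draw only non-keyword level-3/4 terms.
    """
    rng = np.random.default_rng(config.seed + 1)
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]

    term_rows = [{"id": "GO:ROOT", "name": "biological_process",
                  "namespace": "biological_process"}]
    edge_rows = []
    name_to_id = {"biological_process": "GO:ROOT"}
    tid = 1

    def add_term(name: str, parents: list[str]) -> str:
        nonlocal tid
        term_id = f"GO:{tid:07d}"
        tid += 1
        term_rows.append({"id": term_id, "name": name,
                          "namespace": "biological_process"})
        name_to_id[name] = term_id
        for p in parents:
            edge_rows.append({"child": term_id, "parent": name_to_id[p]})
        return term_id

    for name in _LEVEL2:
        add_term(name, ["biological_process"])
    for name, parent, _ in _LEVEL3:
        add_term(name, [parent])
    for name, parents in _LEVEL4:
        add_term(name, parents)

    terms = pd.DataFrame(term_rows)
    edges = pd.DataFrame(edge_rows)
    go = GOGraph.from_tables(terms, edges)

    umbrella_map = {name_to_id[name]: umbrella for name, _, umbrella in _LEVEL3}

    keyword_ids = [name_to_id[n] for n in KEYWORD_TERMS]
    other_ids = [name_to_id[n] for n, _, _ in _LEVEL3
                 if n not in KEYWORD_TERMS]
    keyword_genes = set(gene_ids[:n_keyword_genes])
    direct: dict[str, set[str]] = {}
    for i, g in enumerate(gene_ids):
        if g in keyword_genes:
            picks = {keyword_ids[i % len(keyword_ids)]}
            picks.add(other_ids[int(rng.integers(len(other_ids)))])
        else:
            k = int(rng.integers(1, 4))
            picks = {other_ids[int(j)] for j in rng.integers(0, len(other_ids), k)}
        direct[g] = picks

    from .go import annotate_genes
    annotation = annotate_genes(direct, go)
    return {"graph": go, "terms": terms, "edges": edges,
            "annotation": annotation, "direct": direct,
            "umbrella_map": umbrella_map, "keyword_genes": keyword_genes}


# --- toy genome with planted motifs ---------------------------------------

def _p53_like_pwm(name: str, rng: np.random.Generator,
                  major: float = 0.91) -> PWM:
    """A p53-family half-site-like PPM (RRRCWWGYYY backbone, 10 columns)."""
    consensus_bases = {"R": "AG", "W": "AT", "Y": "CT",
                       "A": "A", "C": "C", "G": "G", "T": "T"}
    backbone = "RRRCWWGYYY"
    minor = (1.0 - major) / 3.0
    rows = []
    for code in backbone:
        allowed = consensus_bases[code]
        pick = allowed[int(rng.integers(len(allowed)))]
        row = np.full(4, minor)
        row["ACGT".index(pick)] = major
        rows.append(row)
    return PWM(name=name, matrix=np.array(rows))


def generate_genome(config: SimConfig, n_chromosomes: int = 2,
                    chrom_len: int = 50_000, n_genes: int = 8,
                    n_planted: int = 4) -> dict:
    """Toy chromosomes, a TSS table, two PWMs and planted consensus motifs.

    ``n_planted`` of the ``n_genes`` promoters receive an exact PWM
    consensus insertion within +/-2 kb of their TSS (alternating strand
    of insertion); the rest stay random background. Truth columns:
    gene_id, motif, genomic insertion offset, promoter offset, strand.
    """
    rng = np.random.default_rng(config.seed + 2)
    chroms = {f"chr{i+1}": rng.choice(list("ACGT"), size=chrom_len)
              for i in range(n_chromosomes)}
    pwms = [_p53_like_pwm("p53_motif_1", rng), _p53_like_pwm("p53_motif_4", rng)]

    tss_rows, truth_rows = [], []
    for i in range(n_genes):
        chrom = f"chr{(i % n_chromosomes) + 1}"
        tss = int(rng.integers(5000, chrom_len - 5000))  # 1-based
        strand = "+" if i % 2 == 0 else "-"
        gene = f"PG{i:03d}"
        tss_rows.append({"gene_id": gene, "chromosome": chrom,
                         "tss": tss, "strand": strand})
        if i < n_planted:
            pwm = pwms[i % len(pwms)]
            cons = pwm.consensus
            offset_in_window = int(rng.integers(100, 4000 - len(cons) - 100))
            start0 = (tss - 1) - 2000 + offset_in_window
            ins_strand = "+" if i % 2 == 0 else "-"
            planted = cons if ins_strand == "+" else reverse_complement(cons)
            chroms[chrom][start0:start0 + len(cons)] = list(planted)
            truth_rows.append({"gene_id": gene, "motif": pwm.name,
                               "genome_offset": start0,
                               "window_offset": offset_in_window,
                               "insert_strand": ins_strand})
    genome = {c: "".join(seq) for c, seq in chroms.items()}
    return {"genome": genome,
            "tss": pd.DataFrame(tss_rows),
            "pwms": pwms,
            "truth": pd.DataFrame(truth_rows)}


def write_genome_fasta(genome: dict[str, str], path: str | Path,
                       width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# --- qPCR Ct tables --------------------------------------------------------

def generate_ct(config: SimConfig, targets: tuple[str, ...] = ("Pmaip1", "Mdm2"),
                reference: str = "Tbp", n_replicates: int = 3,
                planted_fold: float = 4.0, noise_sd: float = 0.05) -> dict:
    """Ct table with a planted fold induction after irradiation.

    Two conditions per biological replicate (mock / irradiated); the
    target's irradiated Ct drops by log2(planted_fold) relative to the
    housekeeping reference, plus small technical noise.
    """
    rng = np.random.default_rng(config.seed + 3)
    rows = []
    for rep in range(1, n_replicates + 1):
        base_ref = 18.0 + rng.normal(0, 0.3)
        base_tgt = {tgt: 24.0 + rng.normal(0, 0.3) for tgt in targets}
        for cond in ("mock", "irr"):
            sid = cond
            shift = rng.normal(0, 0.2)  # sample-wide pipetting offset
            rows.append({"sample_id": sid, "gene": reference,
                         "ct": base_ref + shift + rng.normal(0, noise_sd),
                         "replicate": rep})
            for tgt in targets:
                delta = -np.log2(planted_fold) if cond == "irr" else 0.0
                rows.append({"sample_id": sid, "gene": tgt,
                             "ct": base_tgt[tgt] + delta + shift
                                   + rng.normal(0, noise_sd),
                             "replicate": rep})
    return {"table": pd.DataFrame(rows), "planted_fold": planted_fold,
            "reference": reference, "calibrator": "mock",
            "targets": list(targets)}


# --- synthetic stand-ins for the study's summary tables -------------------

#: named genes carried through the fold/overlap stories (mouse symbols).
GENES_FOLD_UP_2P5H = ["Jag2", "Zmat3", "Traf3", "Phlda3", "Sfn", "Lhx3"]
GENES_FOLD_DOWN = ["Lcn2", "Hhip", "Star", "Cbs"]
GENES_CELL_CYCLE = ["Psrc2", "Ccng1"]
GENES_APOPTOSIS_EXTRA = ["Pmaip1", "Eda2r", "Bbc3x", "Trp53inp1"]

_CLUSTER_SIZES = {"Cl1": 12, "Cl2": 14, "Cl3": 18, "Cl4": 25,
                  "Cl5": 16, "Cl6": 8, "Cl7": 28, "Cl8": 30}  # sums to 151

_OFF_PATTERNS = [frozenset(p) for p in
                 ({1.0, 4.0}, {1.0, 6.0}, {1.0, 2.5}, {2.5, 4.0},
                  {1.0, 2.5, 4.0}, {1.0, 4.0, 6.0}, {1.0, 2.5, 6.0})]


def generate_study_tables(seed: int) -> dict:
    """Synthetic stand-in for the study's deposited summary tables.

    The real deposited data are not desk-scale inputs, so this generator
    plants the study's headline structure into tables of the same shape
    and lets the pipeline re-derive every number from them:

    * a DE table over ~1200 genes in which exactly 167 protein-coding
      genes pass |log2FC| > 1 and padj < 0.05 at >= 1 time point
      (near-miss genes and threshold-passing non-coding genes are
      planted so both thresholds and the biotype filter are
      load-bearing);
    * temporal patterns placing 151 of the 167 into the eight named
      clusters (grouped fraction 151/167 ~ 90%);
    * a toy GO bundle in which exactly 19 of the 151 grouped DEGs carry
      death/damage keyword terms;
    * a normalized-expression matrix in which six named genes average a
      1.33-fold increase at 2.5 h and four named genes run ~1.6-fold
      higher before irradiation;
    * literature lists: a 64-gene p53-target list sharing 8 symbols with
      the DEGs (6 apoptosis-assigned + 2 cell-cycle), and keratinocyte
      iPSC lists of 241 down- / 296 upregulated genes sharing 3 / 8
      symbols with the DEGs;
    * a two-dose pseudocount matrix whose sample structure concentrates
      ~80% of the variance in the first three principal components.
    """
    rng = np.random.default_rng(seed)

    named = (GENES_FOLD_UP_2P5H + GENES_FOLD_DOWN + GENES_CELL_CYCLE
             + GENES_APOPTOSIS_EXTRA)
    n_named = len(named)
    deg_ids = named + [f"Deg{i:04d}" for i in range(167 - n_named)]
    bg_ids = [f"Bkg{i:04d}" for i in range(1013)]
    nc_ids = [f"Linc{i:03d}" for i in range(20)]
    all_ids = deg_ids + bg_ids + nc_ids
    biotype = pd.Series("protein_coding", index=all_ids)
    biotype[nc_ids] = "lincRNA"

    # temporal pattern per DEG: 151 grouped (fixed cluster sizes), 16 not
    patterns: dict[str, frozenset[float]] = {}
    direction: dict[str, float] = {}
    order = list(deg_ids)
    rng.shuffle(order)
    # keep the named fold/overlap genes grouped so downstream stories hold
    order = named + [g for g in order if g not in named]
    pos = 0
    grouped: list[str] = []
    for label in sorted(_CLUSTER_SIZES):
        for _ in range(_CLUSTER_SIZES[label]):
            g = order[pos]
            patterns[g] = CLUSTER_PATTERNS[label]
            if label in ("Cl5", "Cl6"):
                direction[g] = 1.0           # these clusters are all up
            elif label == "Cl8":
                direction[g] = -1.0 if rng.random() < 0.7 else 1.0
            else:
                direction[g] = 1.0 if rng.random() < 0.65 else -1.0
            grouped.append(g)
            pos += 1
    for i, g in enumerate(order[pos:]):
        patterns[g] = _OFF_PATTERNS[i % len(_OFF_PATTERNS)]
        direction[g] = 1.0 if rng.random() < 0.5 else -1.0
    # the named up/down fold genes respond upward / downward respectively
    for g in GENES_FOLD_UP_2P5H:
        direction[g] = 1.0
    for g in GENES_FOLD_DOWN:
        direction[g] = -1.0

    # DE table: gene x timepoint log2fc / p / padj
    timepoints = (1.0, 2.5, 4.0, 6.0)
    near_lfc = set(bg_ids[:30])     # significant padj but |lfc| < 1
    near_padj = set(bg_ids[30:60])  # |lfc| > 1 but padj > 0.05
    rows = []
    for g in all_ids:
        for t in timepoints:
            if g in patterns and t in patterns[g]:
                lfc = direction[g] * rng.uniform(1.2, 4.0)
                padj = rng.uniform(1e-5, 0.045)
            elif g in nc_ids and t == 4.0:
                lfc = rng.uniform(1.5, 3.0)
                padj = rng.uniform(1e-4, 0.04)
            elif g in near_lfc and t == 1.0:
                lfc = rng.uniform(0.5, 0.95) * (1 if rng.random() < 0.5 else -1)
                padj = rng.uniform(1e-3, 0.045)
            elif g in near_padj and t == 6.0:
                lfc = rng.uniform(1.1, 2.5) * (1 if rng.random() < 0.5 else -1)
                padj = rng.uniform(0.06, 0.5)
            else:
                lfc = rng.normal(0, 0.25)
                padj = rng.uniform(0.1, 1.0)
            rows.append({"gene_id": g, "timepoint": t, "log2fc": lfc,
                         "se": 0.25, "p": padj * rng.uniform(0.2, 1.0),
                         "padj": padj})
    de_table = pd.DataFrame(rows)

    # GO bundle: exactly 19 keyword genes among the 151 grouped
    keyword_genes = (GENES_FOLD_UP_2P5H + GENES_APOPTOSIS_EXTRA
                     + [g for g in grouped
                        if g not in named][:19 - len(GENES_FOLD_UP_2P5H)
                                           - len(GENES_APOPTOSIS_EXTRA)])
    go_order = keyword_genes + [g for g in grouped if g not in keyword_genes]
    go_bundle = generate_go(SimConfig(seed=seed), gene_ids=go_order,
                            n_keyword_genes=19)

    # expression matrix for the fold summaries (fold computed with +0.5)
    folds_133 = [1.21, 1.27, 1.30, 1.36, 1.40, 1.44]   # mean 1.33
    folds_160 = [1.50, 1.55, 1.65, 1.70]               # mean 1.60
    filler = [f"Flat{i:03d}" for i in range(200)]
    expr_genes = GENES_FOLD_UP_2P5H + GENES_FOLD_DOWN + filler
    sheet_rows = []
    for t, n_rep in zip(STUDY_TIMES, STUDY_REPLICATES):
        for r in range(1, n_rep + 1):
            sheet_rows.append({"sample_id": f"t{t:g}_r{r}", "time_h": t,
                               "dose_gy": HIGH_DOSE_GY, "replicate": r})
    sheet = pd.DataFrame(sheet_rows)
    expr = pd.DataFrame(0.0, index=expr_genes, columns=sheet["sample_id"])
    base_up = rng.uniform(60, 200, len(GENES_FOLD_UP_2P5H))
    base_dn = rng.uniform(60, 200, len(GENES_FOLD_DOWN))
    for _, s in sheet.iterrows():
        t = s["time_h"]
        for g, m0, f in zip(GENES_FOLD_UP_2P5H, base_up, folds_133):
            expr.loc[g, s["sample_id"]] = (f * (m0 + 0.5) - 0.5) if t == 2.5 else m0
        for g, m1, f in zip(GENES_FOLD_DOWN, base_dn, folds_160):
            # ~1.6-fold higher BEFORE irradiation: 0 h value above the rest
            expr.loc[g, s["sample_id"]] = (f * (m1 + 0.5) - 0.5) if t == 0 else m1
        for i, g in enumerate(filler):
            expr.loc[g, s["sample_id"]] = 100.0 + i
    expr_cm = CountMatrix(values=expr, samples=sheet,
                          biotype=pd.Series("protein_coding", index=expr_genes))

    # literature lists
    apoptosis_six = GENES_FOLD_UP_2P5H  # the six Kenzelmann apoptosis DEGs
    kenzelmann = set(apoptosis_six) | set(GENES_CELL_CYCLE) \
        | {f"P53tgt{i:02d}" for i in range(64 - 8)}
    deg_upper = {g.upper() for g in deg_ids}
    ipsc_down = {f"IPSCDN{i:03d}" for i in range(241 - 3)} \
        | {g.upper() for g in ["Lcn2", "Hhip", "Star"]}
    ipsc_up = {f"IPSCUP{i:03d}" for i in range(296 - 8)} \
        | {g.upper() for g in ["Eda2r", "Pmaip1", "Jag2", "Zmat3",
                               "Traf3", "Phlda3", "Sfn", "Lhx3"]}
    assert len({s for s in ipsc_down} & deg_upper) == 3
    assert len({s for s in ipsc_up} & deg_upper) == 8

    pca_cm = _pca_structured_counts(rng)

    return {
        "de_table": de_table, "biotype": biotype,
        "go": go_bundle, "keyword_genes": set(keyword_genes),
        "expression": expr_cm,
        "genes_fold_up": list(GENES_FOLD_UP_2P5H),
        "genes_fold_down": list(GENES_FOLD_DOWN),
        "kenzelmann": kenzelmann, "apoptosis_six": set(apoptosis_six),
        "ipsc_down": ipsc_down, "ipsc_up": ipsc_up,
        "pca_counts": pca_cm,
        "truth": {"n_deg": 167, "n_grouped": 151, "n_keyword": 19,
                  "pc123_target": 0.80},
    }


def _pca_structured_counts(rng: np.random.Generator,
                           n_samples: int = 13, n_genes: int = 300,
                           pc_fractions: tuple[float, ...] = (0.45, 0.22, 0.13),
                           total_sd: float = 0.8) -> CountMatrix:
    """Two-dose pseudocount matrix with a controlled PCA spectrum.

    The log2 expression matrix is built as mean + U diag(s) V^T with the
    leading squared singular values holding the given variance fractions
    (0.80 in PC1-3 by default) and the remainder spread evenly, so a PCA
    of the log-transformed counts reproduces that structure.
    """
    n_comp = n_samples - 1  # rank after gene-centering
    resid = (1.0 - sum(pc_fractions)) / (n_comp - len(pc_fractions))
    fracs = np.array(list(pc_fractions) + [resid] * (n_comp - len(pc_fractions)))
    total_var = n_samples * n_genes * total_sd**2
    svals = np.sqrt(fracs * total_var)

    # orthonormal sample basis orthogonal to the all-ones vector
    raw = rng.normal(size=(n_samples, n_comp))
    raw -= raw.mean(axis=0, keepdims=True)
    u, _ = np.linalg.qr(raw)
    v, _ = np.linalg.qr(rng.normal(size=(n_genes, n_comp)))
    mu = rng.uniform(6.0, 12.0, n_genes)
    logx = mu[None, :] + u @ np.diag(svals) @ v.T
    counts = np.clip(2.0 ** logx - 1.0, 0.0, None)

    sheet_rows = []
    for dose, reps in ((HIGH_DOSE_GY, STUDY_REPLICATES),
                       (LOW_DOSE_GY, (1,) * len(STUDY_TIMES))):
        for t, n_rep in zip(STUDY_TIMES, reps):
            for r in range(1, n_rep + 1):
                sheet_rows.append({"sample_id": f"d{dose:g}_t{t:g}_r{r}",
                                   "time_h": t, "dose_gy": dose,
                                   "replicate": r})
    sheet = pd.DataFrame(sheet_rows)
    assert len(sheet) == n_samples
    genes = [f"Pca{i:03d}" for i in range(n_genes)]
    values = pd.DataFrame(counts.T, index=genes,
                          columns=sheet["sample_id"])
    return CountMatrix(values=values, samples=sheet,
                       biotype=pd.Series("protein_coding", index=genes))
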