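import numpy as np
import pandas as pd
import pytest

from gammatc import motifs
from gammatc.simulate import (SimConfig, generate_genome, write_genome_fasta)


def brute_force_scan(seq, pwm, min_sim):
    """Independent per-(position, strand) scorer with explicit loops."""
    lods = np.log(np.clip(pwm.matrix, motifs.PROB_FLOOR, None) / 0.25)
    smin = sum(min(col) for col in lods)
    smax = sum(max(col) for col in lods)
    L = len(pwm)
    hits = []
    for strand in ("+", "-"):
        probe = lods if strand == "+" else lods[::-1, ::-1]
        for off in range(len(seq) - L + 1):
            score = 0.0
            for j in range(L):
                base = seq[off + j]
                if base in "ACGT":
                    score += probe[j, "ACGT".index(base)]
                else:
                    score += min(probe[j])
            sim = (score - smin) / (smax - smin)
            if sim >= min_sim - 1e-12:
                hits.append((off, strand, round(sim, 10)))
    return sorted(hits)


def simple_pwm():
    m = np.full((6, 4), 0.04)
    for i, b in enumerate("ACGTAC"):
        m[i, "ACGT".index(b)] = 0.88
    return motifs.PWM(name="toy", matrix=m)


class TestExtractPromoters:
    def make_genome(self, tmp_path, length=10_000):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=length))
        path = tmp_path / "toy.fa"
        write_genome_fasta({"chr1": seq}, path)
        return seq, path

    def test_window_coordinates(self, tmp_path):
        seq, path = self.make_genome(tmp_path)
        tss = pd.DataFrame([{"gene_id": "g", "chromosome": "chr1",
                             "tss": 5000, "strand": "+"}])
        out = motifs.extract_promoters(tss, path)
        row = out.iloc[0]
        assert (row["start"], row["end"]) == (2999, 6999)
        assert len(row["sequence"]) == 4000
        assert row["sequence"] == seq[2999:6999]
        assert not row["truncated"]

    def test_chromosome_start_truncates_and_flags(self, tmp_path):
        _, path = self.make_genome(tmp_path)
        tss = pd.DataFrame([{"gene_id": "g", "chromosome": "chr1",
                             "tss": 1000, "strand": "+"}])
        out = motifs.extract_promoters(tss, path)
        assert len(out.iloc[0]["sequence"]) == 2999
        assert out.iloc[0]["truncated"]

    def test_minus_strand_is_reverse_complement(self, tmp_path):
        _, path = self.make_genome(tmp_path)
        tss = pd.DataFrame([
            {"gene_id": "fw", "chromosome": "chr1", "tss": 5000, "strand": "+"},
            {"gene_id": "rv", "chromosome": "chr1", "tss": 5000, "strand": "-"},
        ])
        out = motifs.extract_promoters(tss, path).set_index("gene_id")
        assert out.loc["rv", "sequence"] == motifs.reverse_complement(
            out.loc["fw", "sequence"])

    def test_missing_chromosome_lists_genes(self, tmp_path):
        _, path = self.make_genome(tmp_path)
        tss = pd.DataFrame([{"gene_id": "lost", "chromosome": "chr9",
                             "tss": 5000, "strand": "+"}])
        with pytest.raises(Exception, match="lost"):
            motifs.extract_promoters(tss, path)


class TestSimilarityScan:
    def test_planted_consensus_scores_exactly_one(self):
        pwm = simple_pwm()
        rng = np.random.default_rng(1)
        bg = "".join(rng.choice(list("ACGT"), size=60))
        seq = bg[:20] + pwm.consensus + bg[20:]
        hits = motifs.pwm_similarity_scan(seq, pwm, min_sim=0.99)
        fw = hits[hits["strand"] == "+"]
        assert 20 in list(fw["offset"])
        assert fw.set_index("offset").loc[20, "similarity"] == pytest.approx(1.0)

    def test_anticonsensus_scores_exactly_zero(self):
        pwm = simple_pwm()
        lods = pwm.log_odds()
        anti = "".join("ACGT"[int(i)] for i in lods.argmin(axis=1))
        hits = motifs.pwm_similarity_scan(anti, pwm, min_sim=0.0)
        fw = hits[(hits["strand"] == "+") & (hits["offset"] == 0)]
        assert fw["similarity"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_all_n_sequence_has_no_hits(self):
        hits = motifs.pwm_similarity_scan("N" * 100, simple_pwm(), min_sim=0.85)
        assert hits.empty

    def test_short_sequence_is_empty(self):
        assert motifs.pwm_similarity_scan("ACG", simple_pwm()).empty

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scorer(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGTN"), size=200,
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        pwm = simple_pwm()
        ours = motifs.pwm_similarity_scan(seq, pwm, min_sim=0.6)
        got = sorted((int(r["offset"]), r["strand"], round(r["similarity"], 10))
                     for _, r in ours.iterrows())
        assert got == brute_force_scan(seq, pwm, 0.6)

    def test_reverse_complement_mirrors_hits(self):
        rng = np.random.default_rng(2)
        pwm = simple_pwm()
        seq = "".join(rng.choice(list("ACGT"), size=150))
        seq = seq[:50] + pwm.consensus + seq[50:]
        fw = motifs.pwm_similarity_scan(seq, pwm, min_sim=0.7)
        rc = motifs.pwm_similarity_scan(motifs.reverse_complement(seq),
                                        pwm, min_sim=0.7)
        L, n = len(pwm), len(seq)
        mirrored = sorted((n - L - int(r["offset"]),
                           "+" if r["strand"] == "-" else "-",
                           round(r["similarity"], 9))
                          for _, r in rc.iterrows())
        original = sorted((int(r["offset"]), r["strand"],
                           round(r["similarity"], 9))
                          for _, r in fw.iterrows())
        assert mirrored == original

    def test_lowering_threshold_only_adds_hits(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        pwm = simple_pwm()
        strict = motifs.pwm_similarity_scan(seq, pwm, min_sim=0.8)
        loose = motifs.pwm_similarity_scan(seq, pwm, min_sim=0.6)
        strict_set = set(map(tuple, strict[["offset", "strand"]].to_numpy()))
        loose_set = set(map(tuple, loose[["offset", "strand"]].to_numpy()))
        assert strict_set <= loose_set


class TestPlantedGenome:
    def test_planted_promoters_carry_perfect_hits(self, tmp_path):
        cfg = SimConfig(seed=7, n_genes=50)
        gen = generate_genome(cfg)
        fa = tmp_path / "g.fa"
        write_genome_fasta(gen["genome"], fa)
        promoters = motifs.extract_promoters(gen["tss"], fa)
        hits = motifs.scan_promoters(promoters, gen["pwms"], min_sim=0.85)
        pwm_by_name = {p.name: p for p in gen["pwms"]}
        for _, row in gen["truth"].iterrows():
            sub = hits[(hits["gene_id"] == row["gene_id"])
                       & (hits["similarity"] >= 1.0 - 1e-9)]
            assert not sub.empty
        # every reported hit is validated by the independent scorer
        proms = promoters.set_index("gene_id")
        for gene, sub in hits.groupby("gene_id"):
            seq = proms.loc[gene, "sequence"]
            for pwm_name, hsub in sub.groupby("motif"):
                expect = brute_force_scan(seq, pwm_by_name[pwm_name], 0.85)
                got = sorted((int(r["offset"]), r["strand"],
                              round(r["similarity"], 10))
                             for _, r in hsub.iterrows())
                assert got == expect

    def test_pwm_text_round_trip(self, tmp_path):
        cfg = SimConfig(seed=8, n_genes=50)
        pwms = generate_genome(cfg)["pwms"]
        path = tmp_path / "p.txt"
        motifs.write_pwms(pwms, path)
        back = motifs.read_pwms(path)
        assert [p.name for p in back] == [p.name for p in pwms]
        for a, b in zip(back, pwms):
            np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-6)
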