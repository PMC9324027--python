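import numpy as np
import pytest

from lncreg import coding, core, filtering, simulate
from lncreg.interactions import genomic_distance
from lncreg.simulate import SimulationConfig, translate_orf


@pytest.fixture(scope="module")
def small_annotation():
    cfg = SimulationConfig(
        seed=7, n_coding_genes=30, n_known_lncrnas=8, n_novel_lncrnas=20,
        n_bait_transcripts=3, n_cis_pairs=2, n_trans_pairs=3, n_duplex_pairs=2,
        n_protein_partners=2, chromosome_length=900_000,
    )
    return cfg, simulate.generate_annotation(cfg)


class TestAnnotation:
    def test_same_seed_identical_outputs(self, small_annotation):
        cfg, (genome, genes, manifest, ref) = small_annotation
        genome2, genes2, manifest2, ref2 = simulate.generate_annotation(cfg)
        assert genome == genome2 and ref == ref2
        assert [t.sequence for g in genes for t in g.transcripts] == [
            t.sequence for g in genes2 for t in g.transcripts
        ]
        assert manifest.expression.equals(manifest2.expression)

    def test_baits_fail_exactly_their_designated_filter(self, small_annotation):
        cfg, (genome, genes, manifest, ref) = small_annotation
        classes = manifest.classes.set_index("transcript_id")
        baits = classes[classes["true_class"] == "bait"]
        assert sorted(baits["bait_reason"]) == sorted(simulate.BAIT_REASONS)
        tx = {t.transcript_id: t for g in genes for t in g.transcripts}
        for tid, row in baits.iterrows():
            t = tx[tid]
            if row["bait_reason"] == "mono_exonic":
                assert t.exon_count == 1 and t.spliced_length > 200
            elif row["bait_reason"] == "too_short":
                assert t.spliced_length <= 200 and t.exon_count >= 2
            else:
                assert t.exon_count >= 2 and t.spliced_length > 200

    def test_structural_filter_removes_each_bait_for_its_reason(self, small_annotation):
        cfg, (genome, genes, manifest, ref) = small_annotation
        counts = simulate.generate_counts(genes, manifest, cfg)
        tx = [t for g in genes for t in g.transcripts]
        totals = {t.transcript_id: float(counts.values.loc[t.gene_id].sum()) for t in tx}
        report = filtering.apply_structural_filters(
            [t for t in tx if t.biotype != "protein_coding"],
            counts=None, counts_by_transcript=totals,
        )
        classes = manifest.classes.set_index("transcript_id")
        baits = classes[classes["true_class"] == "bait"]
        for tid, row in baits.iterrows():
            assert report.status[tid] == "removed"
            assert report.reason[tid] == row["bait_reason"]

    def test_cis_pairs_at_configured_gap(self, small_annotation):
        cfg, (genome, genes, manifest, ref) = small_annotation
        span = {g.gene_id: g.span for g in genes}
        for _, row in manifest.cis_pairs.iterrows():
            d = genomic_distance(span[row["del_gene"]], span[row["deg_gene"]])
            assert d == cfg.cis_gap_bp == row["gap_bp"]

    def test_genome_reextraction_reproduces_transcript_sequences(self, small_annotation):
        cfg, (genome, genes, manifest, ref) = small_annotation
        want = {t.transcript_id: t.sequence for g in genes for t in g.transcripts}
        stripped = [
            core.GeneModel(
                g.gene_id,
                [core.TranscriptModel(t.transcript_id, t.gene_id, t.exons)
                 for t in g.transcripts],
            )
            for g in genes
        ]
        core.extract_transcript_sequences(genome, stripped)
        got = {t.transcript_id: t.sequence for g in stripped for t in g.transcripts}
        assert got == want

    def test_orf_class_separability(self, small_annotation):
        cfg, (genome, genes, manifest, ref) = small_annotation
        classes = manifest.classes.set_index("transcript_id")
        orf_len = {}
        for g in genes:
            for t in g.transcripts:
                o = coding.longest_orf(t.sequence)
                orf_len[t.transcript_id] = o.length if o else 0
        cod = [orf_len[t] for t in classes[classes.true_class == "coding"].index]
        non = [orf_len[t] for t in classes[classes.true_class == "novel_lncRNA"].index]
        assert max(non) < 100 and min(cod) >= 300
        assert np.median(cod) - np.median(non) >= 200

    def test_duplex_pairs_share_exact_reverse_complement_window(self, small_annotation):
        cfg, (genome, genes, manifest, ref) = small_annotation
        seqs = {t.transcript_id: t.sequence for g in genes for t in g.transcripts}
        for _, row in manifest.duplex_pairs.iterrows():
            lnc = seqs[row["del_transcript"]][row["lnc_start"] - 1 : row["lnc_end"]]
            mrna = seqs[row["deg_transcript"]][row["mrna_start"] - 1 : row["mrna_end"]]
            assert lnc == core.reverse_complement(mrna)
            assert len(lnc) == cfg.duplex_length

    def test_known_lncrnas_match_reference_at_high_identity(self, small_annotation):
        cfg, (genome, genes, manifest, ref) = small_annotation
        seqs = {t.transcript_id: t.sequence for g in genes for t in g.transcripts}
        classes = manifest.classes.set_index("transcript_id")
        for tid in classes[classes.true_class == "known_lncRNA"].index:
            rseq = ref[f"REF_{tid.replace('.t1', '')}"]
            same = sum(a == b for a, b in zip(seqs[tid], rseq))
            assert same / len(rseq) >= 0.95


class TestCounts:
    def test_poisson_limit_recovers_configured_means(self):
        cfg = SimulationConfig(seed=3, nb_dispersion=1e-6)
        rng = np.random.default_rng(0)
        means = rng.uniform(50, 500, size=(200, 18))
        draws = simulate.draw_nb_counts(np.random.default_rng(9), means, 1e-6)
        se = np.sqrt(means)
        assert (np.abs(draws - means) <= 3 * se + 1).mean() > 0.99

    def test_zero_mean_gives_all_zero_row(self):
        draws = simulate.draw_nb_counts(np.random.default_rng(0), np.zeros((3, 18)), 0.1)
        assert (draws == 0).all()

    def test_planted_fold_change_visible_in_tissue_ratio(self):
        # planted log2FC = 2 in tissue T at base mean >= 100: T/E FPKM mean
        # ratio lands in [2.5, 6.5] for 95% of planted genes
        rng = np.random.default_rng(42)
        n = 400
        base = rng.uniform(100, 1000, n)
        ratios = []
        for b in base:
            mt = simulate.draw_nb_counts(rng, np.full(6, 4 * b), 0.1)
            me = simulate.draw_nb_counts(rng, np.full(6, float(b)), 0.1)
            ratios.append(mt.mean() / max(me.mean(), 1e-9))
        ratios = np.array(ratios)
        assert ((ratios >= 2.5) & (ratios <= 6.5)).mean() >= 0.95

    def test_counts_reproducible_and_trans_pairs_correlated(self, small_annotation):
        cfg, (genome, genes, manifest, ref) = small_annotation
        c1 = simulate.generate_counts(genes, manifest, cfg)
        c2 = simulate.generate_counts(genes, manifest, cfg)
        assert c1.values.equals(c2.values)
        lengths = {g.gene_id: g.transcripts[0].spliced_length for g in genes}
        fpkm = core.compute_fpkm(c1, lengths)
        logf = np.log2(fpkm.values + 1)
        rs = [
            np.corrcoef(logf.loc[row["del_gene"]], logf.loc[row["deg_gene"]])[0, 1]
            for _, row in manifest.trans_pairs.iterrows()
        ]
        assert np.mean(rs) > 0.9


class TestProteins:
    def test_translation_standard_code(self):
        assert translate_orf("ATGAAATAG") == "MK"
        assert translate_orf("ATGGCCGAA") == "MAE"

    def test_proteins_deterministic_and_from_planted_orfs(self, small_annotation):
        cfg, (genome, genes, manifest, ref) = small_annotation
        p1 = simulate.generate_proteins(genes, manifest, cfg)
        p2 = simulate.generate_proteins(genes, manifest, cfg)
        assert p1 == p2
        orfs = manifest.orfs.set_index("gene_id")
        seqs = {t.transcript_id: t.sequence for g in genes for t in g.transcripts}
        gid = list(p1)[0]
        row = orfs.loc[gid]
        cds = seqs[row["transcript_id"]][int(row["orf_start"]) - 1 : int(row["orf_end"])]
        assert p1[gid] == translate_orf(cds)

    def test_partner_without_orf_raises(self, small_annotation):
        cfg, (genome, genes, manifest, ref) = small_annotation
        broken = manifest.protein_pairs.copy()
        broken.loc[0, "deg_gene"] = "NO_SUCH_GENE"
        m2 = simulate.TruthManifest(**{**vars(manifest), "protein_pairs": broken})
        with pytest.raises(ValueError):
            simulate.generate_proteins(genes, m2, cfg)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(nb_dispersion=0.0).validate()
    with pytest.raises(ValueError):
        SimulationConfig(duplex_length=5).validate()
    with pytest.raises(ValueError):
        SimulationConfig(n_novel_lncrnas=3).validate()
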