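import numpy as np
import pandas as pd
import pytest

from lncreg import interactions as ia
from lncreg._tables import RNA_PAIRS, stack_energy
from lncreg.core import GenomicInterval, ValidationError, reverse_complement
from lncreg.interactions import (
    DuplexResult,
    RelationRecord,
    assemble_relations,
    duplex_ndg,
    export_network,
    find_cis,
    find_trans,
    genomic_distance,
    rna_protein_score,
)


class TestGenomicDistance:
    def test_overlap_is_zero(self):
        a = GenomicInterval("c", 100, 500)
        b = GenomicInterval("c", 400, 900)
        assert genomic_distance(a, b) == 0

    def test_gap_counts_bases_between(self):
        a = GenomicInterval("c", 1, 1000)
        b = GenomicInterval("c", 51_001, 52_000)
        assert genomic_distance(a, b) == 50_000
        assert genomic_distance(b, a) == 50_000  # symmetric

    def test_different_chromosomes_undefined(self):
        a = GenomicInterval("c1", 1, 10)
        b = GenomicInterval("c2", 1, 10)
        assert genomic_distance(a, b) is None


def brute_force_cis(dels, degs, max_distance):
    out = set()
    for d, div in dels.items():
        for g, giv in degs.items():
            dist = genomic_distance(div, giv)
            if dist is not None and dist < max_distance:
                out.add((d, g, dist))
    return out


class TestCis:
    def test_equals_all_pairs_oracle_with_boundary_cases(self, rng):
        chroms = ["c1", "c2", "c3"]
        def random_spans(prefix, n):
            out = {}
            for i in range(n):
                start = int(rng.integers(1, 2_000_000))
                out[f"{prefix}{i}"] = GenomicInterval(
                    str(rng.choice(chroms)), start, start + int(rng.integers(100, 5000))
                )
            return out

        dels = random_spans("d", 100)
        degs = random_spans("g", 100)
        # plant an exactly-at-threshold pair (distance == 100000 -> excluded)
        dels["edge"] = GenomicInterval("c1", 1, 1000)
        degs["edge_partner"] = GenomicInterval("c1", 101_001, 102_000)
        assert genomic_distance(dels["edge"], degs["edge_partner"]) == 100_000
        recs = find_cis(dels, degs)
        got = {(r.del_id, r.deg_id, int(r.distance_bp)) for r in recs}
        assert got == brute_force_cis(dels, degs, 100_000)
        assert ("edge", "edge_partner", 100_000) not in got

    def test_just_inside_threshold_kept(self):
        dels = {"d": GenomicInterval("c", 1, 1000)}
        degs = {"g": GenomicInterval("c", 101_000, 102_000)}  # gap 99,999
        assert len(find_cis(dels, degs)) == 1


class TestTrans:
    def _frame(self, rows, ids):
        return pd.DataFrame(rows, index=ids,
                            columns=[f"s{i}" for i in range(len(rows[0]))])

    def test_perfect_correlation_kept_positive(self):
        x = list(range(1, 19))
        recs, _ = find_trans(self._frame([x], ["d"]), self._frame([x], ["g"]))
        assert len(recs) == 1 and recs[0].sign == "positive"
        assert recs[0].r == pytest.approx(1.0) and recs[0].p == 0.0

    def test_anticorrelation_kept_negative(self):
        x = np.arange(18.0)
        recs, _ = find_trans(self._frame([x], ["d"]), self._frame([-x], ["g"]))
        assert len(recs) == 1 and recs[0].sign == "negative"

    def test_hand_computed_r_and_threshold(self):
        x = np.array([1, 2, 3, 4, 5, 6.0])
        y = np.array([1, 2, 3, 4, 5, 7.0])
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r_hand == pytest.approx(0.9897, abs=1e-4)
        recs, _ = find_trans(self._frame([x], ["d"]), self._frame([y], ["g"]))
        assert len(recs) == 1
        assert recs[0].r == pytest.approx(r_hand)
        # p from t-distribution with df = n-2
        from scipy import stats

        t = r_hand * np.sqrt(4) / np.sqrt(1 - r_hand**2)
        assert recs[0].p == pytest.approx(2 * stats.t.sf(t, df=4))

    def test_zero_variance_profile_skipped_with_warning(self):
        x = np.arange(6.0)
        recs, skipped = find_trans(
            self._frame([np.full(6, 3.0)], ["d"]), self._frame([x], ["g"])
        )
        assert not recs and "d" in skipped

    def test_sample_permutation_applied_to_both_preserves_r(self, rng):
        x, y = rng.normal(size=18), rng.normal(size=18)
        perm = rng.permutation(18)
        r1 = np.corrcoef(x, y)[0, 1]
        r2 = np.corrcoef(x[perm], y[perm])[0, 1]
        assert r1 == pytest.approx(r2)


def oracle_duplex_dg(x, y, min_overlap=10):
    """Exhaustive enumeration of every contiguous pairing at every offset."""
    yr = y[::-1]
    a, b = len(x), len(yr)
    best = 0.0
    for s in range(-(a - min_overlap), b - min_overlap + 1):
        lo, hi = max(0, -s), min(a, b - s)
        if hi - lo < min_overlap:
            continue
        i = lo
        while i < hi:
            if (x[i], yr[i + s]) in RNA_PAIRS:
                k = i
                while k < hi and (x[k], yr[k + s]) in RNA_PAIRS:
                    k += 1
                for p in range(i, k):
                    total = 0.0
                    for q in range(p + 1, k):
                        total += stack_energy(
                            (x[q - 1], yr[q - 1 + s]), (x[q], yr[q + s])
                        )
                        best = min(best, total)
                i = k
            else:
                i += 1
    return best


class TestDuplex:
    def test_poly_a_never_pairs(self):
        res = duplex_ndg("A" * 20, "A" * 20)
        assert res == DuplexResult(0.0, 0, 0.0, None, None)

    def test_exact_reverse_complement_is_significant(self, rng):
        x = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
        res = duplex_ndg(x, reverse_complement(x))
        assert res.ndG < -0.1 and res.paired_length == 20
        assert res.dG == pytest.approx(oracle_duplex_dg(x, reverse_complement(x)))

    def test_equals_exhaustive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            x = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(12, 31)))
            y = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(12, 31)))
            assert duplex_ndg(x, y).dG == pytest.approx(
                oracle_duplex_dg(x, y), abs=1e-9
            )

    def test_extension_of_perfect_complement_monotone(self, rng):
        x = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        short = duplex_ndg(x[:20], reverse_complement(x[:20])).dG
        full = duplex_ndg(x, reverse_complement(x)).dG
        assert full <= short

    def test_all_n_sequence_yields_no_duplex(self):
        res = duplex_ndg("N" * 30, "ACGT" * 10)
        assert res.dG == 0.0 and res.ndG == 0.0

    def test_too_short_sequences_rejected(self):
        with pytest.raises(ValidationError):
            duplex_ndg("ACGT", "ACGTACGTACGT")

    def test_symmetric_in_argument_order(self, rng):
        x = "".join("ACGT"[i] for i in rng.integers(0, 4, 25))
        y = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        assert duplex_ndg(x, y).dG == duplex_ndg(y, x).dG


class TestRnaProtein:
    def test_score_bounded_and_deterministic(self, rng):
        rna = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        prot = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 150))
        s1 = rna_protein_score(rna, prot)
        s2 = rna_protein_score(rna, prot)
        assert 0.0 < s1 < 1.0 and s1 == s2

    def test_x_residue_imputed_unknown_rejected(self, rng):
        rna = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        assert 0.0 < rna_protein_score(rna, "MKXXLL" * 20) < 1.0
        with pytest.raises(ValidationError):
            rna_protein_score(rna, "MKB*LL" * 20)

    def test_calibration_holdout_separates_classes(self):
        model = ia.get_rnaprotein_model()
        assert model.holdout_auc >= 0.9
        assert model.holdout_pos_mean > 0.90
        assert model.holdout_neg_mean < 0.5


class TestAssembly:
    def _recs(self):
        return [
            RelationRecord("d1", "g1", "TRANS", "E_vs_T", r=0.95, p=1e-5, sign="positive"),
            RelationRecord("d1", "g1", "RNA_RNA", "E_vs_T", ndg=-0.2),
            RelationRecord("d2", "g2", "CIS", "E_vs_T", distance_bp=500.0),
            RelationRecord("d2", "g2", "CIS", "E_vs_T", distance_bp=500.0),  # dup
        ]

    def test_empty_inputs_give_empty_outputs(self):
        rel, counts, classes, dup = assemble_relations([])
        assert len(rel) == 0 and len(counts) == 0 and len(classes) == 0 and dup == 0

    def test_multi_kind_gene_classified_by_intersection(self):
        rel, counts, classes, dup = assemble_relations(self._recs())
        assert dup == 1
        row = classes.set_index("deg_id").loc["g1"]
        assert row["kinds"] == "TRANS+RNA_RNA" and row["n_kinds"] == 2

    def test_subset_counts_bounded_by_all_counts(self):
        rel, counts, classes, _ = assemble_relations(self._recs(), subset={"g1"})
        for kind in ia.KINDS:
            assert (counts[f"{kind}_subset"] <= counts[f"{kind}_all"]).all()
        assert counts.iloc[0]["CIS_subset"] == 0 and counts.iloc[0]["CIS_all"] == 1


class TestNetworkExport:
    def test_sif_and_graphml_round_trip(self, tmp_path):
        import networkx as nx

        rel, *_ = assemble_relations(self._recs())
        sif, gml = tmp_path / "n.sif", tmp_path / "n.graphml"
        export_network(rel, sif, gml)
        lines = sif.read_text().strip().splitlines()
        assert len(lines) == len(rel)  # n relations -> n edges
        assert lines[0].split("\t")[1] in ia.KINDS
        g = nx.read_graphml(gml)
        assert g.number_of_edges() == len(rel)
        assert set(nx.get_node_attributes(g, "node_type").values()) == {"lncRNA", "gene"}

    _recs = TestAssembly._recs

    def test_empty_relations_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            export_network(pd.DataFrame(), tmp_path / "n.sif", tmp_path / "n.graphml")
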