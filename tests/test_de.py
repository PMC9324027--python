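from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lncreg import core, de, simulate
from lncreg.core import CountMatrix, ExpressionMatrix, ValidationError


def _matrix(arr, feature_ids, tissues):
    samples = pd.DataFrame(
        {"tissue": list(tissues), "replicate": list(range(1, len(tissues) + 1))},
        index=pd.Index([f"s{i}" for i in range(len(tissues))], name="sample_id"),
    )
    values = pd.DataFrame(np.asarray(arr), index=feature_ids, columns=samples.index)
    return CountMatrix(values=values, samples=samples)


class TestPrimaryTest:
    def test_identical_groups_give_null_result(self):
        g = np.tile([100, 120, 90, 110, 105, 95], (5, 1))
        lfc, p = de.de_test_primary(g, g)
        assert np.allclose(lfc, 0.0)
        assert (p >= 0.99).all()

    def test_all_zero_feature_gets_p_one(self):
        z = np.zeros((1, 6))
        lfc, p = de.de_test_primary(z, z)
        assert lfc[0] == 0.0 and p[0] == 1.0

    def test_zero_group_pseudocount_closed_form(self, rng):
        # one feature with group2 all zero, plus stable background features so
        # size factors stay near 1
        back = rng.poisson(200, size=(40, 12)).astype(float)
        g1 = np.vstack([np.full(6, 100.0), back[:, :6]])
        g2 = np.vstack([np.zeros(6), back[:, 6:]])
        lfc, p = de.de_test_primary(g1, g2)
        assert lfc[0] == pytest.approx(np.log2(100.5 / 0.5), abs=0.3)
        assert np.isfinite(lfc).all()

    def test_detects_planted_fourfold_change(self):
        # planted 4-fold change, base mean 200, dispersion 0.05, n=6/6
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(100):
            g1 = simulate.draw_nb_counts(rng, np.full((1, 6), 400.0), 0.05)
            g2 = simulate.draw_nb_counts(rng, np.full((1, 6), 100.0), 0.05)
            back1 = simulate.draw_nb_counts(rng, np.full((30, 6), 300.0), 0.05)
            back2 = simulate.draw_nb_counts(rng, np.full((30, 6), 300.0), 0.05)
            lfc, p = de.de_test_primary(np.vstack([g1, back1]), np.vstack([g2, back2]))
            hits += p[0] < 0.01
        assert hits >= 95

    def test_requires_two_replicates(self):
        with pytest.raises(ValidationError):
            de.de_test_primary(np.ones((1, 1)), np.ones((1, 6)))


class TestSecondaryTest:
    def test_complete_separation_exact_p(self):
        p = de.de_test_secondary([10, 11, 12, 13, 14, 15], [1, 2, 3, 4, 5, 6])
        assert p == pytest.approx(2 / comb(12, 6))

    def test_identical_constant_groups(self):
        assert de.de_test_secondary([5, 5, 5, 5], [5, 5, 5, 5]) == 1.0

    def test_label_permutation_symmetry(self, rng):
        x, y = rng.normal(10, 2, 6), rng.normal(12, 2, 6)
        assert de.de_test_secondary(x, y) == pytest.approx(de.de_test_secondary(y, x))


def bh_oracle(pvals):
    """Step-up BH from the definition: q_(i) = min_{j>=i}(p_(j) * m / j)."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, pvals[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q


class TestBH:
    def test_single_p_unchanged(self):
        assert de.adjust_bh([0.03])[0] == pytest.approx(0.03)

    def test_hand_worked_example(self):
        q = de.adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8))
    def test_matches_definition_oracle(self, pvals):
        assert np.allclose(de.adjust_bh(pvals), bh_oracle(np.array(pvals)))

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=30)
        q = de.adjust_bh(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            de.adjust_bh([0.5, 1.5])


def _three_tissue_matrix(rng, n_genes=60, n_de=20, lfc=3.0, base=500.0):
    tissues = ["T"] * 6 + ["E"] * 6 + ["DD"] * 6
    means = np.full((n_genes, 18), base)
    means[:n_de, 6:12] *= 2.0**lfc  # first n_de genes up in E
    countarr = simulate.draw_nb_counts(rng, means, 0.1)
    cm = _matrix(countarr, [f"g{i}" for i in range(n_genes)], tissues)
    fpkm = core.compute_fpkm(cm, {f: 1000 for f in cm.feature_ids})
    return cm, fpkm


class TestCallDe:
    def test_conjunction_rule_requires_both_methods(self, rng):
        cm, fpkm = _three_tissue_matrix(rng)
        res = de.call_de(cm, fpkm)
        hit = res[res["is_de"]]
        assert set(hit["comparison"]) <= {"E_vs_T", "E_vs_DD"}
        assert (hit["q_primary"] < 0.01).all() and (hit["q_secondary"] < 0.01).all()
        assert (hit["log2fc"].abs() > 1).all()
        # a feature confirmed by only one method is never DE
        one_sided = res[(res["q_primary"] < 0.01) & (res["q_secondary"] >= 0.01)]
        assert not one_sided["is_de"].any()

    def test_de_calls_invariant_to_sample_order(self, rng):
        cm, fpkm = _three_tissue_matrix(rng, n_genes=40, n_de=15)
        perm = list(rng.permutation(list(cm.values.columns)))
        cm2 = CountMatrix(values=cm.values[perm], samples=cm.samples.loc[perm])
        fpkm2 = ExpressionMatrix(values=fpkm.values[perm], samples=fpkm.samples.loc[perm])
        r1 = de.call_de(cm, fpkm).set_index(["feature_id", "comparison"])
        r2 = de.call_de(cm2, fpkm2).set_index(["feature_id", "comparison"])
        assert (r1["is_de"] == r2["is_de"]).all()
        assert np.allclose(r1["log2fc"], r2["log2fc"])

    def test_missing_tissue_is_an_error(self, rng):
        arr = rng.poisson(100, size=(5, 12))
        cm = _matrix(arr, [f"g{i}" for i in range(5)], ["T"] * 6 + ["E"] * 6)
        fpkm = core.compute_fpkm(cm, {f: 1000 for f in cm.feature_ids})
        with pytest.raises(Exception):
            de.call_de(cm, fpkm)


class TestGroups:
    def _results(self, rows):
        base = {
            "log2fc": 0.0, "p_primary": 1.0, "p_secondary": 1.0,
            "q_primary": 1.0, "q_secondary": 1.0, "confirmed_both": False,
            "direction": "up", "is_de": False,
        }
        return pd.DataFrame([{**base, **r} for r in rows])

    def test_up_in_e_against_both_joins_e_group(self):
        res = self._results([
            {"feature_id": "f", "comparison": "E_vs_T", "log2fc": 2.0, "is_de": True},
            {"feature_id": "f", "comparison": "E_vs_DD", "log2fc": 1.8, "is_de": True},
        ])
        assert de.group_profiles(res)["E_vs_rest"] == ["f"]

    def test_single_comparison_is_not_grouped(self):
        res = self._results([
            {"feature_id": "f", "comparison": "E_vs_T", "log2fc": 2.0, "is_de": True},
        ])
        groups = de.group_profiles(res)
        assert all(not v for v in groups.values())

    def test_sign_inconsistency_excludes(self):
        res = self._results([
            {"feature_id": "f", "comparison": "E_vs_T", "log2fc": 2.0, "is_de": True},
            {"feature_id": "f", "comparison": "E_vs_DD", "log2fc": -2.0, "is_de": True,
             "direction": "down"},
        ])
        groups = de.group_profiles(res)
        assert all(not v for v in groups.values())

    def test_t_group_via_consistent_downregulation(self):
        res = self._results([
            {"feature_id": "f", "comparison": "E_vs_T", "log2fc": 2.0, "is_de": True},
            {"feature_id": "f", "comparison": "DD_vs_T", "log2fc": 2.5, "is_de": True},
        ])
        assert de.group_profiles(res)["T_vs_rest"] == ["f"]

    def test_feature_lands_in_exactly_one_group(self):
        # separates all three tissues: qualifies for E and T; assigned to
        # the group with larger mean |log2FC|
        res = self._results([
            {"feature_id": "f", "comparison": "E_vs_T", "log2fc": 4.0, "is_de": True},
            {"feature_id": "f", "comparison": "E_vs_DD", "log2fc": 1.5, "is_de": True},
            {"feature_id": "f", "comparison": "DD_vs_T", "log2fc": 2.5, "is_de": True},
        ])
        groups = de.group_profiles(res)
        assert sum(len(v) for v in groups.values()) == 1
        assert groups["T_vs_rest"] == ["f"]  # mean(4, 2.5) > mean(4, 1.5)


class TestZscore:
    def _fpkm(self, arr, ids):
        cm = _matrix(np.asarray(arr), ids, ["T", "T", "E"])
        return ExpressionMatrix(values=cm.values.astype(float), samples=cm.samples)

    def test_constant_row_gives_zeros(self):
        z = de.zscore_matrix(self._fpkm([[5, 5, 5]], ["a"]))
        assert (z.to_numpy() == 0).all()

    def test_simple_row(self):
        z = de.zscore_matrix(self._fpkm([[1, 2, 3]], ["a"]))
        assert np.allclose(z.to_numpy()[0], [-1, 0, 1])

    def test_rows_standardized(self, rng):
        arr = rng.uniform(1, 100, size=(10, 3))
        z = de.zscore_matrix(self._fpkm(arr, [f"f{i}" for i in range(10)]))
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1)
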