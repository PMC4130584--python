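"""Differential-expression filter and direction clustering."""

import numpy as np
import pandas as pd
import pytest

import layerome as L
from layerome.expression import cluster_directions, select_de_genes, student_t_test

from conftest import make_dataset


class TestStudentT:
    def test_identical_groups_give_t0_p1(self):
        ds = make_dataset({"g": [1, 2, 3, 1, 2, 3]}, 3, 3)
        t, p = student_t_test(ds, "g")
        assert t == 0.0 and p == 1.0

    def test_closed_form_worked_example(self):
        # pooled-variance t on (1,2,3) vs (3,4,5): t = -2/sqrt(2/3), df = 4
        ds = make_dataset({"g": [1, 2, 3, 3, 4, 5]}, 3, 3)
        t, p = student_t_test(ds, "g")
        assert t == pytest.approx(-2.449, abs=1e-3)
        assert p == pytest.approx(0.0705, abs=5e-4)

    def test_zero_variance_unequal_means_gives_p0(self):
        ds = make_dataset({"g": [2, 2, 5, 5]}, 2, 2)
        t, p = student_t_test(ds, "g")
        assert p == 0.0 and np.isinf(t) and t < 0

    def test_missing_gene_rejected(self):
        ds = make_dataset({"g": [1, 2, 3, 4]}, 2, 2)
        with pytest.raises(KeyError):
            student_t_test(ds, "absent")


class TestSelect:
    def test_null_count_matches_binomial_oracle(self):
        # 1000 independent null genes at alpha=0.05: Binomial(1000, 0.05),
        # so the count should fall within 50 +/- 3*sqrt(1000*0.05*0.95).
        bundle = L.simulate_dataset(L.SyntheticConfig(
            n_genes=1000, de_fraction=0.0, planted_terms=(), rng_seed=5))
        res = select_de_genes(bundle.dataset, alpha=0.05)
        assert 50 - 21 <= res.counts()["total_de"] <= 50 + 21

    def test_alpha_near_one_flags_everything(self):
        bundle = L.simulate_dataset(L.SyntheticConfig(
            n_genes=50, de_fraction=0.0, planted_terms=(), rng_seed=2))
        res = select_de_genes(bundle.dataset, alpha=0.999999)
        assert res.counts()["total_de"] == 50

    def test_planted_gene_power(self):
        # effect 3 sigma with 6/group: per-gene two-sample t power > 0.99,
        # so planted genes should pass in >= 95% of seeded replicates.
        hits = total = 0
        for seed in range(200):
            b = L.simulate_dataset(L.SyntheticConfig(
                n_genes=40, de_fraction=0.25, effect_size=3.0, n_per_group=6,
                planted_terms=(), rng_seed=seed))
            res = select_de_genes(b.dataset, 0.05)
            flagged = set(res.de_genes)
            total += len(b.truth.de_genes)
            hits += sum(1 for g in b.truth.de_genes if g in flagged)
        assert hits / total >= 0.95

    def test_alpha_out_of_range_rejected(self):
        ds = make_dataset({"g": [1, 2, 3, 4]}, 2, 2)
        with pytest.raises(ValueError):
            select_de_genes(ds, alpha=0.0)


class TestClusterDirections:
    def _noiseless(self):
        # two anti-correlated planted profile families, no noise
        vals = {}
        for i in range(5):
            vals[f"up{i}"] = [8 + i, 8 + i, 8 + i, 4 + i, 4 + i, 4 + i]
            vals[f"dn{i}"] = [4 + i, 4 + i, 4 + i, 8 + i, 8 + i, 8 + i]
        return make_dataset(vals, 3, 3)

    def test_noiseless_families_fully_recovered(self):
        ds = self._noiseless()
        res = cluster_directions(ds, select_de_genes(ds, 0.05))
        d = res.direction_map
        assert all(d[f"up{i}"] == "up" for i in range(5))
        assert all(d[f"dn{i}"] == "down" for i in range(5))

    def test_partition_of_de_set(self, default_bundle):
        ds = default_bundle.dataset
        res = cluster_directions(ds, select_de_genes(ds, 0.05))
        de = set(res.de_genes)
        labeled = set(res.genes_with_direction("up", "down", "unclustered"))
        assert labeled == de
        assert set(res.genes_with_direction("not_de")).isdisjoint(de)

    def test_agreement_with_mean_diff_on_noiseless_data(self):
        ds = self._noiseless()
        res = cluster_directions(ds, select_de_genes(ds, 0.05))
        for g in res.de_genes:
            expected = "up" if res.table.loc[g, "mean_diff"] > 0 else "down"
            assert res.table.loc[g, "direction"] == expected

    def test_label_swap_symmetry(self, rng):
        vals = {f"g{i}": list(rng.normal(8, 1, 8) + (3 if i < 6 else 0) * np.r_[np.ones(4), np.zeros(4)] * (1 if i % 2 else -1))
                for i in range(12)}
        ds = make_dataset(vals, 4, 4)
        swapped = L.ExpressionDataset(
            values=ds.values.copy(),
            condition=ds.condition.map({"groupA": "groupB", "groupB": "groupA"}),
            group_a="groupA",
        )
        r1 = cluster_directions(ds, select_de_genes(ds, 0.05))
        r2 = cluster_directions(swapped, select_de_genes(swapped, 0.05))
        assert np.allclose(r1.table["p_value"], r2.table["p_value"])
        assert np.allclose(r1.table["mean_diff"], -r2.table["mean_diff"])
        flip = {"up": "down", "down": "up", "unclustered": "unclustered", "not_de": "not_de"}
        assert list(r2.table["direction"]) == [flip[d] for d in r1.table["direction"]]

    def test_floor_rule_drops_low_correlation_genes(self):
        # correlation at or below the floor means unclustered; at floor 1.0
        # (corr <= 1 always) every DE gene must fall out of both clusters
        ds = self._noiseless()
        res = cluster_directions(ds, select_de_genes(ds, 0.05), corr_floor=1.0)
        assert set(res.genes_with_direction("unclustered")) == set(res.de_genes)

    def test_single_de_gene_uses_sign_of_mean_diff(self):
        vals = {"g1": [9, 9, 9, 3, 3, 3], "g2": [5.0, 5.1, 4.9, 5.05, 4.95, 5.0]}
        ds = make_dataset(vals, 3, 3)
        res = cluster_directions(ds, select_de_genes(ds, 0.05))
        assert res.table.loc["g1", "direction"] == "up"
        assert res.table.loc["g2", "direction"] == "not_de"


def test_dataset_invariants_enforced():
    with pytest.raises(ValueError, match="2 samples"):
        make_dataset({"g": [1, 2, 3]}, 1, 2)
    samples = ["A0", "A1", "B0", "B1"]
    frame = pd.DataFrame([[1, 2, 3, 4]], index=["g"], columns=samples)
    cond = pd.Series(["x", "y", "z", "x"], index=samples)
    with pytest.raises(ValueError, match="2 levels"):
        L.ExpressionDataset(values=frame, condition=cond)
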