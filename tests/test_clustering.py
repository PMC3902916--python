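"""Consensus k-means with Spearman distance, J elbow, core assignment."""

import numpy as np
import pandas as pd
import pytest

from sigmakin.clustering import (
    ClusterCore,
    ClusteringConfig,
    ClusterRun,
    assign_to_cores,
    consensus_cores,
    consensus_cluster,
    jackknife_scan,
    kmeans_spearman,
    select_n,
    spearman_distance,
    within_cluster_J,
)
from sigmakin.errors import ConstantProfileError
from sigmakin.synthetic import make_kinetic_groups


@pytest.fixture(scope="module")
def planted_small():
    # two obvious shape groups, 5 profiles each
    rng = np.random.default_rng(4)
    t = np.arange(13, dtype=float)
    rising = [t * (1 + 0.01 * i) + rng.normal(0, 0.01, 13) for i in range(5)]
    falling = [-t * (1 + 0.01 * i) + 20 + rng.normal(0, 0.01, 13) for i in range(5)]
    vals = pd.DataFrame(rising + falling, index=[f"g{i}" for i in range(10)])
    labels = ["up"] * 5 + ["down"] * 5
    return vals, labels


class TestSpearmanDistance:
    def test_identical_profiles_zero(self):
        p = np.array([1.0, 3, 2, 5, 4])
        assert spearman_distance(p, p) == pytest.approx(0.0)

    def test_monotone_transform_invariance(self):
        p = np.array([0.5, 1.2, 0.1, 3.0, 2.2])
        assert spearman_distance(p, np.exp(p)) == pytest.approx(0.0)

    def test_reversed_ranks_distance_two(self):
        p = np.array([1.0, 2, 3, 4, 5])
        assert spearman_distance(p, p[::-1]) == pytest.approx(2.0)

    def test_constant_profile_rejected(self):
        with pytest.raises(ConstantProfileError):
            spearman_distance(np.ones(5), np.arange(5.0))


class TestKmeans:
    def test_recovers_two_planted_groups(self, planted_small):
        vals, labels = planted_small
        run = kmeans_spearman(vals.to_numpy(), 2, seed=0)
        parts = {lab: set(run.labels[np.array(labels) == lab]) for lab in ("up", "down")}
        assert len(parts["up"]) == 1 and len(parts["down"]) == 1
        assert parts["up"] != parts["down"]

    def test_deterministic_for_seed(self, planted_small):
        vals, _ = planted_small
        a = kmeans_spearman(vals.to_numpy(), 2, seed=42)
        b = kmeans_spearman(vals.to_numpy(), 2, seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.J == b.J

    def test_n_equals_profiles_gives_zero_J(self, planted_small):
        vals, _ = planted_small
        run = kmeans_spearman(vals.to_numpy(), len(vals), seed=1)
        assert run.J == pytest.approx(0.0, abs=1e-9)

    def test_within_cluster_J_is_distance_sum(self, planted_small):
        vals, _ = planted_small
        run = kmeans_spearman(vals.to_numpy(), 2, seed=3)
        total = sum(
            spearman_distance(vals.to_numpy()[i], run.centroids[run.labels[i]])
            for i in range(len(vals))
        )
        assert within_cluster_J(run, vals.to_numpy()) == pytest.approx(total, abs=1e-9)


class TestConsensus:
    def test_identical_runs_reproduce_clusters(self, planted_small):
        vals, labels = planted_small
        base = kmeans_spearman(vals.to_numpy(), 2, seed=0)
        runs = [ClusterRun(i, base.labels.copy(), base.centroids.copy(), base.J) for i in range(10)]
        cores = consensus_cores(runs, vals.to_numpy(), list(vals.index))
        sizes = sorted(len(c.member_gene_ids) for c in cores)
        assert sizes == [5, 5]

    def test_label_permutation_invariance(self, planted_small):
        vals, _ = planted_small
        base = kmeans_spearman(vals.to_numpy(), 2, seed=0)
        flipped = ClusterRun(1, 1 - base.labels, base.centroids[::-1].copy(), base.J)
        runs = [base, flipped, base]
        cores = consensus_cores(runs, vals.to_numpy(), list(vals.index))
        assert sorted(len(c.member_gene_ids) for c in cores) == [5, 5]

    def test_stable_dissenter_joins_other_core(self, planted_small):
        # a gene landing in the *same* other cluster in 6 of 10 runs crosses
        # the 50% bar there and becomes a member of that core
        vals, _ = planted_small
        base = kmeans_spearman(vals.to_numpy(), 2, seed=0)
        runs = []
        for i in range(10):
            labels = base.labels.copy()
            if i < 6:
                labels[0] = 1 - labels[0]
            runs.append(ClusterRun(i, labels, base.centroids.copy(), base.J + 0.01 * i))
        cores = consensus_cores(runs, vals.to_numpy(), list(vals.index))
        members = {g for c in cores for g in c.member_gene_ids}
        assert "g0" in members
        home = next(c for c in cores if "g0" in c.member_gene_ids)
        assert len(home.member_gene_ids) == 6  # g0 plus the other group's 5

    def test_scattered_dissenter_excluded_from_all_cores(self):
        # with three clusters and the gene's assignment scattered 4/3/3
        # across runs, no cluster reaches the 50% consensus bar
        vals, _ = make_kinetic_groups(3, 4, seed=6)
        base = kmeans_spearman(vals.to_numpy(), 3, seed=0)
        runs = []
        for i in range(10):
            labels = base.labels.copy()
            labels[0] = (labels[0] + i) % 3
            runs.append(ClusterRun(i, labels, base.centroids.copy(), base.J + 0.001 * i))
        cores = consensus_cores(runs, vals.to_numpy(), list(vals.index))
        members = {g for c in cores for g in c.member_gene_ids}
        assert vals.index[0] not in members and len(members) == 11

    def test_core_shrinks_as_fraction_rises(self, planted_small):
        vals, _ = planted_small
        rng = np.random.default_rng(0)
        runs = []
        base = kmeans_spearman(vals.to_numpy(), 2, seed=0)
        for i in range(20):
            labels = base.labels.copy()
            flip = rng.random(10) < 0.2
            labels[flip] = 1 - labels[flip]
            runs.append(ClusterRun(i, labels, base.centroids.copy(), base.J))
        small = {g for c in consensus_cores(runs, vals.to_numpy(), list(vals.index), 0.9) for g in c.member_gene_ids}
        big = {g for c in consensus_cores(runs, vals.to_numpy(), list(vals.index), 0.5) for g in c.member_gene_ids}
        assert small <= big


class TestElbow:
    def test_sharp_change_selected(self):
        curve = pd.DataFrame({"n": [2, 3, 4, 5], "J_mean": [10.0, 6.0, 5.8, 5.7]})
        assert select_n(curve, default_n=42) == 3

    def test_linear_curve_falls_back_to_default(self):
        curve = pd.DataFrame({"n": range(2, 10), "J_mean": np.linspace(10, 3, 8)})
        with pytest.warns(UserWarning):
            assert select_n(curve, default_n=42) == 42

    def test_single_drop_then_flat(self):
        curve = pd.DataFrame({"n": [2, 3, 4, 5, 6], "J_mean": [9.0, 8.8, 2.0, 1.9, 1.85]})
        assert select_n(curve, default_n=42) == 4

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError):
            select_n(pd.DataFrame({"n": [2, 3, 4], "J_mean": [3.0, 2, 1]}))


class TestAssignment:
    def _cores(self):
        up = ClusterCore(0, ["m1"], np.arange(13, dtype=float))
        down = ClusterCore(1, ["m2"], np.arange(13, dtype=float)[::-1].copy())
        return [up, down]

    def test_assigned_to_best_core_above_threshold(self, rng):
        vals = pd.DataFrame(
            {
                "gA": np.arange(13, dtype=float) + rng.normal(0, 0.1, 13),
                "gB": -np.arange(13, dtype=float) + rng.normal(0, 0.1, 13),
                "gC": rng.normal(0, 1, 13),  # matches neither
            }
        ).T
        cores = assign_to_cores(vals, self._cores(), assign_r_min=0.8)
        assert "gA" in cores[0].assigned and cores[0].assigned["gA"] > 0.99
        assert "gB" in cores[1].assigned
        assert "gC" not in cores[0].assigned and "gC" not in cores[1].assigned

    def test_identical_to_core_r_one(self):
        vals = pd.DataFrame({"g": np.arange(13, dtype=float)}).T
        cores = assign_to_cores(vals, self._cores(), 0.8)
        assert cores[0].assigned["g"] == pytest.approx(1.0)

    def test_below_threshold_unassigned(self):
        prof = np.arange(13, dtype=float)
        prof[::2] += 8.0  # heavily perturbed rising trend, r < 0.8
        vals = pd.DataFrame({"g": prof}).T
        cores = assign_to_cores(vals, self._cores(), 0.95)
        assert not cores[0].assigned and not cores[1].assigned

    def test_gappy_profile_assigned_on_present_points(self):
        prof = np.arange(13, dtype=float)
        prof[0] = np.nan
        vals = pd.DataFrame({"g": prof}).T
        cores = assign_to_cores(vals, self._cores(), 0.8)
        assert "g" in cores[0].assigned

    def test_too_gappy_profile_unassigned(self):
        prof = np.full(13, np.nan)
        prof[:5] = np.arange(5, dtype=float)
        vals = pd.DataFrame({"g": prof}).T
        cores = assign_to_cores(vals, self._cores(), 0.8, min_points=8)
        assert not cores[0].assigned and not cores[1].assigned


class TestPlantedRecovery:
    def test_six_group_consensus_perfect_and_self_consistent(self):
        from sklearn.metrics import adjusted_rand_score

        vals, labels = make_kinetic_groups(6, 30, seed=11)
        cores = consensus_cluster(vals, ClusteringConfig(n_clusters=6, n_runs=50, rng_seed=2))
        pred = {g: c.core_id for c in cores for g in c.member_gene_ids}
        common = [g for g in vals.index if g in pred]
        ari = adjusted_rand_score([labels[g] for g in common], [pred[g] for g in common])
        assert ari >= 0.99
        # every core member correlates positively with its own core profile
        attached = assign_to_cores(vals, cores, assign_r_min=0.0)
        for c in attached:
            for g in c.member_gene_ids:
                assert c.assigned.get(g, c.assigned.get(g, 1.0)) > 0

    def test_jackknife_zero_fraction_degenerates_to_plain_runs(self):
        vals, _ = make_kinetic_groups(3, 15, seed=7)
        cfg = ClusteringConfig(n_clusters=3, jackknife_fraction=0.0, rng_seed=1)
        curve = jackknife_scan(vals, cfg, n_values=[2, 3, 4, 5], repeats=5)
        assert len(curve) == 4
        assert (curve["J_sd"] >= 0).all()
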