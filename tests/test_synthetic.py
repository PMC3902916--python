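"""Ground-truthed data generation: determinism, noise calibration, fixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from sigmakin.grid import default_grid
from sigmakin.kinetics import FitConfig, anneal_fit
from sigmakin.preprocess import average_replicates, normalize_arrays
from sigmakin.synthetic import (
    SyntheticSpec,
    add_replicate_noise,
    make_dataset,
    make_kinetic_groups,
    make_regulator_profiles,
    make_targets,
    plant_annotations,
    write_fixture,
)

SMALL = SyntheticSpec(
    n_regulators=3, targets_per_regulator=5, n_decoys=30, n_background=10, rng_seed=21
)


@pytest.fixture(scope="module")
def small_dataset():
    return make_dataset(SMALL)


class TestRegulators:
    def test_shape_contract(self, grid, rng):
        profs = make_regulator_profiles(SMALL, grid, rng)
        assert profs.shape == (3, len(grid))
        assert (profs.to_numpy() > 0).all()

    def test_pairwise_spearman_bound(self, grid, rng):
        profs = make_regulator_profiles(SyntheticSpec(n_regulators=5, rng_seed=2), grid, rng).to_numpy()
        for i in range(5):
            for j in range(i + 1, 5):
                assert spearmanr(profs[i], profs[j]).statistic < 0.7

    def test_deterministic(self, grid):
        a = make_regulator_profiles(SMALL, grid, np.random.default_rng(1))
        b = make_regulator_profiles(SMALL, grid, np.random.default_rng(1))
        pd.testing.assert_frame_equal(a, b)


class TestTargets:
    def test_ground_truth_bookkeeping(self, grid, rng):
        regs = make_regulator_profiles(SMALL, grid, rng)
        targets, truth = make_targets(SMALL, regs, grid, rng)
        assert len(truth.edges) == 3 * 5
        assert len(targets) == 3 * 5 + 30 + 10
        assert set(truth.edges["regulator"]) <= set(regs.index)

    def test_noise_free_target_refit_recovers(self, grid, rng):
        regs = make_regulator_profiles(SMALL, grid, rng)
        targets, truth = make_targets(SMALL, regs, grid, rng)
        row = truth.edges.iloc[0]
        fit = anneal_fit(
            targets.loc[row.target].to_numpy(),
            regs.loc[row.regulator].to_numpy(),
            grid,
            FitConfig(seed=3),
        )
        assert fit.c >= 0.99

    def test_profiles_positive(self, grid, rng):
        regs = make_regulator_profiles(SMALL, grid, rng)
        targets, _ = make_targets(SMALL, regs, grid, rng)
        assert (targets.to_numpy() > 0).all()


class TestReplicateNoise:
    def test_zero_noise_zero_outliers_reproduce_truth(self, grid, rng):
        spec = SyntheticSpec(
            n_regulators=2, targets_per_regulator=3, n_decoys=10, n_background=0,
            noise_cv=0.0, outlier_rate=0.0, signal_floor=0.0, rng_seed=3,
        )
        regs = make_regulator_profiles(spec, grid, rng)
        targets, _ = make_targets(spec, regs, grid, rng)
        profiles = pd.concat([regs, targets])
        raw, meta = add_replicate_noise(profiles, spec, grid, rng)
        # every replicate ratio equals truth/reference exactly
        ref = profiles.mean(axis=1).to_numpy()
        for lab in grid.labels:
            for aid in meta.arrays_for(lab):
                v = (2.0 ** raw.log2ratio[aid].to_numpy()) * ref
                np.testing.assert_allclose(v, profiles[lab].to_numpy(), rtol=1e-12)

    def test_log2ratio_consistency_identity(self, small_dataset):
        ds = small_dataset
        floored = ds.true_profiles.to_numpy()
        floor = 0.2 * floored.mean(axis=1, keepdims=True)
        ref = (floored + floor).mean(axis=1)
        # 2^log2ratio * reference is a valid positive abundance everywhere
        v = (2.0 ** ds.raw.log2ratio.to_numpy()) * ref[:, None]
        assert (v > 0).all()

    def test_replicate_cv_matches_requested(self, grid, rng):
        # 10 replicates per point keep the sample-sd small-n bias (c4) under 3%
        for cv in (0.05, 0.2, 0.5):
            spec = SyntheticSpec(
                n_regulators=2, targets_per_regulator=3, n_decoys=120, n_background=0,
                noise_cv=cv, outlier_rate=0.0, replicates_per_point=10, rng_seed=4,
            )
            regs = make_regulator_profiles(spec, grid, rng)
            targets, _ = make_targets(spec, regs, grid, rng)
            profiles = pd.concat([regs, targets])
            raw, meta = add_replicate_noise(profiles, spec, grid, rng)
            ratios = 2.0 ** raw.log2ratio
            cvs = []
            for lab in grid.labels:
                block = ratios[meta.arrays_for(lab)].to_numpy()
                cvs.append(np.std(block, axis=1, ddof=1) / block.mean(axis=1))
            mean_cv = float(np.nanmean(cvs))
            assert abs(mean_cv - cv) / cv < 0.10

    def test_outlier_injection_rate_within_binomial_bounds(self, grid, rng):
        spec = SyntheticSpec(
            n_regulators=2, targets_per_regulator=3, n_decoys=250, n_background=0,
            noise_cv=0.0, outlier_rate=0.01, outlier_fold=10.0, signal_floor=0.0, rng_seed=6,
        )
        regs = make_regulator_profiles(spec, grid, rng)
        targets, _ = make_targets(spec, regs, grid, rng)
        profiles = pd.concat([regs, targets])
        raw, meta = add_replicate_noise(profiles, spec, grid, rng)
        ref = profiles.mean(axis=1).to_numpy()
        n_out = 0
        n_tot = 0
        for lab in grid.labels:
            truth_col = profiles[lab].to_numpy()
            for aid in meta.arrays_for(lab):
                v = (2.0 ** raw.log2ratio[aid].to_numpy()) * ref
                n_out += int((v / truth_col > 5.0).sum())
                n_tot += v.size
        # 99% binomial interval around rate 0.01
        expect = 0.01 * n_tot
        sd = np.sqrt(n_tot * 0.01 * 0.99)
        assert expect - 2.58 * sd <= n_out <= expect + 2.58 * sd


class TestAnnotations:
    def test_every_gene_one_class(self, small_dataset):
        ann = small_dataset.annotation
        assert ann["gene"].is_unique
        assert set(ann["gene"]) == set(small_dataset.true_profiles.index)

    def test_factor_one_plants_nothing(self, grid, rng):
        labels = pd.Series({"a": "G1", "b": "G1", "c": "G2"})
        spec = SyntheticSpec(planted_enrichment_factor=1.0, rng_seed=5)
        ann, enriched = plant_annotations(labels, ["a", "b", "c", "d"], spec, rng)
        assert enriched.empty and len(ann) == 4

    def test_planted_class_oversampled(self, grid, rng):
        genes = [f"g{i}" for i in range(400)]
        labels = pd.Series({g: "G1" for g in genes[:200]})
        spec = SyntheticSpec(planted_enrichment_factor=5.0, n_classes=10, rng_seed=5)
        ann, enriched = plant_annotations(labels, genes, spec, rng)
        planted_class = enriched.iloc[0]["class"]
        in_group = ann[ann["gene"].isin(genes[:200])]
        frac = (in_group["class"] == planted_class).mean()
        assert 0.4 < frac < 0.6  # ~5 x 10% base rate

    def test_spec_example_expectation(self, grid, rng):
        # factor 5 at 4% base frequency in a 60-gene cluster: E[k] ~ 12
        genes = [f"g{i}" for i in range(2000)]
        labels = pd.Series({g: "G1" for g in genes[:60]})
        spec = SyntheticSpec(planted_enrichment_factor=5.0, n_classes=25, rng_seed=5)
        ann, enriched = plant_annotations(labels, genes, spec, rng)
        planted_class = enriched.iloc[0]["class"]
        k = (ann[ann["gene"].isin(genes[:60])]["class"] == planted_class).sum()
        assert 6 <= k <= 19  # binomial(60, 0.2) within ~3.3 sd


class TestKineticGroups:
    def test_within_group_rank_coherence(self):
        vals, labels = make_kinetic_groups(6, 20, seed=1)
        x = vals.to_numpy()
        for grp in labels.unique():
            idx = np.flatnonzero(labels.to_numpy() == grp)
            first = x[idx[0]]
            for j in idx[1:]:
                assert spearmanr(first, x[j]).statistic >= 0.9

    def test_shapes_and_labels(self):
        vals, labels = make_kinetic_groups(4, 7, seed=2)
        assert vals.shape == (28, 13)
        assert labels.value_counts().tolist() == [7, 7, 7, 7]


class TestFixtureIO:
    def test_write_read_round_trip_bit_exact(self, small_dataset, tmp_path):
        paths = write_fixture(small_dataset, tmp_path)
        back = pd.read_csv(paths["log2ratio.tsv"], sep="\t", index_col=0)
        pd.testing.assert_frame_equal(back, small_dataset.raw.log2ratio, check_names=False)
        truth_back = pd.read_csv(paths["truth_edges.tsv"], sep="\t")
        pd.testing.assert_frame_equal(truth_back, small_dataset.truth.edges)

    def test_priors_subset_of_true_edges(self, small_dataset):
        true_pairs = set(zip(small_dataset.truth.edges.regulator, small_dataset.truth.edges.target))
        prior_pairs = set(zip(small_dataset.priors.regulator, small_dataset.priors.target))
        assert prior_pairs <= true_pairs

    def test_fixture_files_sufficient_for_pipeline_input(self, small_dataset, tmp_path):
        paths = write_fixture(small_dataset, tmp_path)
        expected = {
            "log2ratio.tsv", "sample_signal.tsv", "arrays.tsv", "annotation.tsv",
            "priors.tsv", "sigma_factors.txt", "time_grid.tsv",
        }
        assert expected <= set(paths)

    def test_full_determinism_byte_identical(self, tmp_path):
        a = make_dataset(SMALL)
        b = make_dataset(SMALL)
        pd.testing.assert_frame_equal(a.raw.log2ratio, b.raw.log2ratio)
        pd.testing.assert_frame_equal(a.annotation, b.annotation)
        pa = write_fixture(a, tmp_path / "a")
        pb = write_fixture(b, tmp_path / "b")
        for name in pa:
            assert pa[name].read_bytes() == pb[name].read_bytes()


class TestPipelineCompatibility:
    def test_raw_table_feeds_preprocessing(self, small_dataset):
        ratios = normalize_arrays(small_dataset.raw)
        profs = average_replicates(ratios, small_dataset.meta, small_dataset.grid)
        assert len(profs.gene_ids) == len(small_dataset.true_profiles)
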