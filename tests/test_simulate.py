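import numpy as np
import pandas as pd
import pytest

from nmanova import (
    DistributionSpec,
    InputError,
    Partition,
    SamplingOptions,
    ScenarioConfig,
    convergence_curve,
    generate_block_matrix,
    grid_experiment,
    null_calibration,
    partition_search,
    sensitivity_sweep,
)
from nmanova.simulate import _affected_pairs


class TestScenarioConfig:
    def test_from_dict_with_spec_lists(self):
        cfg = ScenarioConfig.from_dict(
            {
                "kind": "null-calibration",
                "group_sizes": [10, 10, 10],
                "within": ["normal", 0, 1],
                "between": {"family": "normal", "params": [0, 1]},
                "n_replicates": 5,
                "seed": 1,
            }
        )
        assert cfg.within == DistributionSpec("normal", 0, 1)
        assert cfg.within == cfg.between

    def test_unknown_kind_rejected(self):
        with pytest.raises(InputError, match="kind"):
            ScenarioConfig(kind="bogus")

    def test_unknown_field_rejected(self):
        with pytest.raises(InputError, match="unknown scenario"):
            ScenarioConfig.from_dict({"kind": "grid", "whatever": 1})

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "kind: convergence\ngroup_sizes: [5, 5]\nn_samplings: 10\nseed: 3\n"
        )
        cfg = ScenarioConfig.from_file(path)
        assert cfg.kind == "convergence"
        assert cfg.group_sizes == (5, 5)


class TestGenerateBlockMatrix:
    def test_block_supports(self):
        m, p = generate_block_matrix(
            (10, 20, 30),
            DistributionSpec("uniform", 0, 1),
            DistributionSpec("uniform", 2, 4),
            rng=0,
        )
        assert m.n == 60
        assert p.sizes.tolist() == [10, 20, 30]
        lo = 0
        within_mask = np.zeros((60, 60), dtype=bool)
        for s in (10, 20, 30):
            within_mask[lo:lo + s, lo:lo + s] = True
            lo += s
        assert m.values[within_mask].max() <= 1.0
        assert m.values[~within_mask].min() >= 2.0

    def test_near_constant_degenerate_fixture(self):
        spec = DistributionSpec("uniform", 5.0, 5.0 + 1e-12)
        m, p = generate_block_matrix((1, 1), spec, spec, rng=0)
        assert np.allclose(m.values, 5.0)
        assert p.g == 2

    def test_seed_determinism(self):
        a, _ = generate_block_matrix(
            (3, 4), DistributionSpec("normal", 0, 1),
            DistributionSpec("normal", 1, 1), rng=42,
        )
        b, _ = generate_block_matrix(
            (3, 4), DistributionSpec("normal", 0, 1),
            DistributionSpec("normal", 1, 1), rng=42,
        )
        np.testing.assert_array_equal(a.values, b.values)

    def test_per_pair_between_specs(self):
        between = {
            (0, 1): DistributionSpec("uniform", 10, 11),
            "default": DistributionSpec("uniform", 0, 1),
        }
        m, _ = generate_block_matrix(
            (2, 2, 2), DistributionSpec("uniform", 0, 1), between, rng=1
        )
        assert m.values[0:2, 2:4].min() >= 10
        assert m.values[2:4, 0:2].max() <= 1

    def test_rejects_empty_group(self):
        with pytest.raises(InputError, match="sizes"):
            generate_block_matrix(
                (0, 3), DistributionSpec("normal", 0, 1),
                DistributionSpec("normal", 0, 1), rng=0,
            )


@pytest.fixture(scope="module")
def mean_sweep():
    cfg = ScenarioConfig(
        kind="sensitivity-mean", group_sizes=(10, 20, 30), psi=0.02,
        n_steps=6, affected=("all",), n_replicates=25, n_samplings=10,
        seed=5,
    )
    return sensitivity_sweep(cfg)


class TestSensitivitySweep:
    def test_mean_p_declines(self, mean_sweep):
        curve = mean_sweep.groupby("step").mean_p.mean()
        assert curve.iloc[-1] < curve.iloc[0]

    def test_table_schema(self, mean_sweep):
        assert set(mean_sweep.columns) >= {
            "scenario", "step", "psi_shift", "replicate", "mean_p", "mean_f"
        }
        assert len(mean_sweep) == 6 * 25

    def test_sd_sweep_less_sensitive(self, mean_sweep):
        cfg = ScenarioConfig(
            kind="sensitivity-sd", group_sizes=(10, 20, 30), psi=0.02,
            n_steps=6, affected=("all",), n_replicates=25, n_samplings=10,
            seed=5,
        )
        sd_curve = sensitivity_sweep(cfg).groupby("step").mean_p.mean()
        mean_curve = mean_sweep.groupby("step").mean_p.mean()
        assert (sd_curve.to_numpy() >= mean_curve.to_numpy()).all()

    def test_null_degenerate_step(self):
        # psi = 0: within spec == between spec, p should hover near 0.5
        cfg = ScenarioConfig(
            kind="sensitivity-mean", group_sizes=(10, 10, 10), psi=0.0,
            n_steps=1, affected=("all",), n_replicates=200, n_samplings=1,
            seed=2,
        )
        table = sensitivity_sweep(cfg)
        assert 0.4 < table.mean_p.mean() < 0.6

    def test_affected_scenarios(self):
        assert _affected_pairs("one-pair", 3) == [(0, 1), (1, 0)]
        assert len(_affected_pairs("all", 4)) == 12
        with pytest.raises(InputError, match="g >= 3"):
            _affected_pairs("two-pairs", 2)

    def test_wrong_kind_rejected(self):
        with pytest.raises(InputError):
            sensitivity_sweep(ScenarioConfig(kind="grid"))


class TestConvergenceCurve:
    def test_forced_pool_curve_constant(self):
        # singleton groups: zero sampling variance, exactly flat curve
        cfg = ScenarioConfig(
            kind="convergence", group_sizes=(1, 1, 1),
            within=DistributionSpec("uniform", 0, 1),
            between=DistributionSpec("uniform", 2, 4),
            n_samplings=500, seed=0,
        )
        t = convergence_curve(cfg)
        np.testing.assert_allclose(
            t.cum_mean_p, t.cum_mean_p.iloc[0], rtol=1e-12
        )

    def test_curve_stabilizes(self):
        cfg = ScenarioConfig(
            kind="convergence", group_sizes=(10, 20, 30),
            within=DistributionSpec("uniform", 0, 1),
            between=DistributionSpec("uniform", 2, 4),
            n_samplings=5000, seed=1,
        )
        t = convergence_curve(cfg)
        last = t[t.n_samplings >= 500].cum_mean_p
        assert abs(last.iloc[-1] - last.iloc[0]) < 0.1 * abs(last.iloc[-1])

    def test_two_seeds_converge_together(self):
        rows = {}
        for seed_pair in (1, 2):
            cfg = ScenarioConfig(
                kind="convergence", group_sizes=(5, 6, 7),
                within=DistributionSpec("uniform", 0, 1),
                between=DistributionSpec("uniform", 0.5, 1.5),
                n_samplings=4000, seed=9,
            )
            # same matrix (seed fixes generation), different sampling chains
            from nmanova.simulate import generate_block_matrix
            from nmanova.stat import nm_anova

            m, p = generate_block_matrix(
                cfg.group_sizes, cfg.within, cfg.between,
                np.random.default_rng(9),
            )
            res = nm_anova(
                m, p, SamplingOptions(n_samplings=4000, seed=seed_pair)
            )
            rows[seed_pair] = np.cumsum(res.p_values) / np.arange(1, 4001)
        gap_early = abs(rows[1][9] - rows[2][9])
        gap_late = abs(rows[1][-1] - rows[2][-1])
        assert gap_late < gap_early


class TestNullCalibration:
    def test_uniformity_small_scale_g4(self):
        cfg = ScenarioConfig(
            kind="null-calibration", group_sizes=(10,) * 4,
            within=DistributionSpec("normal", 0, 1),
            between=DistributionSpec("normal", 0, 1),
            n_replicates=300, n_samplings=1, seed=3,
        )
        res = null_calibration(cfg)
        assert res.ks_pvalue > 0.01
        assert 0.4 < res.mean_p < 0.6

    def test_requires_matching_specs(self):
        cfg = ScenarioConfig(
            kind="null-calibration",
            within=DistributionSpec("normal", 0, 1),
            between=DistributionSpec("normal", 5, 1),
            n_replicates=10,
        )
        with pytest.raises(InputError, match="within spec == between"):
            null_calibration(cfg)

    def test_sample_too_small(self):
        with pytest.raises(InputError, match="n_replicates must be >= 1"):
            ScenarioConfig(kind="null-calibration", n_replicates=0)
        cfg = ScenarioConfig(
            kind="null-calibration",
            within=DistributionSpec("normal", 0, 1),
            between=DistributionSpec("normal", 0, 1),
            n_replicates=1,
        )
        with pytest.raises(InputError, match="sample too small"):
            null_calibration(cfg)


@pytest.fixture(scope="module")
def matrix_and_candidates():
    m, p_true = generate_block_matrix(
        (8, 8, 8), DistributionSpec("normal", 0, 1),
        DistributionSpec("normal", 1.5, 1), rng=11,
    )
    merged = Partition(
        [0 if l in (0, 1) else 1 for l in p_true.labels], ids=m.ids
    )
    return m, p_true, merged


class TestPartitionSearch:
    def test_true_partition_ranks_first(self, matrix_and_candidates):
        m, p_true, merged = matrix_and_candidates
        table = partition_search(
            m, [merged, p_true], SamplingOptions(n_samplings=20, seed=0),
            names=["merged", "true"],
        )
        assert table.iloc[0].partition == "true"

    def test_duplicate_candidate_identical_score(self, matrix_and_candidates):
        m, p_true, _ = matrix_and_candidates
        table = partition_search(
            m, [p_true, p_true], SamplingOptions(n_samplings=10, seed=4)
        )
        assert table.mean_p.iloc[0] == table.mean_p.iloc[1]

    def test_shuffled_object_order_same_ranking(self, matrix_and_candidates):
        m, p_true, merged = matrix_and_candidates
        rng = np.random.default_rng(0)
        order = rng.permutation(m.n)
        m_shuf = m.reordered(order)
        t1 = partition_search(
            m, [p_true, merged], SamplingOptions(n_samplings=10, seed=1),
            names=["true", "merged"],
        )
        t2 = partition_search(
            m_shuf, [p_true, merged], SamplingOptions(n_samplings=10, seed=1),
            names=["true", "merged"],
        )
        # labels drive the canonical order, so results are bit-identical
        pd.testing.assert_frame_equal(t1, t2)

    def test_mismatched_object_sets_rejected(self, matrix_and_candidates):
        m, p_true, _ = matrix_and_candidates
        other = Partition([1, 2], ids=["zz1", "zz2"])
        with pytest.raises(InputError, match="different object sets"):
            partition_search(m, [p_true, other])

    def test_single_candidate_rejected(self, matrix_and_candidates):
        m, p_true, _ = matrix_and_candidates
        with pytest.raises(InputError, match=">= 2 candidate"):
            partition_search(m, [p_true])


class TestGridExperiment:
    def test_schema_and_reproducibility(self):
        cfg = ScenarioConfig(
            kind="grid", group_sizes=(1, 1, 1), n_replicates=10,
            n_samplings=2, seed=5,
        )
        a = grid_experiment(cfg, n_objects=(24,))
        b = grid_experiment(cfg, n_objects=(24,))
        pd.testing.assert_frame_equal(a, b)
        assert set(a.columns) >= {
            "n_objects", "g", "replicate", "within", "between",
            "mean_p", "significant",
        }
        assert len(a) == 10

    def test_family_restriction(self):
        cfg = ScenarioConfig(
            kind="grid", group_sizes=(1, 1, 1), n_replicates=5,
            n_samplings=2, seed=6,
        )
        t = grid_experiment(cfg, n_objects=(24,), families=("normal",))
        assert t.within.str.startswith("normal").all()

    def test_aligned_grouping_detects_signal(self):
        cfg = ScenarioConfig(
            kind="grid", group_sizes=(1, 1, 1), n_replicates=30,
            n_samplings=2, seed=7,
        )
        t = grid_experiment(
            cfg, n_objects=(30,), random_grouping=False,
            families=("normal", "uniform", "gamma"),
        )
        # random distinct distributions aligned with the tested partition
        # are overwhelmingly detected
        assert t.significant.mean() > 0.5
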