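"""Pipeline orchestration: progression curves, model comparison, reports."""

import json

import numpy as np
import pandas as pd
import pytest

from brainage_influence import (
    FeatureSpec,
    GroupPair,
    RunConfig,
    SyntheticSpec,
    generate_cohort,
    mi_with_age,
    rank_features,
    run_feature_influence,
    run_model_vs_logistic,
    write_report,
)

PAIR = GroupPair("CN", "AD")


def small_cohort(seed=0):
    """A 4-feature, 2-group cohort small enough for fast sweeps: two
    age-informative volumes, two disease-informative scores."""
    spec = SyntheticSpec(
        n_per_group={"CN": 120, "AD": 60},
        age_range=(55.0, 90.0),
        feature_specs=[
            FeatureSpec("vol1", age_slope=-0.035, noise_sd=0.15,
                        group_offsets={"AD": -0.10}, shares_latent=True),
            FeatureSpec("vol2", age_slope=-0.025, noise_sd=0.15,
                        group_offsets={"AD": -0.06}, shares_latent=True),
            FeatureSpec("cog1", age_slope=-0.006, noise_sd=1.0,
                        group_offsets={"AD": -2.2}),
            FeatureSpec("cog2", age_slope=-0.004, noise_sd=1.0,
                        group_offsets={"AD": -1.6}),
        ],
        latent_loading=0.08,
        seed=seed,
    )
    return generate_cohort(spec)


def config(master=0, ordering="both"):
    cfg = RunConfig()
    cfg.seeds.master = master
    cfg.experiment.ordering = ordering
    return cfg


@pytest.fixture(scope="module")
def influence_result():
    return run_feature_influence(small_cohort(seed=1), PAIR, config(master=1))


@pytest.fixture(scope="module")
def comparison_result():
    return run_model_vs_logistic(
        small_cohort(seed=2), PAIR, config(master=2, ordering="age")
    )


class TestFeatureInfluence:
    @pytest.fixture
    def result(self, influence_result):
        return influence_result

    def test_two_curves_one_point_per_feature(self, result):
        assert set(result.curves) == {"age", "discrimination"}
        for curve in result.curves.values():
            assert list(curve.points["k"]) == [1, 2, 3, 4]

    def test_curves_coincide_at_full_feature_set(self, result):
        """At k = p both orderings train on the same features with the same
        seeds, so MAE and AUC agree exactly."""
        a = result.curves["age"].points.iloc[-1]
        d = result.curves["discrimination"].points.iloc[-1]
        assert a["mae"] == d["mae"]
        assert a["auc"] == d["auc"]

    def test_tradeoff_at_single_feature(self, result):
        """Age ordering starts from the best age predictor (low MAE, weakly
        diagnostic delta); discrimination ordering the reverse."""
        a = result.curves["age"].points.iloc[0]
        d = result.curves["discrimination"].points.iloc[0]
        assert a["mae"] < d["mae"]
        assert a["auc"] < d["auc"]

    def test_feature_added_tracks_ranking(self, result):
        for crit, curve in result.curves.items():
            assert tuple(curve.points["feature_added"]) == result.rankings[crit].order

    def test_long_table_shape(self, result):
        table = result.table()
        assert len(table) == 8
        assert set(table["ordering"]) == {"age", "discrimination"}


class TestModelVsLogistic:
    @pytest.fixture
    def result(self, comparison_result):
        return comparison_result

    def test_four_curves_on_equal_k_grids(self, result):
        kinds = {c.model_kind for c in result.curves}
        assert kinds == {"delta-linear", "delta-ridge", "delta-svr", "direct-logistic"}
        grids = [tuple(c.points["k"]) for c in result.curves]
        assert len(set(grids)) == 1

    def test_linear_and_ridge_deltas_nearly_coincide(self, result):
        by_kind = {c.model_kind: c.points for c in result.curves}
        diff = np.abs(
            by_kind["delta-linear"]["auc_mean"].to_numpy()
            - by_kind["delta-ridge"]["auc_mean"].to_numpy()
        )
        assert diff.max() < 0.03

    def test_augmentation_table_present(self, result):
        assert list(result.augmentation["input_set"]) == [
            "features", "features+age", "delta", "features+delta"
        ]

    def test_direct_logistic_wins_when_signal_is_age_orthogonal(self):
        """Label carried by a feature with zero age slope: the delta is a 1-D
        age-axis projection and discards it, so the direct model dominates
        at the full feature set."""
        spec = SyntheticSpec(
            n_per_group={"CN": 150, "AD": 80},
            age_range=(55.0, 90.0),
            feature_specs=[
                FeatureSpec("agefeat", age_slope=-0.035, noise_sd=0.10),
                FeatureSpec("orth", age_slope=0.0, noise_sd=1.0,
                            group_offsets={"AD": -2.5}),
            ],
            seed=3,
        )
        cohort = generate_cohort(spec)
        res = run_model_vs_logistic(cohort, PAIR, config(master=3, ordering="age"))
        by_kind = {c.model_kind: c.points for c in res.curves}
        direct = by_kind["direct-logistic"]["auc_mean"].iloc[-1]
        for kind in ("delta-linear", "delta-ridge", "delta-svr"):
            assert direct > by_kind[kind]["auc_mean"].iloc[-1]


class TestRankingStability:
    def test_pure_noise_feature_never_displaces_top_feature(self):
        """Appending an age-independent noise column leaves the top-ranked
        feature unchanged across seeds."""
        for seed in range(10):
            cohort = small_cohort(seed=seed)
            top = rank_features(mi_with_age(cohort, seed=seed)).order[0]
            rng = np.random.default_rng(1000 + seed)
            frame = cohort.frame.copy()
            frame["noise17"] = rng.standard_normal(cohort.n_subjects)
            extended = type(cohort)(frame, cohort.feature_names + ["noise17"])
            top_ext = rank_features(mi_with_age(extended, seed=seed)).order[0]
            assert top_ext == top


class TestWriteReport:
    def test_feature_influence_outputs_and_manifest(self, tmp_path):
        cohort = small_cohort(seed=4)
        cfg = config(master=4)
        result = run_feature_influence(cohort, PAIR, cfg)
        files = write_report(result, tmp_path / "out", cfg)
        names = {f.name for f in files}
        assert f"rankings_{PAIR}.csv" in names
        assert f"feature_influence_{PAIR}.csv" in names
        assert f"feature_influence_{PAIR}.png" in names
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert manifest["master_seed"] == 4
        assert manifest["config"]["mi"]["k_neighbors"] == 3
        assert manifest["config_hash"]

    def test_rerun_is_byte_identical(self, tmp_path):
        cohort = small_cohort(seed=5)
        cfg = config(master=5)
        for d in ("a", "b"):
            write_report(
                run_feature_influence(cohort, PAIR, cfg), tmp_path / d, cfg
            )
        for name in (f"rankings_{PAIR}.csv", f"feature_influence_{PAIR}.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_model_vs_logistic_outputs(self, tmp_path):
        cohort = small_cohort(seed=6)
        cfg = config(master=6, ordering="age")
        result = run_model_vs_logistic(cohort, PAIR, cfg)
        files = write_report(result, tmp_path / "out", cfg)
        names = {f.name for f in files}
        assert f"model_vs_logistic_{PAIR}.csv" in names
        assert f"augmentation_{PAIR}.csv" in names
        aug = pd.read_csv(tmp_path / "out" / f"augmentation_{PAIR}.csv")
        assert len(aug) == 4
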