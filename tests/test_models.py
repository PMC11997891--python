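"""Random-forest training, prediction, importance ranking, metric sweep."""

import numpy as np
import pandas as pd
import pytest

from spectrohist import ModelSpec, metric_count_sweep, predict_image, rank_metrics, train
from spectrohist.cube_io import LABEL_CODES
from spectrohist.models import DEFAULT_TREES, RAPID_CODES, predict_table


def cloud_table(rng, n_per_class=60, n_noise=4, sep=4.0, labels=(1, 5)):
    """Two Gaussian clouds separated along one informative feature."""
    rows = []
    for i, lab in enumerate(labels):
        x0 = rng.standard_normal(n_per_class) + i * sep
        noise = rng.standard_normal((n_per_class, n_noise))
        df = pd.DataFrame(noise, columns=[f"n{j}_max" for j in range(n_noise)])
        df.insert(0, "inform_max", x0)
        df.insert(0, "mouse_id", [f"m{k % 4}" for k in range(n_per_class)])
        df.insert(1, "row", 0)
        df.insert(2, "col", 0)
        df.insert(3, "label", lab)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


class TestTrain:
    def test_separable_clouds_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        table = cloud_table(rng)
        model = train(table, ModelSpec(mode="detailed", seed=0))
        pred = predict_table(model, table)
        truth = np.where(table["label"] == 1, "benign", "fiber")
        assert (pred == truth).mean() == 1.0

    def test_permuted_labels_give_chance_accuracy(self):
        """Held-out accuracy under a permutation null is ~1/n_classes."""
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            table = cloud_table(rng, n_per_class=80)
            perm = table.copy()
            perm["label"] = rng.permutation(perm["label"].to_numpy())
            tr = perm.iloc[::2].reset_index(drop=True)
            te = perm.iloc[1::2].reset_index(drop=True)
            model = train(tr, ModelSpec(mode="detailed", seed=seed))
            pred = predict_table(model, te)
            truth = np.where(te["label"] == 1, "benign", "fiber")
            accs.append((pred == truth).mean())
        assert np.mean(accs) == pytest.approx(0.5, abs=0.1)

    @pytest.mark.parametrize("mode,n", list(DEFAULT_TREES.items()))
    def test_default_tree_counts(self, mode, n):
        assert ModelSpec(mode=mode).n_trees == n

    def test_detailed_model_reports_50_trees(self):
        rng = np.random.default_rng(1)
        model = train(cloud_table(rng), ModelSpec(mode="detailed", seed=1))
        assert len(model.estimator.estimators_) == 50

    def test_single_class_rejected(self):
        rng = np.random.default_rng(2)
        table = cloud_table(rng, labels=(1, 1))
        with pytest.raises(ValueError):
            train(table, ModelSpec(mode="detailed"))

    def test_unknown_feature_subset_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="unknown"):
            train(cloud_table(rng), ModelSpec(mode="rapid", feature_subset=["zz_max"]))

    def test_rapid_map_collapses_cancer_and_panin(self):
        rng = np.random.default_rng(4)
        table = cloud_table(rng, labels=(2, 3))  # cancer, PanIN
        table2 = cloud_table(rng, labels=(1, 5))
        both = pd.concat([table, table2], ignore_index=True)
        model = train(both, ModelSpec(mode="rapid", seed=0))
        assert set(model.classes_) == {"benign", "fiber", "pathology"}

    def test_importances_sum_to_one(self):
        rng = np.random.default_rng(5)
        model = train(cloud_table(rng), ModelSpec(mode="rapid", seed=0))
        assert sum(model.importances.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in model.importances.values())

    def test_seeded_determinism(self):
        rng = np.random.default_rng(6)
        table = cloud_table(rng)
        m1 = train(table, ModelSpec(mode="rapid", seed=42))
        m2 = train(table, ModelSpec(mode="rapid", seed=42))
        assert np.array_equal(predict_table(m1, table), predict_table(m2, table))


class TestPredictImage:
    def test_benign_only_cube_predicts_all_benign(self, region_table):
        import dataclasses

        from spectrohist.phantom import default_class_models, make_phantom
        from spectrohist.metrics import build_feature_table
        from conftest import small_params

        params = small_params(
            axis_spacing=4.0,
            class_fractions={"benign": 0.35, "fiber": 0.25},
            noise_sigma_white=0.002, noise_sigma_corr=0.0, seed=8,
        )
        ph = make_phantom(params, default_class_models(), "m", "control",
                          np.random.default_rng(8))
        table = build_feature_table(ph.cube, ph.labels, region_table)
        model = train(table, ModelSpec(mode="detailed", seed=0))

        benign_only = dataclasses.replace(params, class_fractions={"benign": 0.5})
        ph2 = make_phantom(benign_only, default_class_models(), "m2", "control",
                           np.random.default_rng(9))
        mask, proba = predict_image(model, ph2.cube, region_table)
        tissue = ph2.cube.tissue_mask
        assert (mask[tissue] == LABEL_CODES["benign"]).mean() > 0.95
        assert (mask[~tissue] == 0).all()
        assert proba.shape[2] == len(model.classes_)

    def test_empty_tissue_mask_all_zero(self, region_table):
        from spectrohist import HyperCube

        axis = 900.0 + 4.0 * np.arange(738)
        cube = HyperCube(
            np.ones((4, 4, 738)), axis, np.zeros((4, 4), dtype=bool)
        )
        rng = np.random.default_rng(0)
        model = train(cloud_table(rng), ModelSpec(mode="rapid", seed=0))
        # feature names won't match, but an empty mask never reaches predict
        mask, proba = predict_image(model, cube, region_table)
        assert (mask == 0).all()

    def test_prediction_deterministic(self, region_table, kpc_phantom):
        from spectrohist.metrics import build_feature_table

        table = build_feature_table(kpc_phantom.cube, kpc_phantom.labels, region_table)
        model = train(table, ModelSpec(mode="rapid", seed=3))
        m1, _ = predict_image(model, kpc_phantom.cube, region_table)
        m2, _ = predict_image(model, kpc_phantom.cube, region_table)
        np.testing.assert_array_equal(m1, m2)
        assert set(np.unique(m1[kpc_phantom.cube.tissue_mask])) <= set(
            RAPID_CODES.values()
        )


def noisy_table(rng, n_inform=1, n_noise=9, n=200, effect=3.0):
    y = rng.integers(0, 2, n)
    cols = {}
    for i in range(n_inform):
        cols[f"inf{i}_max"] = rng.standard_normal(n) + effect * y
    for j in range(n_noise):
        cols[f"noise{j}_max"] = rng.standard_normal(n)
    df = pd.DataFrame(cols)
    df.insert(0, "mouse_id", [f"m{k % 5}" for k in range(n)])
    df.insert(1, "row", 0)
    df.insert(2, "col", 0)
    df.insert(3, "label", np.where(y == 1, LABEL_CODES["cancer"], LABEL_CODES["benign"]))
    return df


class TestRankMetrics:
    def test_informative_feature_ranked_first(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            table = noisy_table(rng)
            ranked = rank_metrics(table, ModelSpec(mode="importance", seed=seed))
            hits += ranked[0] == "inf0_max"
        assert hits >= 9

    def test_duplicated_informative_pair_tops_ranking(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            table = noisy_table(rng)
            table["inf_copy_max"] = table["inf0_max"]
            ranked = rank_metrics(table, ModelSpec(mode="importance", seed=seed))
            hits += set(ranked[:2]) == {"inf0_max", "inf_copy_max"}
        assert hits >= 8

    def test_all_noise_importance_stays_near_uniform(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            table = noisy_table(rng, n_inform=0, n_noise=10, effect=0.0)
            eff = ModelSpec(mode="importance", seed=seed)
            model = train(
                table,
                ModelSpec(mode="rapid", n_trees=eff.n_trees,
                          class_map={"benign": "benign", "cancer": "pathology"},
                          seed=seed),
            )
            top = max(model.importances.values())
            hits += top < 3.0 / 10
        assert hits >= 8

    def test_ties_keep_column_order(self):
        rng = np.random.default_rng(0)
        table = noisy_table(rng)
        ranked = rank_metrics(table, ModelSpec(mode="importance", seed=0))
        assert sorted(ranked) == sorted(
            c for c in table.columns if c.endswith("_max")
        )


class TestMetricCountSweep:
    def test_full_count_matches_full_rapid_model(self):
        rng = np.random.default_rng(1)
        table = noisy_table(rng, n_inform=2, n_noise=4)
        ranked = rank_metrics(table, ModelSpec(mode="importance", seed=1))
        res = metric_count_sweep(table, ranked, [len(ranked)], seed=1)
        # recompute LOMO accuracy of the full rapid model independently
        correct = total = 0
        for mouse in table["mouse_id"].unique():
            tr = table[table["mouse_id"] != mouse]
            te = table[table["mouse_id"] == mouse]
            spec = ModelSpec(mode="rapid", feature_subset=ranked, seed=1)
            model = train(tr, spec)
            pred = predict_table(model, te)
            truth = np.where(te["label"] == LABEL_CODES["cancer"], "pathology", "benign")
            correct += (pred == truth).sum()
            total += len(te)
        assert res.accuracies[0] == pytest.approx(correct / total)

    def test_two_informative_metrics_saturate_curve(self):
        """Accuracy plateaus within 1 point of its max from k=2 onward."""
        ok = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            table = noisy_table(rng, n_inform=2, n_noise=6, n=300)
            ranked = rank_metrics(table, ModelSpec(mode="importance", seed=seed))
            res = metric_count_sweep(table, ranked, [1, 2, 4, 8], seed=seed)
            tail = res.accuracies[1:]
            ok += max(res.accuracies) - min(tail) <= 0.01 + 1e-9
        assert ok >= 4

    def test_chosen_k_reports_that_many_names(self):
        rng = np.random.default_rng(2)
        table = noisy_table(rng, n_inform=2, n_noise=8)
        ranked = rank_metrics(table, ModelSpec(mode="importance", seed=2))
        res = metric_count_sweep(table, ranked, [1, 2, 3, 6], seed=2)
        assert len(res.chosen_metrics) == res.chosen_k
        assert res.chosen_metrics == ranked[: res.chosen_k]

    def test_empty_counts_rejected(self):
        rng = np.random.default_rng(3)
        table = noisy_table(rng)
        with pytest.raises(ValueError):
            metric_count_sweep(table, ["inf0_max"], [])

    def test_monotone_information(self):
        """Accuracy with all metrics is not much worse than with one."""
        rng = np.random.default_rng(4)
        table = noisy_table(rng, n_inform=2, n_noise=6, n=300)
        ranked = rank_metrics(table, ModelSpec(mode="importance", seed=4))
        res = metric_count_sweep(table, ranked, [1, len(ranked)], seed=4)
        assert res.accuracies[-1] >= res.accuracies[0] - 0.05
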