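"""Protocol tests: fold plans, grid enumeration, ranking, significance."""

import numpy as np
import pandas as pd
import pytest

from dramote import (
    ExperimentGrid,
    LabeledDataset,
    SamplerConfig,
    SimSpec,
    average_ranks,
    enumerate_experiments,
    gaussian_imbalance,
    make_fold_plan,
    rank_methods,
    run_cell,
    significance_analysis,
)
from dramote.benchmark import anova_oneway, summarize_results
from dramote.errors import MissingCellsError, StratificationError
from dramote.metrics import is_defined


class TestFoldPlan:
    def test_balanced_ten_rows(self):
        ds = LabeledDataset(np.arange(20.0).reshape(10, 2), [1] * 5 + [-1] * 5)
        plan = make_fold_plan(ds, 5, seed=0)
        for te in plan.test_indices:
            assert te.shape[0] == 2
            assert set(ds.y[te]) == {-1, 1}

    def test_partition_law(self, imbalanced):
        plan = make_fold_plan(imbalanced, 5, seed=3)
        union = np.concatenate(plan.test_indices)
        assert sorted(union.tolist()) == list(range(imbalanced.n_samples))
        for i in range(5):
            for j in range(i + 1, 5):
                assert not set(plan.test_indices[i]) & set(plan.test_indices[j])

    def test_determinism(self, imbalanced):
        a = make_fold_plan(imbalanced, 5, seed=9)
        b = make_fold_plan(imbalanced, 5, seed=9)
        for ta, tb in zip(a.test_indices, b.test_indices):
            np.testing.assert_array_equal(ta, tb)

    def test_small_class_error_names_class(self):
        ds = LabeledDataset(np.zeros((8, 1)), [1, 1, 1, -1, -1, -1, -1, -1])
        with pytest.raises(StratificationError, match=r"\+1"):
            make_fold_plan(ds, 5, seed=0)


class TestEnumerateExperiments:
    def test_single_dataset_grid(self):
        n, cells = enumerate_experiments(ExperimentGrid(datasets=("d1",)))
        assert n == 150 and len(cells) == 150

    def test_nine_datasets(self):
        grid = ExperimentGrid(datasets=tuple(f"d{i}" for i in range(9)))
        n, _ = enumerate_experiments(grid)
        assert n == 1350

    def test_empty_methods(self):
        grid = ExperimentGrid(datasets=("d1",), methods=())
        assert enumerate_experiments(grid)[0] == 0


class TestRunCell:
    def test_leakage_audit_empty_intersection(self, imbalanced):
        plan = make_fold_plan(imbalanced, 5, seed=1)
        _, audit = run_cell(
            imbalanced, "knn", "smote", 0, plan,
            sampler_config=SamplerConfig(method="smote", seed=1),
        )
        assert audit["fitted_rows"] & audit["test_rows"] == set()

    def test_ru_on_balanced_data_keeps_size(self):
        ds = gaussian_imbalance(SimSpec(25, 25, 3, 3.0, seed=4))
        plan = make_fold_plan(ds, 5, seed=0)
        metrics, audit = run_cell(
            ds, "lda", "ru", 0, plan,
            sampler_config=SamplerConfig(method="ru", seed=0),
        )
        # balanced input: under-sampling to 1:1 removes (almost) nothing
        assert len(audit["fitted_rows"]) >= ds.n_samples - len(audit["test_rows"]) - 1

    @pytest.mark.parametrize("method", ["ru", "smote", "mwmote", "gsvmru", "dramote"])
    def test_separable_gives_perfect_precision(self, fixtures, method):
        ds = fixtures["separable"]
        plan = make_fold_plan(ds, 5, seed=2)
        metrics, _ = run_cell(
            ds, "svm_linear", method, 0, plan,
            sampler_config=SamplerConfig(method=method, seed=2),
        )
        assert metrics["precision"] == pytest.approx(1.0)


class TestRankMethods:
    def _results(self, means: dict[str, float]) -> pd.DataFrame:
        rows = []
        for clf in ("c1",):
            for method, mu in means.items():
                for fold in range(3):
                    rows.append(
                        {
                            "dataset": "d", "classifier": clf, "method": method,
                            "fold": fold, "f1": mu, "precision": mu,
                            "failed": False,
                        }
                    )
        return pd.DataFrame(rows)

    def test_sort_order(self):
        table = rank_methods(self._results({"a": 0.5, "b": 0.2, "c": 0.7}))
        assert table.ranks.loc["c1"].to_dict() == {"a": 2, "b": 3, "c": 1}

    def test_published_rank_averages(self):
        # the published per-classifier F1 rank columns
        ranks = pd.DataFrame(
            {
                "RU": [3, 4, 3, 4, 1, 4],
                "GSVM-RU": [5, 5, 5, 5, 4, 5],
                "SMOTE": [1, 2, 2, 2, 3, 1],
                "MWMOTE": [4, 3, 4, 3, 5, 3],
                "DRAMOTE": [2, 1, 1, 1, 2, 2],
            },
            index=["SVM-L", "SVM-R", "KNN", "LDA", "NBC", "RF"],
        )
        avg = average_ranks(ranks)
        assert round(avg["DRAMOTE"], 2) == 1.50
        assert round(avg["SMOTE"], 2) == 1.83

    def test_rank_permutation_validity(self, imbalanced):
        from dramote.benchmark import run_grid

        res = run_grid(
            {"d": imbalanced}, classifiers=("knn", "lda"),
            methods=("ru", "smote"), n_folds=3, seed=0,
        )
        table = rank_methods(res)
        m = table.ranks.shape[1]
        for _, row in table.ranks.iterrows():
            assert sorted(row.tolist()) == list(range(1, m + 1))
        assert table.average.sum() == pytest.approx(m * (m + 1) / 2)

    def test_missing_cells_error(self):
        df = self._results({"a": 0.5})
        df = pd.concat(
            [df, pd.DataFrame([{"dataset": "d", "classifier": "c2",
                                "method": "b", "fold": 0, "f1": 0.1,
                                "precision": 0.1, "failed": False}])]
        )
        with pytest.raises(MissingCellsError):
            rank_methods(df)


class TestSignificance:
    def test_worked_anova_example(self):
        f, p = anova_oneway(
            [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([3.0, 4, 5])]
        )
        # SSB = 6, SSW = 6, df = (2, 6): F = (6/2)/(6/6) = 3
        assert f == pytest.approx(3.0, abs=1e-9)

    def test_second_hand_example(self):
        # groups {1,2} and {3,4}: SSB = 4, SSW = 1, df = (1, 2) -> F = 8
        f, _ = anova_oneway([np.array([1.0, 2]), np.array([3.0, 4])])
        assert f == pytest.approx(8.0, abs=1e-9)

    def test_identical_groups_f_zero(self):
        df = pd.DataFrame(
            {
                "method": ["a"] * 3 + ["b"] * 3,
                "f1": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            }
        )
        rep = significance_analysis(df, "f1")
        assert rep["anova_f"] == pytest.approx(0.0)
        assert not rep["significant"] and rep["pairs"] == []

    def test_all_equal_values_undefined(self):
        df = pd.DataFrame({"method": ["a", "a", "b", "b"], "f1": [1.0] * 4})
        rep = significance_analysis(df, "f1")
        assert not is_defined(rep["anova_f"])

    def test_separated_groups_flagged_by_tukey(self, rng):
        vals = np.concatenate([rng.normal(0, 0.01, 10), rng.normal(5, 0.01, 10)])
        df = pd.DataFrame({"method": ["a"] * 10 + ["b"] * 10, "f1": vals})
        rep = significance_analysis(df, "f1")
        assert rep["significant"]
        assert any(pr["reject"] for pr in rep["pairs"])


def test_summary_mean_std_convention(imbalanced):
    from dramote.benchmark import run_grid

    res = run_grid(
        {"d": imbalanced}, classifiers=("lda",), methods=("ru",),
        n_folds=3, seed=0,
    )
    summ = summarize_results(res, metrics=("f1",), by=("dataset", "method"))
    vals = res["f1"].dropna()
    assert summ.loc[("d", "ru"), "f1_mean"] == pytest.approx(vals.mean())
    assert summ.loc[("d", "ru"), "f1_std"] == pytest.approx(vals.std())
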