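"""Cross-validated benchmarking of the imbalance corrections.

Implements the full evaluation protocol: stratified 5-fold CV with
leakage-proof per-fold preprocessing (the test fold never reaches any
fitting step, and an audit record proves it), the fold x classifier x
method experiment grid, per-classifier method ranking on a chosen metric
with rank averaging, and one-way ANOVA with pairwise Tukey HSD follow-up
for significance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .classifiers import ROSTER, make_classifier, minority_score
from .data import LabeledDataset, apply_standardizer, fit_standardizer
from .errors import MissingCellsError, StratificationError
from .feedback import FeedbackConfig, dramote_oversample
from .metrics import (
    METRIC_NAMES,
    UNDEFINED,
    compute_metrics,
    confusion_counts,
    roc_auc,
)
from .samplers import (
    METHODS,
    SamplerConfig,
    gsvm_ru,
    mwmote,
    random_undersample,
    smote,
)

__all__ = [
    "FoldPlan",
    "ExperimentGrid",
    "make_fold_plan",
    "enumerate_experiments",
    "apply_method",
    "run_cell",
    "run_grid",
    "rank_methods",
    "average_ranks",
    "RankTable",
    "significance_analysis",
    "summarize_results",
]


@dataclass
class FoldPlan:
    """Disjoint stratified test index-sets covering every row."""

    test_indices: list[np.ndarray]
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.test_indices)

    def train_indices(self, fold: int) -> np.ndarray:
        test = set(self.test_indices[fold].tolist())
        n = sum(t.shape[0] for t in self.test_indices)
        return np.asarray([i for i in range(n) if i not in test], dtype=int)


def make_fold_plan(data: LabeledDataset, n_folds: int, seed: int) -> FoldPlan:
    """Stratified partition into n_folds test sets, deterministic under
    the seed.  Per-fold class counts differ by at most 1 from perfect
    stratification."""
    for label in (-1, 1):
        count = int(np.sum(data.y == label))
        if count < n_folds:
            raise StratificationError(
                f"class {label:+d} has {count} rows < {n_folds} folds"
            )
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    test_sets = [np.sort(te) for _, te in skf.split(data.X, data.y)]
    return FoldPlan(test_indices=test_sets, seed=seed)


@dataclass
class ExperimentGrid:
    """The dataset x classifier x method x fold enumeration."""

    datasets: tuple[str, ...]
    classifiers: tuple[str, ...] = ROSTER
    methods: tuple[str, ...] = METHODS
    n_folds: int = 5


def enumerate_experiments(grid: ExperimentGrid) -> tuple[int, list[tuple]]:
    """Exact Cartesian product of the grid; returns (count, cell list)."""
    cells = list(
        itertools.product(
            grid.datasets, grid.classifiers, grid.methods, range(grid.n_folds)
        )
    )
    return len(cells), cells


# ---------------------------------------------------------------------------
# cell execution
# ---------------------------------------------------------------------------

def apply_method(
    method: str,
    data: LabeledDataset,
    sampler_config: SamplerConfig,
    feedback_config: FeedbackConfig | None = None,
) -> LabeledDataset:
    """Dispatch a named imbalance correction on a (training) dataset."""
    if method == "none":
        return data
    if method == "ru":
        return random_undersample(data, sampler_config)
    if method == "smote":
        return smote(data, sampler_config)[0]
    if method == "mwmote":
        return mwmote(data, sampler_config)[0]
    if method == "gsvmru":
        return gsvm_ru(data, sampler_config)
    if method == "dramote":
        return dramote_oversample(data, sampler_config, feedback_config)[0]
    raise ValueError(f"unknown method {method!r}; methods: {METHODS}")


def run_cell(
    data: LabeledDataset,
    classifier: str,
    method: str,
    fold: int,
    plan: FoldPlan,
    sampler_config: SamplerConfig | None = None,
    feedback_config: FeedbackConfig | None = None,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Execute one grid cell: split -> fit standardizer on train ->
    correct train only -> fit classifier -> score the untouched test fold.

    Returns (metric record, audit record).  The audit record carries the
    set of original row indices that reached any fitting step; its
    intersection with the test fold must be empty.
    """
    sampler_config = sampler_config or SamplerConfig(method=method, seed=seed)
    if feedback_config is None:
        feedback_config = FeedbackConfig(feedback_classifier=classifier)
    elif feedback_config.feedback_classifier is None:
        # pair the feedback classifier with the one being benchmarked
        from dataclasses import replace

        feedback_config = replace(feedback_config, feedback_classifier=classifier)

    test_idx = plan.test_indices[fold]
    train_idx = plan.train_indices(fold)
    train = data.subset(train_idx)
    test = data.subset(test_idx)

    std = fit_standardizer(train, row_indices=train_idx)
    train_z = LabeledDataset(
        apply_standardizer(std, train.X), train.y,
        ids=[str(i) for i in train_idx],
    )
    corrected = apply_method(method, train_z, sampler_config, feedback_config)

    # provenance: every corrected row is either an original training row or
    # a synthetic interpolant of training rows
    fitted_rows = set(std.fitted_rows.tolist())
    original_rows = {int(i) for i in corrected.ids if not i.startswith("synth")} \
        if corrected.ids is not None else set(train_idx.tolist())
    fitted_rows |= original_rows

    clf = make_classifier(classifier, seed=seed)
    clf.fit(corrected.X, corrected.y)

    Zt = apply_standardizer(std, test.X)
    pred = clf.predict(Zt)
    scores = minority_score(clf, Zt)
    report = compute_metrics(confusion_counts(test.y, pred))
    report.roc_auc = roc_auc(scores, test.y)

    audit = {
        "fitted_rows": fitted_rows,
        "test_rows": set(test_idx.tolist()),
        "method": method,
        "classifier": classifier,
        "fold": fold,
    }
    return report.to_dict(), audit


def run_grid(
    datasets: dict[str, LabeledDataset],
    classifiers: tuple[str, ...] = ROSTER,
    methods: tuple[str, ...] = METHODS,
    n_folds: int = 5,
    seed: int = 0,
    target_ratio: float = 1.0,
    feedback_config: FeedbackConfig | None = None,
    collect_audits: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[dict]]:
    """Run the full grid and return the flat result table.

    One record per cell (dataset, classifier, method, fold) with the
    metric vector; a sampler or classifier failure flags the cell and the
    run continues.
    """
    grid = ExperimentGrid(
        datasets=tuple(datasets), classifiers=classifiers, methods=methods,
        n_folds=n_folds,
    )
    records: list[dict] = []
    audits: list[dict] = []
    for ds_name, data in datasets.items():
        plan = make_fold_plan(data, n_folds, seed)
        for classifier, method, fold in itertools.product(
            classifiers, methods, range(n_folds)
        ):
            cfg = SamplerConfig(
                method=method, seed=seed + 1000 * fold, target_ratio=target_ratio
            )
            rec = {
                "dataset": ds_name, "classifier": classifier,
                "method": method, "fold": fold, "failed": False,
            }
            try:
                metrics, audit = run_cell(
                    data, classifier, method, fold, plan,
                    sampler_config=cfg, feedback_config=feedback_config,
                    seed=seed,
                )
                rec.update(metrics)
                if collect_audits:
                    audits.append(audit)
            except Exception as exc:  # flagged cell, grid continues
                rec["failed"] = True
                rec["error"] = repr(exc)
                rec.update({m: UNDEFINED for m in METRIC_NAMES})
            records.append(rec)
    result = pd.DataFrame.from_records(records)
    n_expected, _ = enumerate_experiments(grid)
    assert len(result) == n_expected
    return (result, audits) if collect_audits else result


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

@dataclass
class RankTable:
    """Per-classifier method ranks (1 = best) and per-method averages."""

    ranks: pd.DataFrame  # index: classifier, columns: method, integer ranks
    average: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.average = average_ranks(self.ranks)


def average_ranks(ranks: pd.DataFrame) -> pd.Series:
    """Average each method's rank position over classifiers.

    The method with the lowest averaged rank is the best performing.
    """
    return ranks.mean(axis=0)


def rank_methods(
    results: pd.DataFrame, metric: str = "f1"
) -> RankTable:
    """Rank methods per classifier by their mean metric over folds (and
    datasets), rank 1 = best.

    Undefined metric values are excluded from the means.  Rank ties break
    by higher mean precision, then method name.  Missing
    (classifier, method) combinations raise an error listing them.
    """
    ok = results[~results.get("failed", False)] if "failed" in results else results
    needed = set(
        itertools.product(ok["classifier"].unique(), ok["method"].unique())
    )
    have = set(map(tuple, ok[["classifier", "method"]].drop_duplicates().values))
    all_pairs = set(
        itertools.product(
            results["classifier"].unique(), results["method"].unique()
        )
    )
    missing = sorted(all_pairs - have) or sorted(needed - have)
    if missing:
        raise MissingCellsError(f"missing (classifier, method) cells: {missing}")

    means = ok.groupby(["classifier", "method"])[metric].mean().unstack()
    prec = ok.groupby(["classifier", "method"])["precision"].mean().unstack()
    if means.isna().any().any():
        bad = [
            (c, m)
            for c in means.index for m in means.columns
            if pd.isna(means.loc[c, m])
        ]
        raise MissingCellsError(f"no defined {metric} values for cells: {bad}")

    rank_rows = {}
    for clf in means.index:
        order = sorted(
            means.columns,
            key=lambda m: (-means.loc[clf, m], -prec.loc[clf, m]
                           if pd.notna(prec.loc[clf, m]) else 0.0, m),
        )
        rank_rows[clf] = {m: r + 1 for r, m in enumerate(order)}
    ranks = pd.DataFrame.from_dict(rank_rows, orient="index")[list(means.columns)]
    return RankTable(ranks=ranks)


def summarize_results(
    results: pd.DataFrame,
    metrics: tuple[str, ...] = METRIC_NAMES,
    by: tuple[str, ...] = ("dataset", "method"),
) -> pd.DataFrame:
    """Mean (and standard deviation) over folds per group, with a count
    of excluded undefined values per metric."""
    ok = results[~results.get("failed", False)] if "failed" in results else results
    out = {}
    g = ok.groupby(list(by))
    for m in metrics:
        out[f"{m}_mean"] = g[m].mean()
        out[f"{m}_std"] = g[m].std()
        out[f"{m}_n_undefined"] = g[m].apply(lambda s: int(s.isna().sum()))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across groups."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    allvals = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(allvals) == 0:
        return UNDEFINED, UNDEFINED  # zero variance everywhere
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def significance_analysis(
    results: pd.DataFrame,
    metric: str = "f1",
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA across methods on fold-level metric values; when the
    methods differ (p < alpha) follow up with all-pairs Tukey HSD at the
    same alpha, flagging each significantly different pair."""
    ok = results[~results.get("failed", False)] if "failed" in results else results
    ok = ok.dropna(subset=[metric])
    methods = sorted(ok["method"].unique())
    groups = [ok.loc[ok["method"] == m, metric].to_numpy() for m in methods]
    f, p = anova_oneway(groups)
    report: dict = {
        "metric": metric,
        "alpha": alpha,
        "methods": methods,
        "anova_f": f,
        "anova_p": p,
        "df_between": len(groups) - 1,
        "df_within": sum(len(g) for g in groups) - len(groups),
        "significant": bool(np.isfinite(p) and p < alpha),
        "pairs": [],
    }
    if report["significant"]:
        tk = pairwise_tukeyhsd(
            ok[metric].to_numpy(), ok["method"].to_numpy(), alpha=alpha
        )
        tbl = tk.summary().data[1:]
        for row in tbl:
            report["pairs"].append(
                {
                    "a": str(row[0]),
                    "b": str(row[1]),
                    "meandiff": float(row[2]),
                    "p_adj": float(row[3]),
                    "reject": bool(row[6]),
                }
            )
    return report
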