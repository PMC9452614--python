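"""Classifier benchmarking with grouped CV and statistical comparison.

Four classifiers (logistic regression, RBF-kernel SVM, random forest,
gradient boosting) are trained on a feature table and evaluated by
stratified, patient-grouped k-fold cross-validation (all rows of a case
share a fold).  A feature standardizer is learned on training rows only
and applied to LR/SVM; tree ensembles consume raw features.
Harmonization, when requested, is refit on each training fold and the
held-out fold is transformed with the training-fold model, so no
statistic of a held-out case ever enters a fitted artifact.

AUC uses the Mann-Whitney construction with ties counted 1/2;
correlated AUCs are compared by DeLong's test, paired binary
predictions by McNemar (continuity-corrected) and a chi-square test.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedGroupKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from lipomics.combat import NON_FEATURE_COLUMNS, ComBatModel

CLASSIFIER_NAMES = ("LR", "SVM", "RF", "GB")

# Hyperparameter grids, frozen; searched by inner stratified 3-fold CV on AUC.
DEFAULT_GRIDS: dict[str, dict] = {
    "LR": {"clf__C": [0.01, 0.1, 1.0, 10.0]},
    "SVM": {"clf__C": [0.1, 1.0, 10.0], "clf__gamma": ["scale", 0.1, 10.0]},
    "RF": {"clf__n_estimators": [100, 300], "clf__max_depth": [None, 5, 10]},
    "GB": {
        "clf__n_estimators": [100, 300],
        "clf__learning_rate": [0.05, 0.1],
        "clf__max_depth": [2, 3],
    },
}

# Reduced grids for quick runs (single point per model, no search).
FAST_GRIDS: dict[str, dict] = {
    "LR": {"clf__C": [1.0]},
    "SVM": {"clf__C": [1.0], "clf__gamma": ["scale"]},
    "RF": {"clf__n_estimators": [100], "clf__max_depth": [None]},
    "GB": {"clf__n_estimators": [100], "clf__learning_rate": [0.1], "clf__max_depth": [2]},
}


# ----------------------------------------------------------------------
# CV plan


@dataclasses.dataclass
class CVPlan:
    """Case-level fold assignment: stratified by label, grouped by case."""

    k: int
    folds: dict[str, int]  # case_id -> fold
    seed: int

    def fold_of(self, case_ids) -> np.ndarray:
        return np.array([self.folds[c] for c in case_ids])


def make_cv_plan(table: pd.DataFrame, k: int = 10, seed: int = 0) -> CVPlan:
    """Assign each case to one of k folds, stratified by class label.

    ``table`` needs one row per case with ``case_id`` and ``label``
    columns (extra rows per case are collapsed first).  Deterministic
    given the seed.
    """
    cases = table[["case_id", "label"]].drop_duplicates("case_id").reset_index(drop=True)
    counts = cases.label.value_counts()
    if (counts < k).any():
        raise ValueError(
            f"smallest class has {int(counts.min())} cases < k={k}; use a smaller k"
        )
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: dict[str, int] = {}
    for f, (_, test_idx) in enumerate(
        splitter.split(cases.case_id, cases.label, groups=cases.case_id)
    ):
        for i in test_idx:
            folds[cases.case_id.iloc[i]] = f
    return CVPlan(k=k, folds=folds, seed=seed)


# ----------------------------------------------------------------------
# metrics


def auc_mann_whitney(scores, labels) -> float:
    """AUC via the Mann-Whitney U statistic, ties counted 1/2.

    Returns NaN when either class is absent (undefined, not 0).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def binary_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """Sensitivity, specificity, per-class precision/F1 and the confusion matrix."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())

    def _safe(num, den):
        return num / den if den > 0 else float("nan")

    prec_pos = _safe(tp, tp + fp)
    rec_pos = _safe(tp, tp + fn)
    prec_neg = _safe(tn, tn + fn)
    rec_neg = _safe(tn, tn + fp)
    return {
        "threshold": threshold,
        "sensitivity": rec_pos,
        "specificity": rec_neg,
        "precision_malignant": prec_pos,
        "precision_benign": prec_neg,
        "f1_malignant": _safe(2 * prec_pos * rec_pos, prec_pos + rec_pos),
        "f1_benign": _safe(2 * prec_neg * rec_neg, prec_neg + rec_neg),
        "auc": auc_mann_whitney(scores, labels),
        "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    }


def threshold_sweep(
    scores, labels, grid: np.ndarray | None = None, sensitivity_target: float = 1.0
) -> tuple[pd.DataFrame, float]:
    """Metrics over a threshold grid plus the chosen operating point.

    The operating point is the smallest threshold whose sensitivity
    reaches ``sensitivity_target`` (default 1.0, i.e. no missed
    malignancy).
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    rows = []
    for t in grid:
        m = binary_metrics(scores, labels, threshold=float(t))
        m.pop("confusion")
        m.pop("auc")
        rows.append(m)
    sweep = pd.DataFrame(rows)
    ok = sweep[sweep.sensitivity >= sensitivity_target]
    operating = float(ok.threshold.max()) if len(ok) else float(grid[0])
    return sweep, operating


# ----------------------------------------------------------------------
# classifiers


def _make_estimator(name: str, seed: int):
    if name == "LR":
        return Pipeline(
            [("scale", StandardScaler()), ("clf", LogisticRegression(max_iter=5000))]
        )
    if name == "SVM":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", SVC(kernel="rbf", probability=True, random_state=seed)),
            ]
        )
    if name == "RF":
        return Pipeline([("clf", RandomForestClassifier(random_state=seed))])
    if name == "GB":
        return Pipeline([("clf", GradientBoostingClassifier(random_state=seed))])
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


def train_classifier(
    name: str,
    X: np.ndarray,
    y: np.ndarray,
    grid: dict | None = None,
    seed: int = 0,
    inner_k: int = 3,
):
    """Fit one of the four classifiers with inner-CV hyperparameter search.

    LR/SVM get a standardizer learned on the training rows only (it is
    part of the pipeline, so it never sees evaluation rows); RF/GB
    consume raw features.  Returns the fitted estimator exposing
    ``predict_proba``.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training rows contain a single class")
    est = _make_estimator(name, seed)
    grid = DEFAULT_GRIDS[name] if grid is None else grid
    if sum(len(v) for v in grid.values()) > len(grid):  # a real search
        inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
        search = GridSearchCV(est, grid, scoring="roc_auc", cv=inner, n_jobs=1)
        search.fit(X, y)
        return search.best_estimator_
    est.set_params(**{k: v[0] for k, v in grid.items()})
    est.fit(X, y)
    return est


# ----------------------------------------------------------------------
# DeLong and paired tests


def _delong_components(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise ValueError("DeLong needs >= 2 cases per class")
    # psi(x, y) = 1 if x > y, 1/2 if tie, 0 otherwise
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(np.float64) + 0.5 * (diff == 0)
    auc = psi.mean()
    v10 = psi.mean(axis=1)  # per positive case
    v01 = psi.mean(axis=0)  # per negative case
    return auc, v10, v01


def delong_test(scores_a, scores_b, labels) -> dict:
    """Two-sided DeLong test for two correlated AUCs on the same cases.

    Returns a dict with both AUCs, the z statistic, the p value, the
    variance of the AUC difference and a ``degenerate`` flag (p = 1 when
    the paired difference has zero variance, e.g. identical scores).
    """
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        # zero estimated variance of the paired difference: identical
        # rankings give p = 1; different AUCs with no sampling spread in
        # the structural components are maximally significant
        same = abs(auc_a - auc_b) < 1e-12
        return {
            "auc_a": float(auc_a), "auc_b": float(auc_b),
            "z": 0.0 if same else float(np.sign(auc_a - auc_b) * np.inf),
            "p": 1.0 if same else 0.0,
            "var_diff": float(max(var_diff, 0.0)), "degenerate": True,
        }
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return {
        "auc_a": float(auc_a), "auc_b": float(auc_b), "z": float(z), "p": float(p),
        "var_diff": float(var_diff), "degenerate": False,
    }


def delong_variance(scores, labels) -> float:
    """DeLong variance estimate of a single AUC."""
    _, v10, v01 = _delong_components(scores, labels)
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


def paired_tests(preds_a, preds_b, labels) -> dict:
    """McNemar (continuity-corrected) and chi-square on paired predictions.

    McNemar works on the discordant pairs of the correct/incorrect
    cross-table; the chi-square tests independence of the two
    classifiers' correctness.  Both are symmetric in A and B.
    """
    preds_a = np.asarray(preds_a).astype(int)
    preds_b = np.asarray(preds_b).astype(int)
    labels = np.asarray(labels).astype(int)
    ok_a = preds_a == labels
    ok_b = preds_b == labels
    table = np.array(
        [
            [np.sum(ok_a & ok_b), np.sum(ok_a & ~ok_b)],
            [np.sum(~ok_a & ok_b), np.sum(~ok_a & ~ok_b)],
        ]
    )
    b, c = int(table[0, 1]), int(table[1, 0])
    if b + c == 0:
        mcnemar_stat, mcnemar_p, degenerate = 0.0, 1.0, True
    else:
        res = _sm_mcnemar(table, exact=False, correction=True)
        mcnemar_stat, mcnemar_p, degenerate = float(res.statistic), float(res.pvalue), False
    if table.min() == 0 or table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        chi2_stat, chi2_p = float("nan"), float("nan")
        try:
            chi2_stat, chi2_p, _, _ = stats.chi2_contingency(table)
            chi2_stat, chi2_p = float(chi2_stat), float(chi2_p)
        except ValueError:
            pass
    else:
        chi2_stat, chi2_p, _, _ = stats.chi2_contingency(table)
        chi2_stat, chi2_p = float(chi2_stat), float(chi2_p)
    return {
        "mcnemar_statistic": mcnemar_stat,
        "mcnemar_p": mcnemar_p,
        "mcnemar_degenerate": degenerate,
        "chi2_statistic": chi2_stat,
        "chi2_p": chi2_p,
        "contingency": table.tolist(),
    }


# ----------------------------------------------------------------------
# the benchmark grid


def cross_validated_scores(
    table: pd.DataFrame,
    plan: CVPlan,
    classifier: str,
    harmonize: bool = False,
    batch_column: str = "batch",
    grids: dict[str, dict] | None = None,
    seed: int = 0,
    protect: str | None = None,
) -> pd.DataFrame:
    """Out-of-fold malignancy scores for one classifier.

    With ``harmonize=True`` a ComBat model is fit on each training fold
    and applied to both partitions before training/scoring; ``protect``
    optionally names a covariate column (e.g. ``"label"``) used during
    estimation only, which is essential when class and batch are
    confounded.
    """
    feats = [c for c in table.columns if c not in NON_FEATURE_COLUMNS]
    fold = plan.fold_of(table.case_id)
    out = []
    for f in range(plan.k):
        train = table[fold != f]
        test = table[fold == f]
        if harmonize:
            model = ComBatModel.fit(
                train, batch_column=batch_column, feature_columns=feats, protect=protect
            )
            train = model.transform(train, batch_column=batch_column)
            test = model.transform(test, batch_column=batch_column)
        est = train_classifier(
            classifier,
            train[feats].to_numpy(),
            train.label.to_numpy(),
            grid=(grids or DEFAULT_GRIDS)[classifier],
            seed=seed,
        )
        prob = est.predict_proba(test[feats].to_numpy())[:, 1]
        out.append(
            pd.DataFrame(
                {
                    "case_id": test.case_id.to_numpy(),
                    "label": test.label.to_numpy(),
                    "fold": f,
                    "score": prob,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def _per_fold_summary(scores: pd.DataFrame, threshold: float = 0.5) -> dict:
    rows = []
    for f, grp in scores.groupby("fold"):
        m = binary_metrics(grp.score, grp.label, threshold)
        rows.append({"fold": f, "auc": m["auc"], "sensitivity": m["sensitivity"], "specificity": m["specificity"]})
    per_fold = pd.DataFrame(rows)
    agg = {}
    for k in ("auc", "sensitivity", "specificity"):
        vals = per_fold[k].dropna()
        agg[f"{k}_mean"] = float(vals.mean())
        agg[f"{k}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return {"per_fold": per_fold.to_dict("records"), **agg}


def run_benchmark(
    table: pd.DataFrame,
    plan: CVPlan | None = None,
    k: int = 10,
    batch_column: str = "batch",
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES,
    grids: dict[str, dict] | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict:
    """The full 2 x |classifiers| benchmark grid on one feature table.

    Every classifier is run on raw features and on per-fold ComBat
    harmonized features; pairwise raw-vs-corrected DeLong tests and
    paired McNemar/chi-square tests are computed on the pooled
    out-of-fold scores.  Returns a JSON-serializable report.
    """
    plan = plan or make_cv_plan(table, k=k, seed=seed)
    report: dict = {"k": plan.k, "seed": seed, "rows": [], "comparisons": []}
    pooled: dict[tuple[str, str], pd.DataFrame] = {}
    for dataset, harm in (("radiomics", False), ("radiomics_combat", True)):
        for name in classifiers:
            sc = cross_validated_scores(
                table, plan, name, harmonize=harm, batch_column=batch_column,
                grids=grids, seed=seed,
            ).sort_values("case_id", ignore_index=True)
            pooled[(dataset, name)] = sc
            summ = _per_fold_summary(sc, threshold)
            report["rows"].append({"dataset": dataset, "classifier": name, **summ})
    for name in classifiers:
        a = pooled[("radiomics", name)]
        b = pooled[("radiomics_combat", name)]
        dl = delong_test(a.score, b.score, a.label)
        pt = paired_tests(
            (a.score >= threshold).astype(int), (b.score >= threshold).astype(int), a.label
        )
        report["comparisons"].append(
            {"classifier": name, "contrast": "raw_vs_combat", **dl, **pt}
        )
    return report
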