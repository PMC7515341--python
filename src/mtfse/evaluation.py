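"""Group statistics and the repeated cross-validated classification protocol.

Two questions are answered about a feature matrix of MTFSE indices: do the
indices differ between groups (Welch two-sample t-tests, mean +/- SD per
group), and how well do they classify segments (KNN / SVM / decision-tree
classifiers under repeated, subsampled, stratified 10-fold cross-validation
with accuracy / sensitivity / specificity reporting)?

Protocol: per repetition a fixed number of segments is drawn from each group
without replacement, one stratified k-fold pass is run, fold confusion counts
are summed, and Acc/Sen/Spe are computed from the summed counts; reported
values are means over repetitions. Classifiers run at scikit-learn defaults
(only a seed-derived random_state is injected so reports are reproducible).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import confusion_matrix
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .indices import INDEX_NAMES

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "TTestReport",
    "EvalReport",
    "compute_metrics",
    "index_ttests",
    "repeated_cv",
    "CLASSIFIERS",
]

CLASSIFIERS = ("KNN", "SVM", "DT")

#: groups earlier in this list are treated as the positive (diseased) class
#: in binary tasks.
_POSITIVE_PRIORITY = ("A-OSA", "A-N", "apnea-like", "lf-dominant")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; the positive class is the screened condition."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """Accuracy / sensitivity / specificity in percent; None when undefined."""

    acc: float
    sen: float | None
    spe: float | None


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Acc = (TP+TN)/all, Sen = TP/(TP+FN), Spe = TN/(FP+TN), all in percent.

    Sen/Spe with an empty denominator are flagged undefined (None), not zero.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics of zero test samples")
    acc = 100.0 * (c.tp + c.tn) / c.total
    sen = None if c.tp + c.fn == 0 else 100.0 * c.tp / (c.tp + c.fn)
    spe = None if c.fp + c.tn == 0 else 100.0 * c.tn / (c.fp + c.tn)
    return Metrics(acc=acc, sen=sen, spe=spe)


@dataclass(frozen=True)
class TTestReport:
    """Per-group mean/SD of each index plus Welch p-values per group pair."""

    group_stats: pd.DataFrame  # rows = indices, columns = (group, mean|sd)
    pvalues: pd.DataFrame  # rows = indices, columns = "G1 vs G2"; NaN = undefined
    stars: pd.DataFrame  # significance markers: '', '*', '**', '***'


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _index_columns(features: pd.DataFrame) -> list[str]:
    cols = [c for c in INDEX_NAMES if c in features.columns]
    if not cols:
        raise ValueError("feature matrix contains none of the MTFSE index columns")
    return cols


def index_ttests(features: pd.DataFrame, label_col: str = "label") -> TTestReport:
    """Welch two-sample t-tests of every index between every pair of groups.

    Rows with a missing value in an index are dropped for that index only.
    Zero-variance-in-both-groups comparisons yield an undefined p (NaN).
    """
    if label_col not in features.columns:
        raise ValueError(f"missing label column {label_col!r}")
    cols = _index_columns(features)
    groups = sorted(features[label_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups for t-tests")

    stats_frame = pd.DataFrame(
        index=cols,
        columns=pd.MultiIndex.from_product([groups, ["mean", "sd"]]),
        dtype=float,
    )
    pairs = [
        f"{a} vs {b}" for i, a in enumerate(groups) for b in groups[i + 1 :]
    ]
    pvals = pd.DataFrame(index=cols, columns=pairs, dtype=float)

    per_group = {g: features.loc[features[label_col] == g, cols] for g in groups}
    for col in cols:
        samples = {g: per_group[g][col].dropna().to_numpy() for g in groups}
        for g in groups:
            x = samples[g]
            if len(x) < 2:
                raise ValueError(
                    f"group {g!r} has fewer than 2 samples for index {col!r}"
                )
            stats_frame.loc[col, (g, "mean")] = x.mean()
            stats_frame.loc[col, (g, "sd")] = x.std(ddof=1)
        for i, a in enumerate(groups):
            for b in groups[i + 1 :]:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # 0/0 on degenerate input
                    res = stats.ttest_ind(samples[a], samples[b], equal_var=False)
                pvals.loc[col, f"{a} vs {b}"] = (
                    res.pvalue if np.isfinite(res.pvalue) else np.nan
                )
    stars = pvals.map(_stars)
    return TTestReport(group_stats=stats_frame, pvalues=pvals, stars=stars)


def _make_classifier(name: str, random_state: int):
    if name == "KNN":
        return KNeighborsClassifier()
    if name == "SVM":
        return SVC(random_state=random_state)
    if name == "DT":
        return DecisionTreeClassifier(random_state=random_state)
    raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")


@dataclass
class EvalReport:
    """Outcome of repeated cross-validation for one classifier and task."""

    classifier: str
    classifier_params: dict
    groups: list
    task: str  # "binary" | "multiclass"
    positive_label: str | None
    n_per_group: int
    n_repeats: int
    k: int
    seed: int
    n_excluded_missing: int
    acc: float = np.nan
    sen: float | None = None
    spe: float | None = None
    acc_per_rep: np.ndarray = field(default_factory=lambda: np.array([]))
    per_class: dict = field(default_factory=dict)  # class -> {acc, sen, spe}
    macro: dict = field(default_factory=dict)  # mean row of per_class
    rate_table: np.ndarray | None = None  # row-normalized % rates, rows=true class

    def to_dict(self) -> dict:
        out = {
            "classifier": self.classifier,
            "classifier_params": {
                k: repr(v) for k, v in sorted(self.classifier_params.items())
            },
            "groups": list(self.groups),
            "task": self.task,
            "positive_label": self.positive_label,
            "n_per_group": self.n_per_group,
            "n_repeats": self.n_repeats,
            "k": self.k,
            "seed": self.seed,
            "n_excluded_missing": self.n_excluded_missing,
            "acc": self.acc,
            "sen": self.sen,
            "spe": self.spe,
            "per_class": self.per_class,
            "macro": self.macro,
        }
        if self.rate_table is not None:
            out["rate_table"] = self.rate_table.tolist()
        return out


def _choose_positive(groups: list[str]) -> str:
    for g in _POSITIVE_PRIORITY:
        if g in groups:
            return g
    return groups[0]


def repeated_cv(
    features: pd.DataFrame,
    classifier: str,
    n_per_group: int = 300,
    n_repeats: int = 500,
    k: int = 10,
    seed: int = 0,
    label_col: str = "label",
    positive_label: str | None = None,
) -> EvalReport:
    """Repeated, subsampled, stratified k-fold cross-validation.

    Each repetition draws ``n_per_group`` rows per group without replacement
    (reduced to the smallest group size with a warning if a group is smaller),
    runs one stratified k-fold pass, sums the fold confusion counts and scores
    them; reported metrics are means over repetitions. For more than two
    groups, sensitivity/specificity are one-vs-rest per class with a macro
    "mean" row, plus the row-normalized classification-rate table.
    """
    if label_col not in features.columns:
        raise ValueError(f"missing label column {label_col!r}")
    cols = _index_columns(features)
    clean = features.dropna(subset=cols)
    n_excluded = len(features) - len(clean)
    groups = sorted(clean[label_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups for classification")

    counts = clean[label_col].value_counts()
    n_sub = min(n_per_group, int(counts.min()))
    if n_sub < n_per_group:
        warnings.warn(
            f"subsample size reduced from {n_per_group} to {n_sub} "
            f"(smallest group: {counts.idxmin()!r})",
            stacklevel=2,
        )
    if n_sub < k:
        raise ValueError(f"subsample of {n_sub} per group cannot fill {k} folds")

    task = "binary" if len(groups) == 2 else "multiclass"
    pos = None
    if task == "binary":
        pos = positive_label if positive_label is not None else _choose_positive(groups)
        if pos not in groups:
            raise ValueError(f"positive_label {pos!r} not among groups {groups}")

    X_all = clean[cols].to_numpy(dtype=float)
    y_all = clean[label_col].to_numpy()
    group_idx = {g: np.flatnonzero(y_all == g) for g in groups}

    rng = np.random.default_rng(seed)
    report = EvalReport(
        classifier=classifier,
        classifier_params=_make_classifier(classifier, 0).get_params(),
        groups=groups,
        task=task,
        positive_label=pos,
        n_per_group=n_sub,
        n_repeats=n_repeats,
        k=k,
        seed=seed,
        n_excluded_missing=n_excluded,
    )

    accs = np.empty(n_repeats)
    if task == "binary":
        sens = np.empty(n_repeats)
        spes = np.empty(n_repeats)
    else:
        cls_acc = np.empty((n_repeats, len(groups)))
        cls_sen = np.empty((n_repeats, len(groups)))
        cls_spe = np.empty((n_repeats, len(groups)))
        tables = np.empty((n_repeats, len(groups), len(groups)))

    for rep in range(n_repeats):
        rep_rs = int(rng.integers(0, 2**31 - 1))
        pick = np.concatenate(
            [rng.choice(group_idx[g], size=n_sub, replace=False) for g in groups]
        )
        X, y = X_all[pick], y_all[pick]
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_rs)
        cm = np.zeros((len(groups), len(groups)), dtype=int)
        for train, test in skf.split(X, y):
            clf = _make_classifier(classifier, rep_rs)
            clf.fit(X[train], y[train])
            pred = clf.predict(X[test])
            cm += confusion_matrix(y[test], pred, labels=groups)
        if cm.sum() != len(groups) * n_sub:
            raise AssertionError("fold confusion counts do not cover the subsample")

        if task == "binary":
            p = groups.index(pos)
            n = 1 - p
            m = compute_metrics(
                ConfusionCounts(tp=cm[p, p], fp=cm[n, p], tn=cm[n, n], fn=cm[p, n])
            )
            accs[rep], sens[rep], spes[rep] = m.acc, m.sen, m.spe
        else:
            accs[rep] = 100.0 * np.trace(cm) / cm.sum()
            for ci in range(len(groups)):
                tp = cm[ci, ci]
                fn = cm[ci].sum() - tp
                fp = cm[:, ci].sum() - tp
                tn = cm.sum() - tp - fn - fp
                m = compute_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
                cls_acc[rep, ci] = m.acc
                cls_sen[rep, ci] = m.sen
                cls_spe[rep, ci] = m.spe
            tables[rep] = 100.0 * cm / cm.sum(axis=1, keepdims=True)

    report.acc_per_rep = accs
    report.acc = float(accs.mean())
    if task == "binary":
        report.sen = float(sens.mean())
        report.spe = float(spes.mean())
    else:
        report.per_class = {
            g: {
                "acc": float(cls_acc[:, ci].mean()),
                "sen": float(cls_sen[:, ci].mean()),
                "spe": float(cls_spe[:, ci].mean()),
            }
            for ci, g in enumerate(groups)
        }
        report.macro = {
            "acc": float(cls_acc.mean()),
            "sen": float(cls_sen.mean()),
            "spe": float(cls_spe.mean()),
        }
        report.sen = report.macro["sen"]
        report.spe = report.macro["spe"]
        report.rate_table = tables.mean(axis=0)
    return report
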