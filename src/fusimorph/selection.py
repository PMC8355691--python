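"""Two-stage consensus feature selection for small cohorts.

Stage one screens the 382 features with per-feature two-sample t-tests,
keeping those with p <= 0.1 (Welch's test by default; the pooled-variance
variant is available).  Stage two runs four selection methods — largest
|t| (SelectKBest-style), and recursive feature elimination wrapped around a
linear SVM, an L2 logistic regression, and a random forest — each selecting
five features, repeated 30 times on stratified 80% subsamples of the
screened matrix.  How often each feature is selected by each method is
tabulated, and two consensus sets are derived: the union of each method's
two most frequent features, and the set of features selected at least
two-thirds of the time by at least one method.

Screening runs once on the full data; only the selection repetitions see
subsamples.  Subsampling is stratified by outcome because an unstratified
80% draw of a 12-vs-25 cohort can lose most of the minority class.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

__all__ = [
    "SelectionConfig",
    "FrequencyTable",
    "ttest_screen",
    "select_kbest",
    "rfe",
    "repeated_selection",
    "consensus_sets",
]

METHODS = ("kbest_t", "rfe_svm", "rfe_lr", "rfe_rf")
POSITIVE_LABEL = "ruptured"


@dataclass
class SelectionConfig:
    alpha: float = 0.1  # screening p-value cutoff
    k: int = 5  # features selected per run; capped at 5 for n=37
    reps: int = 30
    subsample_frac: float = 0.8
    methods: tuple = METHODS
    seed: int = 0
    equal_var: bool = False  # False = Welch's t-test
    standardize: bool = True  # scale features before the linear RFE estimators

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.k > 5:
            raise ValueError("feature set size is capped at 5 for this cohort size")


@dataclass
class FrequencyTable:
    """Per-method selection counts over the repetitions."""

    counts: dict  # method -> {feature name -> count}
    reps: int
    screened: list  # feature names that survived screening, in matrix order

    def to_frame(self, top: int | None = None) -> pd.DataFrame:
        """Rank table mirroring the frequency-table layout: per method,
        alternating feature and count columns."""
        cols = {}
        depth = top or max((len(c) for c in self.counts.values()), default=0)
        for method, counter in self.counts.items():
            ranked = self._ranked(method)[:depth]
            names = [n for n, _ in ranked] + [""] * (depth - len(ranked))
            freqs = [c for _, c in ranked] + [np.nan] * (depth - len(ranked))
            cols[f"{method}_feature"] = names
            cols[f"{method}_freq"] = freqs
        frame = pd.DataFrame(cols)
        frame.insert(0, "rank", np.arange(1, depth + 1))
        return frame

    def _ranked(self, method: str) -> list:
        order = {name: i for i, name in enumerate(self.screened)}
        counter = self.counts[method]
        return sorted(counter.items(), key=lambda kv: (-kv[1], order.get(kv[0], 1 << 30)))

    def top(self, method: str, n: int = 2, include_ties: bool = True) -> list:
        """The ``n`` most frequent features; ties at the cut are all kept."""
        ranked = self._ranked(method)
        if len(ranked) <= n:
            return [name for name, _ in ranked]
        cut = ranked[n - 1][1]
        if not include_ties:
            return [name for name, _ in ranked[:n]]
        out = [name for name, count in ranked if count >= cut]
        if len(out) > n:
            warnings.warn(
                f"{method}: {len(out) - n} tie(s) at rank {n} included", stacklevel=2
            )
        return out


def _binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    return (y == POSITIVE_LABEL).astype(int)


def _tstats(X: np.ndarray, y01: np.ndarray, equal_var: bool) -> tuple[np.ndarray, np.ndarray]:
    res = stats.ttest_ind(X[y01 == 1], X[y01 == 0], equal_var=equal_var, axis=0)
    return np.asarray(res.statistic), np.asarray(res.pvalue)


def ttest_screen(
    matrix: pd.DataFrame,
    labels,
    alpha: float = 0.1,
    equal_var: bool = False,
) -> list:
    """Feature names with two-sample t-test p <= alpha.

    ``matrix`` holds feature columns only (no identifier/label).  Features
    that are constant within both classes, or contain missing values, are
    excluded with a warning before testing.
    """
    y = _binary(labels)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both outcome classes must be present")
    usable = []
    for name in matrix.columns:
        col = matrix[name].to_numpy(dtype=float)
        if np.any(~np.isfinite(col)):
            warnings.warn(f"feature {name} has missing values; excluded", stacklevel=2)
            continue
        scale = max(abs(np.mean(col)), 1.0)
        if col[y == 1].std(ddof=1) <= 1e-9 * scale and col[y == 0].std(ddof=1) <= 1e-9 * scale:
            warnings.warn(f"feature {name} is constant in both classes; excluded", stacklevel=2)
            continue
        usable.append(name)
    X = matrix[usable].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = _tstats(X, y, equal_var)
    keep = np.nan_to_num(pvals, nan=1.0) <= alpha
    return [name for name, k in zip(usable, keep) if k]


def select_kbest(matrix: pd.DataFrame, labels, k: int, equal_var: bool = False) -> list:
    """The k features with the largest |t| (smallest p); ties break by column order."""
    y = _binary(labels)
    X = matrix.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, _ = _tstats(X, y, equal_var)
    t = np.nan_to_num(t, nan=0.0)
    order = np.lexsort((np.arange(X.shape[1]), -np.abs(t)))
    chosen = sorted(order[:k])
    return [matrix.columns[i] for i in chosen]


def _make_estimator(kind: str, seed: int):
    if kind == "linear_svm":
        return SVC(kernel="linear")
    if kind == "logreg_l2":
        return LogisticRegression(solver="liblinear")  # L2 penalty is the default
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed)
    raise ValueError(f"unknown RFE estimator {kind!r}")


def rfe(
    matrix: pd.DataFrame,
    labels,
    estimator: str,
    k: int,
    seed: int = 0,
    standardize: bool = True,
) -> list:
    """Recursive feature elimination down to ``k`` features.

    One feature is dropped per iteration — the one with the smallest
    |coefficient| for the linear estimators, or the smallest impurity
    importance for the random forest.  Linear estimators see standardized
    features (zero mean, unit variance of the data passed in).
    """
    y = _binary(labels)
    X = matrix.to_numpy(dtype=float)
    if estimator != "random_forest" and standardize:
        sd = X.std(axis=0)
        sd[sd == 0.0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    selector = RFE(_make_estimator(estimator, seed), n_features_to_select=k, step=1)
    selector.fit(X, y)
    return [name for name, keep in zip(matrix.columns, selector.support_) if keep]


_METHOD_ESTIMATOR = {"rfe_svm": "linear_svm", "rfe_lr": "logreg_l2", "rfe_rf": "random_forest"}


def _stratified_subsample(y01: np.ndarray, frac: float, rng) -> np.ndarray:
    idx = []
    for cls in (0, 1):
        members = np.flatnonzero(y01 == cls)
        take = max(2, int(round(frac * len(members))))
        idx.append(rng.choice(members, size=min(take, len(members)), replace=False))
    return np.sort(np.concatenate(idx))


def repeated_selection(
    matrix: pd.DataFrame,
    labels,
    config: SelectionConfig | None = None,
) -> FrequencyTable:
    """Screen once, then tabulate selections over repeated 80% subsamples.

    Each repetition draws one stratified subsample shared by all methods,
    so the methods are compared on identical data.  A repetition in which
    an estimator fails to converge is excluded from that method's counts
    with a warning.
    """
    config = config or SelectionConfig()
    labels = np.asarray(labels)
    screened = ttest_screen(matrix, labels, config.alpha, config.equal_var)
    if len(screened) < config.k:
        raise ValueError(
            f"only {len(screened)} features survive screening; need >= k={config.k}"
        )
    sub = matrix[screened]
    y01 = _binary(labels)
    rng = np.random.default_rng(config.seed)

    counts = {m: {} for m in config.methods}
    for rep in range(config.reps):
        rows = _stratified_subsample(y01, config.subsample_frac, rng)
        Xr = sub.iloc[rows]
        yr = labels[rows]
        rep_seed = int(rng.integers(2**31))
        for method in config.methods:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("error", ConvergenceWarning)
                    if method == "kbest_t":
                        chosen = select_kbest(Xr, yr, config.k, config.equal_var)
                    else:
                        chosen = rfe(
                            Xr,
                            yr,
                            _METHOD_ESTIMATOR[method],
                            config.k,
                            seed=rep_seed,
                            standardize=config.standardize,
                        )
            except Exception as exc:
                warnings.warn(
                    f"{method} failed on repetition {rep}: {exc}; run excluded",
                    stacklevel=2,
                )
                continue
            for name in chosen:
                counts[method][name] = counts[method].get(name, 0) + 1
    return FrequencyTable(counts=counts, reps=config.reps, screened=screened)


def consensus_sets(table: FrequencyTable, frequent_fraction: float = 2.0 / 3.0) -> dict:
    """Consensus feature sets from the frequency table.

    ``top2_union`` is the union of each method's two most frequent features
    (rank-2 ties are all included); ``frequent`` holds the features
    selected at least ``ceil(frequent_fraction * reps)`` times by at least
    one method (20 of 30 at the default settings).
    """
    top2 = set()
    for method in table.counts:
        top2.update(table.top(method, n=2))
    cutoff = int(np.ceil(frequent_fraction * table.reps))
    frequent = {
        name
        for counter in table.counts.values()
        for name, count in counter.items()
        if count >= cutoff
    }
    return {"top2_union": top2, "frequent": frequent}
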