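"""Balancing, double cross-validation, classifiers, and performance measures.

MT is the positive class throughout.  KNN (Tanimoto distance, majority
vote) and the Tanimoto kernel are implemented here; RF and SVM solvers
are delegated to scikit-learn under the fixed hyperparameter grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from promidiag.chem_similarity import MT, ST, Fingerprint, pack_fingerprints, tanimoto_matrix
from promidiag.errors import ConfigError
from promidiag.group_sampling import MTGroup

KNN = "KNN"
RF = "RF"
SVM = "SVM"
MODELS = (KNN, RF, SVM)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVProtocol:
    """Double cross-validation protocol (external and internal splits)."""

    n_external_trials: int = 10
    test_fraction: float = 0.2
    n_internal_trials: int = 10
    internal_test_fraction: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("test_fraction", "internal_test_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.n_external_trials < 1 or self.n_internal_trials < 1:
            raise ConfigError("trial counts must be >= 1")


@dataclass(frozen=True)
class KNNConfig:
    k_grid: Tuple[int, ...] = (1, 3, 5)

    def __post_init__(self) -> None:
        if not self.k_grid:
            raise ConfigError("k_grid must be non-empty")
        if any(k < 1 or k % 2 == 0 for k in self.k_grid):
            raise ConfigError(f"all k must be odd and positive, got {self.k_grid}")


@dataclass(frozen=True)
class RFConfig:
    n_estimators_grid: Tuple[int, ...] = (10, 100, 250, 500)
    min_samples_split_grid: Tuple[int, ...] = (2, 3, 5, 7, 10)

    def __post_init__(self) -> None:
        if not self.n_estimators_grid or not self.min_samples_split_grid:
            raise ConfigError("RF grids must be non-empty")


@dataclass(frozen=True)
class SVMConfig:
    c_grid: Tuple[float, ...] = (0.1, 1, 10, 50, 100, 200, 400, 500, 750, 1000)
    kernels: Tuple[str, ...] = ("linear", "tanimoto")

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.c_grid):
            raise ConfigError(f"all C must be > 0, got {self.c_grid}")
        unknown = set(self.kernels) - {"linear", "tanimoto"}
        if unknown:
            raise ConfigError(f"unknown kernels: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# performance measures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def tnr(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclass(frozen=True)
class MetricSet:
    ba: float
    f1: float
    mcc: float
    precision: float
    recall: float
    auc: Optional[float] = None


@dataclass(frozen=True)
class TrialResult:
    trial: int
    model: str
    params: Dict[str, object]
    confusion: ConfusionCounts
    metrics: MetricSet


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> ConfusionCounts:
    """2x2 counts with MT as the positive class."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors must have equal length")
    tp = tn = fp = fn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t not in (MT, ST) or p not in (MT, ST):
            raise ValueError(f"labels must be {MT!r} or {ST!r}, got ({t!r}, {p!r})")
        if t == MT:
            if p == MT:
                tp += 1
            else:
                fn += 1
        else:
            if p == MT:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(cc: ConfusionCounts, auc: Optional[float] = None) -> MetricSet:
    """Balanced accuracy, MCC, F1, precision, recall from a confusion table.

    MCC follows the convention of returning 0 when any marginal of the
    table is zero (undefined denominator).  BA requires both true classes
    to be present.
    """
    if cc.n == 0:
        raise ValueError("empty confusion table")
    if cc.tp + cc.fn == 0 or cc.tn + cc.fp == 0:
        raise ValueError("both true classes must be present to compute BA")
    ba = 0.5 * (cc.tpr + cc.tnr)
    f1 = 2 * cc.tp / (2 * cc.tp + cc.fp + cc.fn) if (2 * cc.tp + cc.fp + cc.fn) > 0 else 0.0
    precision = cc.tp / (cc.tp + cc.fp) if (cc.tp + cc.fp) > 0 else 0.0
    recall = cc.tp / (cc.tp + cc.fn)
    denom = (
        (cc.tp + cc.fp) * (cc.tp + cc.fn) * (cc.tn + cc.fp) * (cc.tn + cc.fn)
    )
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (cc.tp * cc.tn - cc.fp * cc.fn) / math.sqrt(denom)
    return MetricSet(ba=ba, f1=f1, mcc=mcc, precision=precision, recall=recall, auc=auc)


def roc_auc(true_labels: Sequence[str], scores: Sequence[float]) -> float:
    """Area under the ROC curve via the rank statistic with midrank ties."""
    y = np.array([1 if t == MT else 0 for t in true_labels])
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("labels and scores must have equal length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(s)  # midranks for ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def balance_groups(groups: Sequence[MTGroup], rng: np.random.Generator) -> List[Tuple[str, str]]:
    """Draw exactly one ST-CPD uniformly per group, yielding balanced MT/ST pairs."""
    pairs: List[Tuple[str, str]] = []
    for g in groups:
        sts = sorted(set(g.st_by_target.values()))
        pairs.append((g.mt, sts[int(rng.integers(len(sts)))]))
    return pairs


def split_pairs(
    pairs: Sequence[Tuple[str, str]], test_fraction: float, rng: np.random.Generator
) -> Tuple[List[Tuple[str, str]], List[Tuple[str, str]]]:
    """Pair-level train/test split: both members of a pair stay together."""
    n = len(pairs)
    n_test = int(np.floor(test_fraction * n))
    if n_test == 0 or n_test == n:
        raise ValueError(f"cannot split {n} pairs with test_fraction {test_fraction}")
    perm = rng.permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train = [p for i, p in enumerate(pairs) if i not in test_idx]
    test = [p for i, p in enumerate(pairs) if i in test_idx]
    return train, test


def tanimoto_kernel(a: Sequence[Fingerprint], b: Sequence[Fingerprint]) -> np.ndarray:
    """Gram matrix of pairwise Tanimoto similarities between two fingerprint lists."""
    lengths = {fp.n_bits for fp in a} | {fp.n_bits for fp in b}
    if len(lengths) > 1:
        raise ValueError(f"fingerprint length mismatch: {sorted(lengths)}")
    x = np.stack([fp.bits for fp in a])
    y = np.stack([fp.bits for fp in b])
    return tanimoto_matrix(x, y)


def knn_classify(
    train_fps: Sequence[Fingerprint],
    train_labels: Sequence[str],
    test_fp: Fingerprint,
    k: int,
    train_ids: Optional[Sequence[str]] = None,
) -> Tuple[str, float]:
    """Majority vote among the k nearest training compounds by Tanimoto distance.

    Returns ``(label, score)`` where score is the MT fraction among the k
    neighbors.  Distance ties break by lexicographic compound identifier
    (or by training index when no identifiers are given).
    """
    n = len(train_fps)
    if k > n:
        raise ValueError(f"k={k} exceeds training-set size {n}")
    if train_ids is None:
        train_ids = [f"{i:09d}" for i in range(n)]
    sims = tanimoto_matrix(test_fp.bits[None, :], np.stack([fp.bits for fp in train_fps]))[0]
    order = sorted(range(n), key=lambda i: (1.0 - sims[i], train_ids[i]))
    top = order[:k]
    mt_fraction = sum(1 for i in top if train_labels[i] == MT) / k
    return (MT if mt_fraction > 0.5 else ST), mt_fraction


# ---------------------------------------------------------------------------
# model wrappers (shared precomputed bit matrix / gram slices)
# ---------------------------------------------------------------------------


class _Workspace:
    """Bit matrix and (lazy) full Tanimoto gram over all compounds in a run."""

    def __init__(self, ids: Sequence[str], fingerprints: Mapping[str, Fingerprint]):
        self.ids = list(ids)
        self.index = {c: i for i, c in enumerate(self.ids)}
        self.x = pack_fingerprints(fingerprints, self.ids).astype(np.float64)
        self._gram: Optional[np.ndarray] = None

    @property
    def gram(self) -> np.ndarray:
        if self._gram is None:
            self._gram = tanimoto_matrix(self.x, self.x)
        return self._gram

    def rows(self, compounds: Sequence[str]) -> np.ndarray:
        return np.array([self.index[c] for c in compounds])


def _knn_predict(
    ws: _Workspace, train: Sequence[str], labels: Sequence[str], test: Sequence[str], k: int
) -> Tuple[List[str], np.ndarray]:
    tr = ws.rows(train)
    te = ws.rows(test)
    sim = ws.gram[np.ix_(te, tr)]
    labels = np.asarray(labels)
    train_keys = np.array(train)
    preds: List[str] = []
    scores = np.empty(len(test))
    for i in range(len(test)):
        order = sorted(range(len(train)), key=lambda j: (1.0 - sim[i, j], train_keys[j]))
        top = order[:k]
        frac = float(np.sum(labels[top] == MT)) / k
        scores[i] = frac
        preds.append(MT if frac > 0.5 else ST)
    return preds, scores


def _fit_predict(
    model: str,
    params: Dict[str, object],
    ws: _Workspace,
    train: Sequence[str],
    train_labels: Sequence[str],
    test: Sequence[str],
    rng_seed: int,
) -> Tuple[List[str], np.ndarray]:
    """Fit one configured model and return test predictions and ranking scores."""
    if model == KNN:
        return _knn_predict(ws, train, train_labels, test, int(params["k"]))

    tr = ws.rows(train)
    te = ws.rows(test)
    y = np.array([1 if l == MT else 0 for l in train_labels])

    if model == RF:
        from sklearn.ensemble import RandomForestClassifier

        clf = RandomForestClassifier(
            n_estimators=int(params["n_estimators"]),
            min_samples_split=int(params["min_samples_split"]),
            random_state=rng_seed,
            n_jobs=1,
        )
        clf.fit(ws.x[tr], y)
        proba = clf.predict_proba(ws.x[te])[:, list(clf.classes_).index(1)]
        preds = [MT if p > 0.5 else ST for p in proba]
        return preds, proba

    if model == SVM:
        from sklearn.svm import SVC

        if params["kernel"] == "tanimoto":
            clf = SVC(C=float(params["C"]), kernel="precomputed")
            clf.fit(ws.gram[np.ix_(tr, tr)], y)
            scores = clf.decision_function(ws.gram[np.ix_(te, tr)])
        else:
            clf = SVC(C=float(params["C"]), kernel="linear")
            clf.fit(ws.x[tr], y)
            scores = clf.decision_function(ws.x[te])
        preds = [MT if s > 0 else ST for s in scores]
        return preds, np.asarray(scores)

    raise ValueError(f"unknown model {model!r}")


def _grid(model: str, knn: KNNConfig, rf: RFConfig, svm: SVMConfig) -> List[Dict[str, object]]:
    """Hyperparameter grid in parsimony order (ties resolve to the earlier point)."""
    if model == KNN:
        return [{"k": k} for k in sorted(knn.k_grid)]
    if model == RF:
        return [
            {"n_estimators": n, "min_samples_split": m}
            for n in sorted(rf.n_estimators_grid)
            for m in sorted(rf.min_samples_split_grid)
        ]
    if model == SVM:
        return [
            {"C": c, "kernel": kern}
            for c in sorted(svm.c_grid)
            for kern in svm.kernels
        ]
    raise ValueError(f"unknown model {model!r}")


def _pairs_to_instances(pairs: Sequence[Tuple[str, str]]) -> Tuple[List[str], List[str]]:
    ids = [c for pair in pairs for c in pair]
    labels = [lab for _ in pairs for lab in (MT, ST)]
    return ids, labels


def run_double_cv(
    groups: Sequence[MTGroup],
    model: str,
    fingerprints: Mapping[str, Fingerprint],
    protocol: CVProtocol = CVProtocol(),
    knn_config: KNNConfig = KNNConfig(),
    rf_config: RFConfig = RFConfig(),
    svm_config: SVMConfig = SVMConfig(),
) -> List[TrialResult]:
    """Double cross-validation over balanced MT/ST pairs.

    Each external trial re-balances the groups (one ST per group), splits
    pairs into train/test, runs the internal loop (repeated sub-splits of
    the training pairs) to pick the grid point with the best mean internal
    BA, refits on the full training pairs, and scores the test pairs.
    Sub-seeds are derived from the protocol seed and trial indices so
    trials are independent yet reproducible.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    if len(groups) < 10:
        raise ValueError(f"need >= 10 groups for double CV, got {len(groups)}")

    all_ids = sorted({c for g in groups for c in g.members})
    ws = _Workspace(all_ids, fingerprints)
    grid = _grid(model, knn_config, rf_config, svm_config)

    results: List[TrialResult] = []
    for trial in range(protocol.n_external_trials):
        rng = np.random.default_rng([protocol.rng_seed, trial])
        pairs = balance_groups(groups, rng)
        train_pairs, test_pairs = split_pairs(pairs, protocol.test_fraction, rng)

        # internal loop: mean BA per grid point over repeated sub-splits
        mean_ba = np.zeros(len(grid))
        n_ok = np.zeros(len(grid))
        for inner in range(protocol.n_internal_trials):
            irng = np.random.default_rng([protocol.rng_seed, trial, inner])
            itrain, itest = split_pairs(train_pairs, protocol.internal_test_fraction, irng)
            itrain_ids, itrain_labels = _pairs_to_instances(itrain)
            itest_ids, itest_labels = _pairs_to_instances(itest)
            for gi, params in enumerate(grid):
                if model == KNN and int(params["k"]) > len(itrain_ids):
                    continue
                preds, _ = _fit_predict(
                    model, params, ws, itrain_ids, itrain_labels, itest_ids,
                    rng_seed=protocol.rng_seed + 7919 * trial + inner,
                )
                cc = confusion(itest_labels, preds)
                mean_ba[gi] += compute_metrics(cc).ba
                n_ok[gi] += 1
        with np.errstate(invalid="ignore"):
            mean_ba = np.where(n_ok > 0, mean_ba / np.maximum(n_ok, 1), -np.inf)
        best = int(np.argmax(mean_ba))  # argmax takes the first (most parsimonious) maximum
        params = grid[best]

        train_ids, train_labels = _pairs_to_instances(train_pairs)
        test_ids, test_labels = _pairs_to_instances(test_pairs)
        try:
            preds, scores = _fit_predict(
                model, params, ws, train_ids, train_labels, test_ids,
                rng_seed=protocol.rng_seed + 104729 * trial,
            )
            cc = confusion(test_labels, preds)
            auc = roc_auc(test_labels, scores)
            metrics = compute_metrics(cc, auc=auc)
        except ValueError:
            # degenerate trial (single-class partition): recorded and skipped;
            # unreachable under pair-level splits but guarded per contract
            continue
        results.append(
            TrialResult(trial=trial, model=model, params=dict(params), confusion=cc, metrics=metrics)
        )
    return results


def mean_ba(results: Sequence[TrialResult]) -> float:
    return float(np.mean([r.metrics.ba for r in results]))


def summarize_trials(results: Sequence[TrialResult]) -> Dict[str, Tuple[float, float]]:
    """Mean and sd per measure over trials."""
    out: Dict[str, Tuple[float, float]] = {}
    for name in ("ba", "f1", "mcc", "precision", "recall", "auc"):
        vals = [getattr(r.metrics, name) for r in results]
        if any(v is None for v in vals):
            continue
        arr = np.asarray(vals, dtype=float)
        out[name] = (float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0)
    return out


def write_trial_results(results: Sequence[TrialResult], path, condition: str = "FULL") -> None:
    """Per-trial results TSV: model, condition, trial, hyperparameters, counts, measures."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(
            "model\tcondition\ttrial\tparams\tTP\tTN\tFP\tFN\tBA\tF1\tMCC\tprecision\trecall\tAUC\n"
        )
        for r in results:
            params = ";".join(f"{k}={v}" for k, v in sorted(r.params.items()))
            auc = "" if r.metrics.auc is None else f"{r.metrics.auc:.6f}"
            fh.write(
                f"{r.model}\t{condition}\t{r.trial}\t{params}\t"
                f"{r.confusion.tp}\t{r.confusion.tn}\t{r.confusion.fp}\t{r.confusion.fn}\t"
                f"{r.metrics.ba:.6f}\t{r.metrics.f1:.6f}\t{r.metrics.mcc:.6f}\t"
                f"{r.metrics.precision:.6f}\t{r.metrics.recall:.6f}\t{auc}\n"
            )


def roc_points(true_labels: Sequence[str], scores: Sequence[float]) -> List[Tuple[float, float]]:
    """ROC curve vertices (FPR, TPR) for export; thresholds descending."""
    from sklearn.metrics import roc_curve

    y = [1 if t == MT else 0 for t in true_labels]
    fpr, tpr, _ = roc_curve(y, scores)
    return list(zip(fpr.tolist(), tpr.tolist()))


def write_roc_points(points: Sequence[Tuple[float, float]], path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in points:
            fh.write(f"{fpr:.6f}\t{tpr:.6f}\n")
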