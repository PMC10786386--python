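"""Referral-point prediction from dynamic clinical interaction networks.

For each referred patient a cumulative network state is built interaction by
interaction, up to and including the interaction that precipitated the
referral.  Each state is flattened to a binary vector

    X_{p,t} = [v_1 .. v_n | a_{i,j} for i < j]

of node-presence bits followed by upper-triangle edge bits, indexed against
the full interaction network's node ordering.  The referral state is labeled
1, all earlier states 0.  A Bernoulli naive Bayes classifier with Laplace
smoothing (alpha = 1) is fit on these vectors; performance is measured by
balanced accuracy over many patient-grouped 80:20 train/test resamples with
random minority oversampling in each training split, and feature relevance
by permutation importance (drop in test balanced accuracy when one feature
column is permuted within the test partition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .eventlog import EventLog
from .netbuild import build_interaction_network, edges_from_interaction

__all__ = [
    "LabeledStateDataset",
    "BernoulliNBModel",
    "ImportanceReport",
    "state_feature_names",
    "vectorize_state",
    "build_dynamic_states",
    "fit_bernoulli_nb",
    "balanced_accuracy",
    "oversample_minority",
    "grouped_resample_splits",
    "permutation_importance",
]

DEFAULT_REFERRAL_ACTION = "Referral to Emergency Psychiatry"


def state_feature_names(node_order: Sequence[str]) -> tuple[str, ...]:
    """Node names followed by ``a|b`` edge names in upper-triangle order."""
    nodes = tuple(node_order)
    return nodes + tuple(f"{a}|{b}" for a, b in combinations(nodes, 2))


def vectorize_state(
    nodes: set[str], edges: set[tuple[str, str]], node_order: Sequence[str]
) -> np.ndarray:
    """Flatten one network state to its binary feature vector (uint8).

    Layout: n node-presence bits, then n(n-1)/2 upper-triangle edge bits in
    row-major (i < j) order of ``node_order``.
    """
    order = list(node_order)
    index = {v: i for i, v in enumerate(order)}
    n = len(order)
    vec = np.zeros(n + n * (n - 1) // 2, dtype=np.uint8)
    for v in nodes:
        vec[index[v]] = 1
    # offset of row i in the flattened upper triangle
    offsets = np.concatenate(([0], np.cumsum(np.arange(n - 1, 0, -1))))
    for a, b in edges:
        i, j = sorted((index[a], index[b]))
        vec[n + offsets[i] + (j - i - 1)] = 1
    return vec


@dataclass
class LabeledStateDataset:
    """Binary state vectors X, labels y, and the patient grouping vector.

    Exactly one positive label per referred patient (the state at the
    precipitating interaction); no states beyond the referral point.
    """

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    node_order: tuple[str, ...]
    feature_names: tuple[str, ...] = field(repr=False)

    @property
    def n_states(self) -> int:
        return len(self.y)

    @property
    def n_patients(self) -> int:
        return len(np.unique(self.groups))


def build_dynamic_states(
    log: EventLog,
    referral_action: str = DEFAULT_REFERRAL_ACTION,
    node_order: Sequence[str] | None = None,
) -> LabeledStateDataset:
    """Cumulative pre-referral network states for every referred patient.

    One state per interaction from the first through the one carrying
    ``referral_action``; interactions after the referral are discarded, and
    patients without a referral are excluded with a notice.  ``node_order``
    defaults to the sorted node set of the full interaction network of
    ``log`` (the state vectors index against that universe).
    """
    if node_order is None:
        node_order = sorted(build_interaction_network(log).nodes())
    node_order = tuple(node_order)
    universe = set(node_order)
    catalog = log.catalog

    X_rows, y_rows, group_rows = [], [], []
    skipped = []
    for pid in log.patients:
        recs = log.records_for(pid)
        referral_at = next(
            (t for t, r in enumerate(recs) if r.action == referral_action), None
        )
        if referral_at is None:
            skipped.append(pid)
            continue
        nodes: set[str] = set()
        edges: set[tuple[str, str]] = set()
        for t, rec in enumerate(recs[: referral_at + 1]):
            mentioned = set(rec.agents) | set(rec.info_systems)
            if not mentioned <= universe:
                raise ValueError(
                    f"patient {pid}: state mentions nodes outside the network universe: "
                    f"{sorted(mentioned - universe)}"
                )
            nodes |= mentioned
            edges |= edges_from_interaction(rec, catalog)
            X_rows.append(vectorize_state(nodes, edges, node_order))
            y_rows.append(1 if t == referral_at else 0)
            group_rows.append(pid)
    if skipped:
        warnings.warn(
            f"excluded {len(skipped)} patients without a {referral_action!r} event"
        )
    if not X_rows:
        raise ValueError("no referred patients in the log")
    return LabeledStateDataset(
        X=np.array(X_rows, dtype=np.uint8),
        y=np.array(y_rows, dtype=np.int8),
        groups=np.array(group_rows, dtype=object),
        node_order=node_order,
        feature_names=state_feature_names(node_order),
    )


@dataclass
class BernoulliNBModel:
    """Bernoulli naive Bayes with Laplace smoothing.

    ``feature_prob[c, f] = (count_{c,f} + alpha) / (n_c + 2 alpha)`` is the
    per-class probability that feature f is on; smoothing keeps every
    probability strictly inside (0, 1).  Prediction is by maximum posterior,
    computed in log space; an exact posterior tie predicts class 0 (no
    referral), the conservative choice.
    """

    class_log_prior: np.ndarray  # shape (2,)
    feature_prob: np.ndarray  # shape (2, d)
    alpha: float

    def predict_log_posterior(self, X: np.ndarray) -> np.ndarray:
        """Unnormalized log posterior, shape (len(X), 2)."""
        X = np.asarray(X, dtype=np.float64)
        log_p = np.log(self.feature_prob)
        log_q = np.log1p(-self.feature_prob)
        return self.class_log_prior + X @ (log_p - log_q).T + log_q.sum(axis=1)

    def margins(self, X: np.ndarray) -> np.ndarray:
        """log posterior(class 1) - log posterior(class 0)."""
        lp = self.predict_log_posterior(X)
        return lp[:, 1] - lp[:, 0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.margins(X) > 0).astype(np.int8)

    @property
    def margin_weights(self) -> tuple[np.ndarray, float]:
        """(w, b) with margin(x) = b + x . w — the linear form of the model."""
        log_p = np.log(self.feature_prob)
        log_q = np.log1p(-self.feature_prob)
        w = (log_p[1] - log_q[1]) - (log_p[0] - log_q[0])
        b = float(
            self.class_log_prior[1]
            - self.class_log_prior[0]
            + (log_q[1] - log_q[0]).sum()
        )
        return w, b


def fit_bernoulli_nb(X: np.ndarray, y: np.ndarray, alpha: float = 1.0) -> BernoulliNBModel:
    """Fit the classifier; both classes must be present in the training data."""
    X = np.asarray(X)
    y = np.asarray(y)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(
            "training data must contain both classes; oversample the minority "
            "class before fitting"
        )
    n = len(y)
    counts = np.array([(y == 0).sum(), (y == 1).sum()], dtype=np.float64)
    on = np.stack([X[y == 0].sum(axis=0), X[y == 1].sum(axis=0)]).astype(np.float64)
    feature_prob = (on + alpha) / (counts[:, None] + 2.0 * alpha)
    class_log_prior = np.log(counts / n)
    return BernoulliNBModel(class_log_prior, feature_prob, alpha)


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of sensitivity and specificity: (TP/(TP+FN) + TN/(TN+FP)) / 2."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == 1
    neg = y_true == 0
    if not pos.any() or not neg.any():
        raise ValueError("balanced accuracy is undefined when a class is absent")
    tpr = (y_pred[pos] == 1).mean()
    tnr = (y_pred[neg] == 0).mean()
    return float(0.5 * (tpr + tnr))


def oversample_minority(y: np.ndarray, idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Return ``idx`` plus resampled minority indices so classes balance.

    Duplicates whole rows (with replacement), the plain random-oversampling
    scheme.
    """
    idx = np.asarray(idx)
    y_sub = np.asarray(y)[idx]
    n_pos = int((y_sub == 1).sum())
    n_neg = int((y_sub == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("cannot oversample a single-class split")
    if n_pos == n_neg:
        return idx
    minority = 1 if n_pos < n_neg else 0
    short = abs(n_neg - n_pos)
    pool = idx[y_sub == minority]
    extra = rng.choice(pool, size=short, replace=True)
    return np.concatenate([idx, extra])


def grouped_resample_splits(
    dataset: LabeledStateDataset,
    n_splits: int,
    test_fraction: float = 0.2,
    seed: int = 0,
    max_redraws: int = 1000,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (train_idx, test_idx) with whole patients assigned to one side.

    The training side is already minority-oversampled.  Splits whose test
    partition lacks a class (balanced accuracy would be undefined) or whose
    training partition lacks a class are rejected and redrawn.
    """
    rng = np.random.default_rng(seed)
    for _ in range(n_splits):
        train_idx, test_idx = _draw_split(dataset, test_fraction, rng, max_redraws)[:2]
        yield train_idx, test_idx


def _draw_split(
    dataset: LabeledStateDataset,
    test_fraction: float,
    rng: np.random.Generator,
    max_redraws: int = 1000,
) -> tuple[np.ndarray, np.ndarray, int]:
    patients = np.unique(dataset.groups)
    n_test = max(1, int(round(test_fraction * len(patients))))
    y = dataset.y
    for redraw in range(max_redraws):
        test_patients = set(rng.choice(patients, size=n_test, replace=False))
        in_test = np.array([g in test_patients for g in dataset.groups])
        test_idx = np.flatnonzero(in_test)
        train_idx = np.flatnonzero(~in_test)
        if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
            continue
        train_idx = oversample_minority(y, train_idx, rng)
        return train_idx, test_idx, redraw
    raise RuntimeError("could not draw a split with both classes on both sides")


@dataclass
class ImportanceReport:
    """Permutation importances and baseline scores over resampling splits.

    ``mean_importance[f]`` is the mean over splits of (baseline balanced
    accuracy - balanced accuracy after permuting feature f in the test
    partition); the 95% interval is the empirical 2.5-97.5 percentile.
    Negative importances are legitimate and reported as-is.
    """

    feature_names: tuple[str, ...]
    mean_importance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    baseline_scores: np.ndarray
    n_splits: int
    n_rejected_splits: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature": self.feature_names,
                "mean_importance": self.mean_importance,
                "lower95": self.ci_low,
                "upper95": self.ci_high,
            }
        )
        df["n_splits"] = self.n_splits
        return df.sort_values("mean_importance", ascending=False, ignore_index=True)


def permutation_importance(
    dataset: LabeledStateDataset,
    n_splits: int = 10000,
    test_fraction: float = 0.2,
    seed: int = 0,
    alpha: float = 1.0,
) -> ImportanceReport:
    """Grouped-resampling permutation importance with a Bernoulli NB scorer.

    Per split: fit on the oversampled training patients, score balanced
    accuracy on the held-out patients, then permute each feature column once
    within the test partition and record the score drop.  The naive Bayes
    margin is linear in the features, so permuting a single column shifts
    each margin by ``(x_perm - x) * w_f``; scoring uses that identity rather
    than refitting, which is exact.
    """
    rng = np.random.default_rng(seed)
    d = dataset.X.shape[1]
    importances = np.empty((n_splits, d))
    baselines = np.empty(n_splits)
    n_rejected = 0
    Xf = dataset.X.astype(np.float64)
    y = dataset.y
    for s in range(n_splits):
        train_idx, test_idx, redraws = _draw_split(dataset, test_fraction, rng)
        n_rejected += redraws
        model = fit_bernoulli_nb(Xf[train_idx], y[train_idx], alpha=alpha)
        w, b = model.margin_weights
        X_test = Xf[test_idx]
        y_test = y[test_idx]
        margins = b + X_test @ w
        baselines[s] = balanced_accuracy(y_test, (margins > 0).astype(np.int8))
        # one independent row permutation per feature column
        order = np.argsort(rng.random((len(test_idx), d)), axis=0)
        X_perm = np.take_along_axis(X_test, order, axis=0)
        shifted = margins[:, None] + (X_perm - X_test) * w[None, :]
        pred = shifted > 0
        pos = y_test == 1
        neg = y_test == 0
        tpr = pred[pos].mean(axis=0)
        tnr = (~pred[neg]).mean(axis=0)
        importances[s] = baselines[s] - 0.5 * (tpr + tnr)
    return ImportanceReport(
        feature_names=dataset.feature_names,
        mean_importance=importances.mean(axis=0),
        ci_low=np.percentile(importances, 2.5, axis=0),
        ci_high=np.percentile(importances, 97.5, axis=0),
        baseline_scores=baselines,
        n_splits=n_splits,
        n_rejected_splits=n_rejected,
    )
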