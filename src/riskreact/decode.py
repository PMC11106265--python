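"""Per-timepoint stimulus decoding from sensor epochs.

For every 10-ms bin of localizer data a bank of three one-vs-rest lasso
logistic classifiers is trained, one per outcome stimulus (O1, O2, OS).
Each classifier discriminates its stimulus's sensor pattern from the other
six stimuli plus null (inter-trial-interval) samples and emits an
*activation probability* -- the estimated probability that its stimulus's
pattern is present in a sensor snapshot.  Cross-validated accuracy is scored
by whether a held-out outcome event's own classifier has the highest
activation probability, for every (train bin, test bin) combination, giving
a temporal-generalization accuracy matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "EpochSet",
    "ClassifierBank",
    "OUTCOME_STIMULI",
    "STIMULUS_VOCABULARY",
    "scale_95",
    "train_bank",
    "crossval_accuracy",
    "accuracy_permutation_threshold",
]

OUTCOME_STIMULI = ("O1", "O2", "OS")  # fixed order; argmax ties break this way
STIMULUS_VOCABULARY = ("O1", "O2", "OS", "P1", "P2", "P3", "P4")
ITI_LABEL = "ITI"
DEFAULT_LAMBDA_GRID = (0.0005, 0.001, 0.002, 0.004, 0.008)
DEFAULT_LAMBDA = 0.002


@dataclass
class EpochSet:
    """Sensor epochs: a sensors x timebins x events block with labels.

    ``times_ms[j]`` is the time of bin j relative to the alignment event
    (stimulus onset for localizer epochs, probability-stimulus onset for
    task epochs); bins are 10 ms wide.
    """

    data: np.ndarray  # (n_sensors, n_bins, n_events)
    event_labels: np.ndarray  # (n_events,) strings
    times_ms: np.ndarray  # (n_bins,)
    alignment: str = "stimulus"  # "stimulus" | "probability_stimulus"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.event_labels = np.asarray(self.event_labels, dtype=object)
        self.times_ms = np.asarray(self.times_ms, float)
        if self.data.ndim != 3:
            raise ValueError("data must be sensors x timebins x events")
        if self.data.shape[2] != len(self.event_labels):
            raise ValueError("event label count does not match data")
        if self.data.shape[1] != len(self.times_ms):
            raise ValueError("time base does not match data")

    @property
    def n_sensors(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    @property
    def n_events(self) -> int:
        return self.data.shape[2]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset(
                "labels", data=np.array([str(x) for x in self.event_labels], dtype="S8")
            )
            f.create_dataset("times_ms", data=self.times_ms)
            f.attrs["alignment"] = self.alignment

    @classmethod
    def load(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][:],
                event_labels=np.array([x.decode() for x in f["labels"][:]]),
                times_ms=f["times_ms"][:],
                alignment=str(f.attrs["alignment"]),
            )


@dataclass
class ClassifierBank:
    """Lasso logistic classifiers per (outcome stimulus, train bin)."""

    weights: np.ndarray  # (3, n_train_bins, n_sensors)
    intercepts: np.ndarray  # (3, n_train_bins)
    scale: float  # 95th absolute percentile of the training block
    lam: float
    train_times_ms: np.ndarray  # (n_train_bins,)
    stimuli: tuple = OUTCOME_STIMULI

    def activation_probs(self, data: np.ndarray) -> np.ndarray:
        """Apply every classifier to every test bin of (already raw) data.

        ``data`` is sensors x test_bins x events, divided here by the bank's
        stored training scale.  Returns probabilities with shape
        (3, n_train_bins, n_test_bins, n_events).
        """
        x = np.asarray(data, float) / self.scale
        z = np.einsum("ots,sue->otue", self.weights, x)
        z += self.intercepts[:, :, None, None]
        return expit(z)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("weights", data=self.weights)
            f.create_dataset("intercepts", data=self.intercepts)
            f.create_dataset("train_times_ms", data=self.train_times_ms)
            f.attrs["scale"] = self.scale
            f.attrs["lam"] = self.lam

    @classmethod
    def load(cls, path) -> "ClassifierBank":
        with h5py.File(path, "r") as f:
            return cls(
                weights=f["weights"][:],
                intercepts=f["intercepts"][:],
                scale=float(f.attrs["scale"]),
                lam=float(f.attrs["lam"]),
                train_times_ms=f["train_times_ms"][:],
            )


def scale_95(data: np.ndarray) -> tuple[np.ndarray, float]:
    """Divide a data block by the 95th percentile of its absolute values."""
    data = np.asarray(data, float)
    if data.size == 0:
        raise ValueError("empty data")
    s = float(np.percentile(np.abs(data), 95))
    if s == 0.0:
        raise ValueError("scale is zero (all-(near-)zero data)")
    return data / s, s


def _make_classifier(lam: float, n_samples: int, random_state: int) -> LogisticRegression:
    # C maps lambda from a (1/n) * logloss + lambda * ||w||_1 objective;
    # large intercept_scaling leaves the intercept effectively unpenalized
    return LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (lam * n_samples),
        solver="liblinear",
        intercept_scaling=100.0,
        max_iter=2000,
        random_state=random_state,
    )


def _fit_bin_classifiers(
    feats: np.ndarray,
    labels: np.ndarray,
    lam: float,
    rng: np.random.Generator,
    null_match: str = "total",
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the three outcome classifiers on one time bin.

    ``feats`` is events x sensors (already scaled).  Negatives for each
    outcome are the other six stimuli plus ITI samples drawn without
    replacement, matched in count to all stimulus examples ("total") or to
    the positives alone ("positives").
    """
    is_iti = labels == ITI_LABEL
    iti_pool = np.flatnonzero(is_iti)
    W = np.zeros((len(OUTCOME_STIMULI), feats.shape[1]))
    b = np.zeros(len(OUTCOME_STIMULI))
    for i, stim in enumerate(OUTCOME_STIMULI):
        pos = np.flatnonzero(labels == stim)
        others = np.flatnonzero(~is_iti & (labels != stim))
        n_null = len(pos) + len(others) if null_match == "total" else len(pos)
        n_null = min(n_null, len(iti_pool))
        null_idx = rng.choice(iti_pool, size=n_null, replace=False) if n_null else []
        idx = np.concatenate([pos, others, null_idx]).astype(int)
        y = np.zeros(len(idx))
        y[: len(pos)] = 1.0
        clf = _make_classifier(lam, len(idx), int(rng.integers(2**31 - 1)))
        clf.fit(feats[idx], y)
        W[i] = clf.coef_[0]
        b[i] = clf.intercept_[0]
    return W, b


def train_bank(
    localizer: EpochSet,
    lam: float = DEFAULT_LAMBDA,
    seed: int = 0,
    null_match: str = "total",
    event_subset: np.ndarray | None = None,
) -> ClassifierBank:
    """Train the full classifier bank on localizer epochs.

    One lasso logistic classifier per outcome stimulus and 10-ms train bin.
    The whole training block is scaled by its 95th absolute percentile,
    which is stored for reuse on test data.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    labels = localizer.event_labels
    if event_subset is not None:
        labels = labels[event_subset]
        data = localizer.data[:, :, event_subset]
    else:
        data = localizer.data
    present = set(labels)
    missing = [s for s in STIMULUS_VOCABULARY if s not in present]
    if missing:
        raise ValueError(f"localizer lacks stimulus labels: {missing}")
    if ITI_LABEL not in present:
        raise ValueError("localizer lacks ITI (null) segments")

    scaled, s = scale_95(data)
    rng = np.random.default_rng(seed)
    n_bins = scaled.shape[1]
    W = np.zeros((len(OUTCOME_STIMULI), n_bins, scaled.shape[0]))
    b = np.zeros((len(OUTCOME_STIMULI), n_bins))
    for j in range(n_bins):
        W[:, j], b[:, j] = _fit_bin_classifiers(
            scaled[:, j, :].T, labels, lam, rng, null_match
        )
    return ClassifierBank(
        weights=W,
        intercepts=b,
        scale=s,
        lam=lam,
        train_times_ms=localizer.times_ms.copy(),
    )


def _accuracy_matrix(bank: ClassifierBank, test: EpochSet, test_events: np.ndarray) -> np.ndarray:
    """Accuracy(train bin, test bin) over outcome-stimulus test events."""
    labels = test.event_labels[test_events]
    is_outcome = np.isin(labels, OUTCOME_STIMULI)
    ev = test_events[is_outcome]
    truth = np.array([OUTCOME_STIMULI.index(l) for l in labels[is_outcome]])
    probs = bank.activation_probs(test.data[:, :, ev])  # (3, nt, nb, ne)
    pred = np.argmax(probs, axis=0)  # ties -> lowest index = fixed stimulus order
    return (pred == truth[None, None, :]).mean(axis=2)


def crossval_accuracy(
    localizer: EpochSet,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    folds: int = 7,
    seed: int = 0,
    null_match: str = "total",
    labels: np.ndarray | None = None,
):
    """Cross-validated temporal-generalization accuracy and lambda selection.

    Folds are stratified by stimulus label.  Returns ``(acc, lam_star)``
    where ``acc[i]`` is the train x test accuracy matrix for
    ``lambda_grid[i]`` (mean over folds) and ``lam_star`` maximizes the mean
    diagonal (matched train/test bin) accuracy.
    """
    lambda_grid = list(lambda_grid)
    if not lambda_grid:
        raise ValueError("empty lambda grid")
    if labels is None:
        labels = localizer.event_labels
    counts = min(np.sum(labels == s) for s in STIMULUS_VOCABULARY)
    if counts < folds:
        raise ValueError("need at least `folds` events per stimulus")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    n_bins = localizer.n_bins
    acc = np.zeros((len(lambda_grid), n_bins, n_bins))
    idx = np.arange(localizer.n_events)
    shim = EpochSet(localizer.data, labels, localizer.times_ms, localizer.alignment)
    for fold, (train_idx, test_idx) in enumerate(skf.split(idx, labels.astype(str))):
        for li, lam in enumerate(lambda_grid):
            bank = train_bank(
                shim, lam=lam, seed=seed + 1000 * fold, null_match=null_match,
                event_subset=train_idx,
            )
            acc[li] += _accuracy_matrix(bank, shim, test_idx)
    acc /= folds
    diag_means = [np.trace(a) / n_bins for a in acc]
    lam_star = lambda_grid[int(np.argmax(diag_means))]
    return acc, lam_star


def _diagonal_accuracy_line(
    localizer: EpochSet,
    labels: np.ndarray,
    lam: float,
    folds: int,
    seed: int,
    null_match: str = "total",
) -> np.ndarray:
    """Matched train/test bin CV accuracy, one value per bin."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    n_bins = localizer.n_bins
    correct = np.zeros(n_bins)
    total = np.zeros(n_bins)
    idx = np.arange(localizer.n_events)
    for fold, (train_idx, test_idx) in enumerate(skf.split(idx, labels.astype(str))):
        rng = np.random.default_rng(seed + 1000 * fold)
        train_labels = labels[train_idx]
        test_labels = labels[test_idx]
        is_outcome = np.isin(test_labels, OUTCOME_STIMULI)
        truth = np.array([OUTCOME_STIMULI.index(l) for l in test_labels[is_outcome]])
        # per-fold scale from the training block, as at bank-training time
        _, s_tr = scale_95(localizer.data[:, :, train_idx])
        for j in range(n_bins):
            feats_tr = localizer.data[:, j, train_idx].T / s_tr
            W, b = _fit_bin_classifiers(feats_tr, train_labels, lam, rng, null_match)
            feats_te = localizer.data[:, j, test_idx].T[is_outcome] / s_tr
            probs = expit(feats_te @ W.T + b)
            correct[j] += np.sum(np.argmax(probs, axis=1) == truth)
            total[j] += len(truth)
    return correct / total


def accuracy_permutation_threshold(
    localizer: EpochSet,
    lam: float = DEFAULT_LAMBDA,
    n_perm: int = 100,
    seed: int = 0,
    folds: int = 7,
    null_match: str = "total",
) -> float:
    """95th percentile of peak shuffled-label diagonal CV accuracy.

    For each permutation the event labels are shuffled, the diagonal CV
    accuracy line is recomputed, and its peak recorded; the returned
    threshold is the 95th percentile of those peaks.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    peaks = np.empty(n_perm)
    labels = localizer.event_labels
    for k in range(n_perm):
        perm_labels = labels[rng.permutation(len(labels))]
        line = _diagonal_accuracy_line(
            localizer, perm_labels, lam, folds, seed=seed + k + 1, null_match=null_match
        )
        peaks[k] = line.max()
    return float(np.percentile(peaks, 95))
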