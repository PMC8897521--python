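"""Time-resolved decoding of symbol position from multichannel scalp voltages.

At every time point a linear maximum-margin classifier (SVM) is trained to
separate the scalp topography of trials whose search item appeared in the
patterned location from trials where it appeared in the random location.
Single trials are noisy, so each class's trials are randomly partitioned
into ``n_folds`` equal blocks and averaged within block; a full
cross-validation rotation trains on ``n_folds - 1`` block-averages per class
and tests on the held-out pair.  With the defaults (3 folds, 10 iterations,
2 classes) every time point accumulates exactly 60 decoding attempts and
accuracy is their correct proportion (chance 0.50).

Features are the scalp channels (ocular and reference channels excluded),
standardized per time point with training-block statistics only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .containers import EpochSet

__all__ = [
    "DecodingTimecourse",
    "WindowAccuracy",
    "make_class_blocks",
    "decode_timecourse",
    "window_mean_accuracy",
]

EXCLUDED_CHANNELS = ("HEOG", "VEOG", "A1", "A2")


@dataclass
class DecodingTimecourse:
    """Per-time-point decoding accuracy for one participant."""

    times: np.ndarray
    accuracy: np.ndarray
    n_attempts_per_point: int
    participant_id: str = ""
    trial_type: str = ""
    n_dropped: int = 0
    config: dict = field(default_factory=dict)


@dataclass
class WindowAccuracy:
    """Window-averaged decoding accuracy with a group test against chance."""

    per_participant: np.ndarray
    mean: float
    chance: float
    t: float
    df: int
    p_value: float
    cohen_d: float
    note: str = ""


def _class_rng(base, idx) -> np.random.Generator:
    """Generator keyed to a class's trial-index *set* (plus a base seed).

    Keying randomization to the index set rather than to the class label or
    its position makes blocking invariant under exchanging the two class
    labels — the label-swap symmetry of decoding accuracy holds exactly.
    """
    base_list = [int(b) for b in (base if isinstance(base, (tuple, list)) else [base])]
    return np.random.default_rng(base_list + [int(i) for i in np.sort(idx)])


def make_class_blocks(
    data: np.ndarray, labels: np.ndarray, n_folds: int = 3, seed=0
) -> tuple[np.ndarray, np.ndarray, int]:
    """Randomly partition each class's trials into ``n_folds`` averaged blocks.

    ``data`` is ``(n_trials, n_features, n_samples)``; trials left over after
    the equal split are dropped at random and counted.  Returns ``(blocks,
    classes, n_dropped)`` with ``blocks`` of shape
    ``(n_classes, n_folds, n_features, n_samples)``.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    n_dropped = 0
    blocks = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size < n_folds:
            raise ValueError(
                f"class {cls!r} has {idx.size} trials; needs at least {n_folds}"
            )
        rng = _class_rng(seed, idx)
        per_block = idx.size // n_folds
        n_dropped += idx.size - per_block * n_folds
        idx = rng.permutation(idx)[: per_block * n_folds]
        blocks.append(
            data[idx].reshape(n_folds, per_block, *data.shape[1:]).mean(axis=1)
        )
    return np.stack(blocks), classes, n_dropped


def decode_timecourse(
    epochs: EpochSet,
    labels=None,
    n_folds: int = 3,
    n_iterations: int = 10,
    seed: int = 0,
    window_ms=None,
    exclude_channels=EXCLUDED_CHANNELS,
    standardize: bool = True,
    participant_id: str = "",
    trial_type: str = "",
) -> DecodingTimecourse:
    """Iterated cross-validated decoding accuracy at every time point.

    ``labels`` is a binary per-trial label array, or ``None`` to use the
    ``symbol_position`` column of the trial table.  Classes are equated by
    random subsampling to the smaller class before blocking.  Per iteration
    the blocks are re-drawn and every fold serves as test once, so each time
    point scores ``n_classes * n_folds * n_iterations`` attempts (60 with
    the defaults).
    """
    if labels is None:
        labels = epochs.trials["symbol_position"].to_numpy()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"decoding requires exactly two classes, got {classes!r}")

    feat_idx = [i for i, ch in enumerate(epochs.channels) if ch not in set(exclude_channels)]
    sample_mask = (
        epochs.time_mask(window_ms) if window_ms is not None
        else np.ones(epochs.n_samples, dtype=bool)
    )
    times = epochs.times[sample_mask]
    data = epochs.data[:, feat_idx, :][:, :, sample_mask]

    # Equate class sizes by random subsampling to the smaller class (the
    # draw is keyed to each class's index set; see _class_rng).
    idx_by_class = [np.flatnonzero(labels == c) for c in classes]
    n_per_class = min(len(i) for i in idx_by_class)
    n_dropped_balance = sum(len(i) - n_per_class for i in idx_by_class)
    keep = np.sort(np.concatenate(
        [_class_rng((seed, 1), i).permutation(i)[:n_per_class] for i in idx_by_class]
    ))  # sorted so trial positions (the rng keys) are label-order invariant
    data = data[keep]
    labels = labels[keep]

    n_points = data.shape[2]
    n_attempts = len(classes) * n_folds * n_iterations
    correct = np.zeros(n_points)
    n_dropped = n_dropped_balance
    degenerate_warned = False

    for iteration in range(n_iterations):
        blocks, cls_order, dropped = make_class_blocks(
            data, labels, n_folds, seed=(seed, 2, iteration)
        )
        n_dropped += dropped
        y_train = np.repeat(np.arange(len(cls_order)), n_folds - 1)
        for test_fold in range(n_folds):
            train_folds = [f for f in range(n_folds) if f != test_fold]
            # (n_classes * (n_folds-1), n_features, n_points)
            tr = blocks[:, train_folds].reshape(-1, blocks.shape[2], n_points)
            te = blocks[:, test_fold]  # (n_classes, n_features, n_points)
            for p in range(n_points):
                X_tr = tr[:, :, p]
                X_te = te[:, :, p]
                if standardize:
                    mu = X_tr.mean(axis=0)
                    sd = X_tr.std(axis=0)
                    sd = np.where(sd == 0, 1.0, sd)
                    X_tr = (X_tr - mu) / sd
                    X_te = (X_te - mu) / sd
                if np.allclose(X_tr, X_tr[0]):
                    if not degenerate_warned:
                        warnings.warn(
                            "degenerate features (identical training vectors); "
                            "predictions default to the first class",
                            stacklevel=2,
                        )
                        degenerate_warned = True
                    pred = np.zeros(len(cls_order), dtype=int)
                else:
                    clf = SVC(kernel="linear", C=1.0)
                    clf.fit(X_tr, y_train)
                    pred = clf.predict(X_te)
                correct[p] += np.sum(pred == np.arange(len(cls_order)))

    return DecodingTimecourse(
        times=times,
        accuracy=correct / n_attempts,
        n_attempts_per_point=n_attempts,
        participant_id=participant_id,
        trial_type=trial_type,
        n_dropped=n_dropped,
        config={
            "n_folds": n_folds,
            "n_iterations": n_iterations,
            "classifier": "linear SVM (C=1)",
            "standardize": standardize,
            "n_trials_per_class": n_per_class,
        },
    )


def window_mean_accuracy(
    timecourses: list, window_ms=(150.0, 300.0), chance: float = 0.5
) -> WindowAccuracy:
    """Window-averaged accuracy per participant with a one-sample t vs chance.

    Accepts a list of :class:`DecodingTimecourse` sharing a time axis.  The
    group test is a two-sided one-sample t against ``chance`` with Cohen's d;
    a zero-variance sample is reported as such instead of an infinite t.
    """
    if len(timecourses) < 3:
        raise ValueError("the group test needs at least three participants")
    times = timecourses[0].times
    lo, hi = window_ms
    if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
        raise ValueError(f"window {window_ms} lies outside the decoded series")
    mask = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    per_part = np.array([tc.accuracy[mask].mean() for tc in timecourses])
    n = per_part.size
    sd = per_part.std(ddof=1)
    if sd == 0:
        return WindowAccuracy(
            per_participant=per_part,
            mean=float(per_part.mean()),
            chance=chance,
            t=0.0,
            df=n - 1,
            p_value=float("nan"),
            cohen_d=float("nan"),
            note="zero variance across participants; t undefined",
        )
    t = (per_part.mean() - chance) / (sd / np.sqrt(n))
    return WindowAccuracy(
        per_participant=per_part,
        mean=float(per_part.mean()),
        chance=chance,
        t=float(t),
        df=n - 1,
        p_value=float(2.0 * stats.t.sf(abs(t), df=n - 1)),
        cohen_d=float((per_part.mean() - chance) / sd),
    )
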