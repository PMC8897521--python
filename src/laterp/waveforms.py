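"""Contralateral/ipsilateral averages, difference waves and grand averages.

The lateralized component lives in the posterior channel pair PO7/PO8: for a
left-hemifield item the contralateral channel is PO8 (right hemisphere), for
a right-hemifield item it is PO7.  Condition averages collapse trials of one
``(symbol_position, trial_type)`` cell; the difference wave is contra minus
ipsi; grand averages are unweighted means across participants; and jackknife
grand averages leave one participant out at a time for latency inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochSet

__all__ = [
    "LateralizedERP",
    "DifferenceWave",
    "assign_laterality",
    "lateralized_trial_traces",
    "condition_average",
    "difference_wave",
    "grand_average",
    "jackknife_grand_averages",
]

_CONTRA = {"left": "PO8", "right": "PO7"}


def assign_laterality(item_side: str) -> tuple[str, str]:
    """Map an item's hemifield to the ``(contra, ipsi)`` posterior channels.

    Target Absent trials (``item_side='none'``) carry no reference object and
    have no defined laterality.
    """
    if item_side not in _CONTRA:
        raise ValueError(
            f"item_side {item_side!r} has no laterality (target_absent trials "
            "carry no reference object)"
        )
    contra = _CONTRA[item_side]
    ipsi = "PO7" if contra == "PO8" else "PO8"
    return contra, ipsi


@dataclass
class LateralizedERP:
    """Per-condition contralateral and ipsilateral average waveforms (uV)."""

    contra: np.ndarray
    ipsi: np.ndarray
    times: np.ndarray
    condition: tuple[str, str]
    n_trials: int
    participant_id: str = ""

    def __post_init__(self):
        if self.contra.shape != self.ipsi.shape or self.contra.shape != self.times.shape:
            raise ValueError("contra, ipsi and time axes must share one shape")
        if self.n_trials < 1:
            raise ValueError("a condition average needs at least one trial")


@dataclass
class DifferenceWave:
    """A contra-minus-ipsi difference waveform (uV) on a millisecond time axis."""

    values: np.ndarray
    times: np.ndarray
    condition: tuple[str, str] | None = None
    participant_id: str = ""
    n_participants: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("values and time axis must share one shape")


def lateralized_trial_traces(epochs: EpochSet) -> np.ndarray:
    """Per-trial contra-minus-ipsi traces, shape ``(n_trials, n_samples)``.

    Requires an ``item_side`` column in the trial table with every trial
    lateralized (no Target Absent trials).
    """
    po7 = epochs.get_channel("PO7")
    po8 = epochs.get_channel("PO8")
    sides = epochs.trials["item_side"].to_numpy()
    traces = np.empty((epochs.n_trials, epochs.n_samples))
    for i, side in enumerate(sides):
        contra, _ = assign_laterality(side)
        traces[i] = (po8[i] - po7[i]) if contra == "PO8" else (po7[i] - po8[i])
    return traces


def condition_average(
    epochs: EpochSet,
    symbol_position: str,
    trial_type: str,
    participant_id: str = "",
) -> LateralizedERP:
    """Average the contralateral and ipsilateral channels over one condition's trials."""
    meta = epochs.trials
    mask = (meta["symbol_position"].to_numpy() == symbol_position) & (
        meta["trial_type"].to_numpy() == trial_type
    )
    if not mask.any():
        raise ValueError(
            f"participant {participant_id or '?'} has no trials in condition "
            f"({symbol_position!r}, {trial_type!r})"
        )
    sub = epochs.select_trials(mask)
    po7 = sub.get_channel("PO7")
    po8 = sub.get_channel("PO8")
    contra_tr = np.empty_like(po7)
    ipsi_tr = np.empty_like(po7)
    for i, side in enumerate(sub.trials["item_side"].to_numpy()):
        contra, _ = assign_laterality(side)
        if contra == "PO8":
            contra_tr[i], ipsi_tr[i] = po8[i], po7[i]
        else:
            contra_tr[i], ipsi_tr[i] = po7[i], po8[i]
    return LateralizedERP(
        contra=contra_tr.mean(axis=0),
        ipsi=ipsi_tr.mean(axis=0),
        times=sub.times.copy(),
        condition=(symbol_position, trial_type),
        n_trials=sub.n_trials,
        participant_id=participant_id,
    )


def difference_wave(erp: LateralizedERP) -> DifferenceWave:
    """Contralateral minus ipsilateral, sample-wise."""
    return DifferenceWave(
        values=erp.contra - erp.ipsi,
        times=erp.times.copy(),
        condition=erp.condition,
        participant_id=erp.participant_id,
    )


def _common_axis(waves) -> np.ndarray:
    times = waves[0].times
    for w in waves[1:]:
        if w.times.shape != times.shape or not np.allclose(w.times, times):
            raise ValueError("difference waves do not share a common time axis")
    return times


def grand_average(waves: list[DifferenceWave]) -> DifferenceWave:
    """Unweighted mean across participants (standard ERP convention)."""
    if len(waves) < 2:
        raise ValueError("a grand average needs at least two participants")
    times = _common_axis(waves)
    condition = waves[0].condition if all(w.condition == waves[0].condition for w in waves) else None
    return DifferenceWave(
        values=np.mean([w.values for w in waves], axis=0),
        times=times.copy(),
        condition=condition,
        participant_id="grand",
        n_participants=len(waves),
    )


def jackknife_grand_averages(waves: list[DifferenceWave]) -> list[DifferenceWave]:
    """Leave-one-out grand averages: the i-th output omits the i-th participant."""
    n = len(waves)
    if n < 3:
        raise ValueError("jackknife grand averages need at least three participants")
    times = _common_axis(waves)
    stack = np.stack([w.values for w in waves])
    total = stack.sum(axis=0)
    out = []
    for i in range(n):
        out.append(
            DifferenceWave(
                values=(total - stack[i]) / (n - 1),
                times=times.copy(),
                condition=waves[i].condition,
                participant_id=f"loo-{waves[i].participant_id or i}",
                n_participants=n - 1,
            )
        )
    return out
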