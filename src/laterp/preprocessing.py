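"""Deterministic signal conditioning and trial selection.

Pipeline order: re-reference to averaged earlobes -> zero-phase Butterworth
filtering (40 Hz low-pass at 48 dB/octave, 0.1 Hz high-pass at 12 dB/octave,
60 Hz notch) -> baseline correction over -100..0 ms -> amplitude-threshold
artifact rejection (|HEOG| > 25 uV or |VEOG| > 60 uV within 0-300 ms, any
other channel |v| > 80 uV within -100..500 ms) -> retention of correct,
non-Target-Absent trials.

"Exceeding +/- X uV" is read literally as instantaneous absolute amplitude
within the criterion's window, boundaries inclusive at sample resolution.
The stated roll-offs map to an 8th-order low-pass and 2nd-order high-pass
Butterworth (6 dB/octave per order), each applied forward-backward
(``sosfiltfilt``) so no group delay is introduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochSet

__all__ = [
    "FilterSpec",
    "RejectionCriteria",
    "ArtifactReport",
    "rereference_to_earlobes",
    "filter_epochs",
    "baseline_correct",
    "reject_artifacts",
    "select_analysis_trials",
    "preprocess",
]


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth filtering parameters.

    ``None`` disables a stage.  Orders approximate the nominal roll-offs:
    order 8 ~ 48 dB/octave, order 2 ~ 12 dB/octave.  The notch is an IIR
    notch of half-width ``notch_halfwidth_hz`` (-3 dB points).
    """

    lowpass_hz: float | None = 40.0
    lowpass_order: int = 8
    highpass_hz: float | None = 0.1
    highpass_order: int = 2
    notch_hz: float | None = 60.0
    notch_halfwidth_hz: float = 2.5

    def validate(self, sfreq: float) -> None:
        nyquist = sfreq / 2.0
        for name, cutoff in (("lowpass", self.lowpass_hz), ("highpass", self.highpass_hz),
                             ("notch", self.notch_hz)):
            if cutoff is not None and not 0.0 < cutoff < nyquist:
                raise ValueError(f"{name} cutoff {cutoff} Hz outside (0, Nyquist={nyquist})")
        if self.lowpass_hz is not None and self.highpass_hz is not None:
            if self.highpass_hz >= self.lowpass_hz:
                raise ValueError("highpass cutoff must lie below lowpass cutoff")


@dataclass(frozen=True)
class RejectionCriteria:
    """Absolute-amplitude rejection thresholds per channel class.

    A trial is rejected iff |voltage| exceeds the class threshold anywhere
    inside that class's closed time window.
    """

    heog_abs_uv: float = 25.0
    heog_window_ms: tuple = (0.0, 300.0)
    veog_abs_uv: float = 60.0
    veog_window_ms: tuple = (0.0, 300.0)
    other_abs_uv: float = 80.0
    other_window_ms: tuple = (-100.0, 500.0)
    heog_label: str = "HEOG"
    veog_label: str = "VEOG"
    exclude_labels: tuple = ("A1", "A2")

    def __post_init__(self):
        for t in (self.heog_abs_uv, self.veog_abs_uv, self.other_abs_uv):
            if t <= 0:
                raise ValueError("rejection thresholds must be positive")


@dataclass
class ArtifactReport:
    """Outcome of artifact rejection: retained epochs plus bookkeeping."""

    retained: EpochSet
    rejected: np.ndarray                 # bool per input trial
    counts: dict                         # criterion -> number of trials triggering it
    table: pd.DataFrame                  # per-trial decision with triggering criteria


def rereference_to_earlobes(epochs: EpochSet, earlobe_channels=("A1", "A2")) -> EpochSet:
    """Subtract the averaged earlobe signal from every channel.

    The earlobe channels themselves are dropped from the returned set (they
    are identically re-expressed relative to their own mean and carry no
    further analysis value).
    """
    missing = [ch for ch in earlobe_channels if ch not in epochs.channels]
    if missing:
        raise ValueError(f"earlobe channels missing from montage: {missing}")
    ref = np.mean(
        [epochs.get_channel(ch) for ch in earlobe_channels], axis=0
    )  # (trials, samples)
    out = epochs.copy()
    out.data = out.data - ref[:, None, :]
    return out.drop_channels(earlobe_channels)


def filter_epochs(epochs: EpochSet, spec: FilterSpec | None = None) -> EpochSet:
    """Apply the zero-phase Butterworth cascade to every trial and channel.

    Forward-backward application (``sosfiltfilt``/``filtfilt``) keeps
    symmetric pulses centred: the sample index of an extremum is unchanged.
    Epochs shorter than the filter's padding requirement are rejected.
    """
    spec = spec or FilterSpec()
    spec.validate(epochs.sfreq)
    out = epochs.copy()
    flat = out.data.reshape(-1, out.n_samples)
    if spec.lowpass_hz is not None:
        sos = signal.butter(spec.lowpass_order, spec.lowpass_hz, "lowpass",
                            fs=epochs.sfreq, output="sos")
        flat = signal.sosfiltfilt(sos, flat, axis=-1)
    if spec.highpass_hz is not None:
        sos = signal.butter(spec.highpass_order, spec.highpass_hz, "highpass",
                            fs=epochs.sfreq, output="sos")
        flat = signal.sosfiltfilt(sos, flat, axis=-1)
    if spec.notch_hz is not None:
        q = spec.notch_hz / (2.0 * spec.notch_halfwidth_hz)
        b, a = signal.iirnotch(spec.notch_hz, q, fs=epochs.sfreq)
        flat = signal.filtfilt(b, a, flat, axis=-1)
    out.data = np.ascontiguousarray(flat.reshape(out.data.shape))
    return out


def baseline_correct(epochs: EpochSet, baseline_window_ms=(-100.0, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    mask = epochs.time_mask(baseline_window_ms)
    out = epochs.copy()
    out.data = out.data - out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def reject_artifacts(epochs: EpochSet, criteria: RejectionCriteria | None = None) -> ArtifactReport:
    """Flag and drop trials whose amplitude exceeds the class thresholds.

    Channel classes: the HEOG channel, the VEOG channel, and all remaining
    channels (minus ``exclude_labels``) under the "other" criterion.  Returns
    an :class:`ArtifactReport`; retained trials preserve their order.
    """
    criteria = criteria or RejectionCriteria()
    classes = []
    if criteria.heog_label in epochs.channels:
        classes.append(("heog", [criteria.heog_label], criteria.heog_abs_uv,
                        criteria.heog_window_ms))
    if criteria.veog_label in epochs.channels:
        classes.append(("veog", [criteria.veog_label], criteria.veog_abs_uv,
                        criteria.veog_window_ms))
    excluded = {criteria.heog_label, criteria.veog_label, *criteria.exclude_labels}
    other = [ch for ch in epochs.channels if ch not in excluded]
    if other:
        classes.append(("other", other, criteria.other_abs_uv, criteria.other_window_ms))

    rejected = np.zeros(epochs.n_trials, dtype=bool)
    counts: dict[str, int] = {}
    trigger_cols = {}
    for name, chans, threshold, window in classes:
        mask = epochs.time_mask(window)
        idx = [epochs.channel_index(c) for c in chans]
        exceeded = (
            np.abs(epochs.data[:, idx, :][:, :, mask]).max(axis=(1, 2)) > threshold
            if epochs.n_trials
            else np.zeros(0, dtype=bool)
        )
        counts[name] = int(exceeded.sum())
        trigger_cols[name] = exceeded
        rejected |= exceeded

    table = pd.DataFrame({"trial": np.arange(epochs.n_trials), "rejected": rejected,
                          **trigger_cols})
    return ArtifactReport(
        retained=epochs.select_trials(~rejected),
        rejected=rejected,
        counts=counts,
        table=table,
    )


def select_analysis_trials(epochs: EpochSet, schedule: pd.DataFrame | None = None) -> EpochSet:
    """Retain correct, non-Target-Absent trials for the ERP analyses.

    Trial metadata comes from ``schedule`` when given (must align row-for-row
    with the epochs), else from ``epochs.trials``.
    """
    meta = epochs.trials if schedule is None else schedule.reset_index(drop=True)
    if len(meta) != epochs.n_trials:
        raise ValueError("trial metadata is not aligned with the epochs")
    for col in ("correct", "trial_type"):
        if col not in meta.columns:
            raise ValueError(f"trial metadata lacks required column {col!r}")
    keep = meta["correct"].astype(bool).to_numpy() & (
        meta["trial_type"].to_numpy() != "target_absent"
    )
    if not keep.any():
        warnings.warn("no analyzable trials remain after selection", stacklevel=2)
    out = epochs.select_trials(keep)
    if schedule is not None:
        out.trials = meta.loc[keep].reset_index(drop=True)
    return out


def preprocess(
    epochs: EpochSet,
    filter_spec: FilterSpec | None = None,
    criteria: RejectionCriteria | None = None,
    baseline_window_ms=(-100.0, 0.0),
    earlobe_channels=("A1", "A2"),
) -> tuple[EpochSet, ArtifactReport]:
    """Full conditioning chain on one participant's epochs.

    Order: re-reference (skipped when the earlobes are absent from the
    montage) -> filter -> baseline -> artifact rejection -> correct-trial
    selection.  Returns the analysis-ready epochs and the artifact report.
    """
    if all(ch in epochs.channels for ch in earlobe_channels):
        epochs = rereference_to_earlobes(epochs, earlobe_channels)
    epochs = filter_epochs(epochs, filter_spec)
    epochs = baseline_correct(epochs, baseline_window_ms)
    report = reject_artifacts(epochs, criteria)
    clean = select_analysis_trials(report.retained)
    return clean, report
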