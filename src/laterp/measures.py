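"""Scalar component measures on difference waves.

Four measures of the lateralized negativity, each evaluated inside a closed
time window of the difference wave:

* **mean amplitude** — arithmetic mean of the samples in the window
  (default 200-300 ms);
* **signed negative area** — integrated magnitude of the negative-going part
  of the wave (default 150-300 ms), in uV*ms.  The wave is treated as the
  linear interpolant of its samples, so the integral is a trapezoid rule
  refined at the interpolated zero crossings (exact for the interpolant);
* **fractional-area latency** — the time dividing the cumulative negative
  area at a stated fraction (default 50%), linearly interpolated within the
  bracketing sample interval; undefined when the window holds no negative
  area;
* **onset threshold crossing** — the first time the wave passes from above
  to at-or-below a negative threshold (default -0.75 uV), linearly
  interpolated between the bracketing samples; undefined when the threshold
  is never reached.

Undefined measures are flagged (``defined=False``, value ``NaN``), never
silently zero — mirroring the exclusion of participants whose data do not
meet a latency measure's existence condition.

:func:`jackknife_latency_analysis` estimates onset latency on
leave-one-participant-out grand averages, retrieves per-participant scores
through the jackknife back-transformation and corrects paired test
statistics by the factor ``n - 1``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .waveforms import DifferenceWave, grand_average, jackknife_grand_averages

__all__ = [
    "MeasureResult",
    "mean_amplitude",
    "signed_negative_area",
    "fractional_area_latency",
    "onset_threshold_crossing",
    "jackknife_latency_analysis",
    "JackknifeLatencyResult",
    "JackknifeComparison",
]

N2PC_WINDOW_MS = (200.0, 300.0)
BROAD_WINDOW_MS = (150.0, 300.0)
ONSET_THRESHOLD_UV = -0.75


@dataclass
class MeasureResult:
    """A scalar ERP measure with window and units metadata.

    ``defined`` is False when the wave fails the measure's existence
    condition; ``value`` is then ``NaN``.
    """

    measure: str
    value: float
    window_ms: tuple[float, float]
    units: str
    defined: bool = True
    params: dict = field(default_factory=dict)


def _window_values(wave: DifferenceWave, window_ms) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = window_ms
    if hi <= lo:
        raise ValueError(f"window {window_ms} is empty")
    if lo < wave.times[0] - 1e-9 or hi > wave.times[-1] + 1e-9:
        raise ValueError(f"window {window_ms} exceeds the epoch ({wave.times[0]}..{wave.times[-1]} ms)")
    mask = (wave.times >= lo - 1e-9) & (wave.times <= hi + 1e-9)
    if mask.sum() < 2:
        raise ValueError(f"window {window_ms} holds fewer than two samples")
    return wave.values[mask], wave.times[mask]


def _segment_negative_integrals(values: np.ndarray, dt: float) -> np.ndarray:
    """Integral of ``min(v, 0)`` over each inter-sample segment of the linear
    interpolant (vectorized over leading axes).  Results are <= 0."""
    v0 = values[..., :-1]
    v1 = values[..., 1:]
    both_neg = (v0 <= 0) & (v1 <= 0)
    trap = 0.5 * dt * (v0 + v1)
    # Sign change inside the segment: only the triangular part below zero counts.
    down = (v0 >= 0) & (v1 < 0)  # crosses downward
    up = (v0 < 0) & (v1 >= 0)    # crosses upward
    denom_down = np.where(down, v1 - v0, 1.0)
    denom_up = np.where(up, v0 - v1, 1.0)
    seg = np.where(both_neg, trap, 0.0)
    seg = np.where(down, 0.5 * dt * v1 * v1 / denom_down, seg)
    seg = np.where(up, 0.5 * dt * v0 * v0 / denom_up, seg)
    return seg


def negative_area_magnitude(values: np.ndarray, dt: float) -> np.ndarray:
    """Magnitude of the negative area (>= 0, uV*ms) of sample arrays; vectorized."""
    return -_segment_negative_integrals(np.asarray(values, dtype=float), dt).sum(axis=-1)


def mean_amplitude(wave: DifferenceWave, window_ms=N2PC_WINDOW_MS) -> MeasureResult:
    """Mean of the difference-wave samples inside the closed window (uV)."""
    values, _ = _window_values(wave, window_ms)
    return MeasureResult(
        measure="mean_amplitude",
        value=float(values.mean()),
        window_ms=tuple(window_ms),
        units="uV",
    )


def signed_negative_area(wave: DifferenceWave, window_ms=BROAD_WINDOW_MS) -> MeasureResult:
    """Integrated magnitude of the negative part of the wave (uV*ms, >= 0).

    Reported as a non-negative magnitude; larger means more negative area.
    """
    values, times = _window_values(wave, window_ms)
    dt = float(times[1] - times[0])
    return MeasureResult(
        measure="signed_negative_area",
        value=float(negative_area_magnitude(values, dt)),
        window_ms=tuple(window_ms),
        units="uV*ms",
    )


def fractional_area_latency(
    wave: DifferenceWave, window_ms=BROAD_WINDOW_MS, fraction: float = 0.5
) -> MeasureResult:
    """Time at which the cumulative negative area reaches ``fraction`` of the total.

    Undefined (``defined=False``) when the window holds no negative area.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    values, times = _window_values(wave, window_ms)
    dt = float(times[1] - times[0])
    seg = _segment_negative_integrals(values, dt)  # <= 0 per segment
    total = seg.sum()
    params = {"fraction": fraction}
    if total >= 0.0 or np.isclose(total, 0.0):
        return MeasureResult("fractional_area_latency", float("nan"), tuple(window_ms),
                             "ms", defined=False, params=params)
    target = fraction * total  # negative
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    k = int(np.searchsorted(-cum, -target, side="left"))  # first boundary with cum <= target
    if k == 0:
        latency = float(times[0])
    elif k > len(seg):
        latency = float(times[-1])
    else:
        c = seg[k - 1]
        frac_in = (target - cum[k - 1]) / c if c < 0 else 1.0
        latency = float(times[k - 1] + dt * frac_in)
    return MeasureResult("fractional_area_latency", latency, tuple(window_ms), "ms",
                         params=params)


def onset_threshold_crossing(
    wave: DifferenceWave,
    threshold_uv: float = ONSET_THRESHOLD_UV,
    window_ms=BROAD_WINDOW_MS,
    n_sustained: int = 1,
    anchor: str = "first",
) -> MeasureResult:
    """Time the wave reaches a negative threshold, linearly interpolated.

    ``anchor="first"`` (default) takes the first sample-pair bracket where
    the wave passes from above to at-or-below threshold; ``n_sustained > 1``
    additionally requires the wave to stay at-or-below threshold for that
    many consecutive samples.  ``anchor="peak"`` walks backward from the
    window's most negative sample to the threshold crossing at the leading
    edge of the component's own sub-threshold run — robust against isolated
    noise dips before the component in noisy grand averages.  Undefined when
    the threshold is never reached inside the window.
    """
    if threshold_uv >= 0:
        raise ValueError("threshold_uv must be negative for an onset of a negativity")
    if anchor not in ("first", "peak"):
        raise ValueError(f"unknown anchor {anchor!r}")
    values, times = _window_values(wave, window_ms)
    below = values <= threshold_uv
    params = {"threshold_uv": threshold_uv, "n_sustained": n_sustained,
              "anchor": anchor}
    if anchor == "peak":
        i_peak = int(np.argmin(values))
        if not below[i_peak]:
            return MeasureResult("onset_latency", float("nan"), tuple(window_ms),
                                 "ms", defined=False, params=params)
        i = i_peak
        while i > 0 and below[i - 1]:
            i -= 1
        hits = np.array([i])
    elif n_sustained > 1:
        runs = np.convolve(below.astype(int), np.ones(n_sustained, dtype=int), "valid")
        hits = np.flatnonzero(runs == n_sustained)
    else:
        hits = np.flatnonzero(below)
    if hits.size == 0:
        return MeasureResult("onset_latency", float("nan"), tuple(window_ms), "ms",
                             defined=False, params=params)
    i = int(hits[0])
    if i == 0:
        latency = float(times[0])
    else:
        v0, v1 = values[i - 1], values[i]
        latency = float(times[i - 1] + (times[i] - times[i - 1]) * (threshold_uv - v0) / (v1 - v0))
    return MeasureResult("onset_latency", latency, tuple(window_ms), "ms", params=params)


# -- jackknife latency inference -------------------------------------------


@dataclass
class JackknifeComparison:
    """Corrected paired contrast between two conditions' jackknife latencies."""

    condition_a: tuple
    condition_b: tuple
    mean_a_ms: float
    mean_b_ms: float
    t_corrected: float
    df: int
    p_value: float
    note: str = ""


@dataclass
class JackknifeLatencyResult:
    """Jackknife onset-latency analysis across conditions.

    ``latencies`` holds per-subsample (leave-one-out) latencies,
    ``full_latency`` the latency of the full grand average, ``scores`` the
    retrieved per-participant values ``n*L_all - (n-1)*L_(-i)``, and
    ``defined`` whether every subsample of a condition reached threshold.
    Conditions failing the threshold are excluded from ``comparisons``.
    """

    latencies: dict
    full_latency: dict
    scores: dict
    defined: dict
    comparisons: list


def jackknife_latency_analysis(
    waves_by_condition: dict,
    threshold_uv: float = ONSET_THRESHOLD_UV,
    window_ms=BROAD_WINDOW_MS,
    anchor: str = "first",
    n_sustained: int = 1,
    measure: str = "threshold_crossing",
    fraction: float = 0.5,
) -> JackknifeLatencyResult:
    """Onset latencies on leave-one-out grand averages with corrected contrasts.

    For each condition (mapping to one :class:`DifferenceWave` per
    participant, participants aligned across conditions), latency is measured
    on every leave-one-out grand average — by default the threshold crossing
    (``measure="threshold_crossing"``; ``anchor``/``n_sustained`` are passed
    through), or the fractional-area latency
    (``measure="fractional_area"`` with ``fraction``), a smoother functional
    that is considerably more stable on noisy grand averages and therefore
    preferable for latency *contrasts* between conditions.  Per-participant
    scores are retrieved by the jackknife back-transformation; paired t
    statistics computed on the subsample latencies are divided by ``n - 1``
    to undo the jackknife variance compression.  Conditions in which any
    subsample fails to reach threshold are flagged and excluded from the
    pairwise contrasts.
    """
    if measure == "threshold_crossing":
        def _latency(w):
            return onset_threshold_crossing(w, threshold_uv, window_ms,
                                            n_sustained, anchor)
    elif measure == "fractional_area":
        def _latency(w):
            return fractional_area_latency(w, window_ms, fraction)
    else:
        raise ValueError(f"unknown latency measure {measure!r}")

    latencies, full_latency, scores, defined = {}, {}, {}, {}
    n_by_cond = {c: len(w) for c, w in waves_by_condition.items()}
    for cond, waves in waves_by_condition.items():
        n = len(waves)
        loo = jackknife_grand_averages(waves)
        lat = np.array([_latency(w).value for w in loo])
        full = _latency(grand_average(waves))
        latencies[cond] = lat
        full_latency[cond] = full.value
        defined[cond] = bool(np.all(np.isfinite(lat)) and full.defined)
        scores[cond] = (
            n * full.value - (n - 1) * lat if defined[cond] else np.full(n, np.nan)
        )

    comparisons = []
    usable = [c for c in waves_by_condition if defined[c]]
    for a, b in itertools.combinations(usable, 2):
        if n_by_cond[a] != n_by_cond[b]:
            continue
        n = n_by_cond[a]
        d = latencies[a] - latencies[b]
        sd = d.std(ddof=1)
        note = ""
        if sd == 0.0:
            t_c, p = (float("nan"), float("nan"))
            note = "zero variance across subsamples; corrected t undefined"
        else:
            t_sub = d.mean() / (sd / np.sqrt(n))
            t_c = float(t_sub / (n - 1))
            p = float(2.0 * stats.t.sf(abs(t_c), df=n - 1))
        comparisons.append(
            JackknifeComparison(
                condition_a=a,
                condition_b=b,
                mean_a_ms=float(np.mean(latencies[a])),
                mean_b_ms=float(np.mean(latencies[b])),
                t_corrected=t_c,
                df=n - 1,
                p_value=p,
                note=note,
            )
        )
    return JackknifeLatencyResult(
        latencies=latencies,
        full_latency=full_latency,
        scores=scores,
        defined=defined,
        comparisons=comparisons,
    )
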