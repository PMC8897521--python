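"""Synthetic EEG and behavior with known ground-truth component parameters.

Because the study's recordings are not deposited, every downstream stage is
validated against simulated data in which the lateralized component is known
exactly.  For each non-Target-Absent trial a negative raised-cosine
deflection is injected into the posterior channel *contralateral* to the
search item (PO8 for left items, PO7 for right items) and nothing into the
ipsilateral channel; 1/f-plus-white Gaussian noise is added to all channels;
and with a configurable probability an ocular excursion exceeding the
artifact-rejection thresholds is injected into HEOG or VEOG, with the
injected-artifact flag recorded as ground truth.

Default parameters define the reference simulation conditions used
throughout the test-suite and the acceptance analyses: component amplitude
-2 uV (Exemplar Match) / -0.5 uV (Foil), onsets 180 ms (patterned side) and
240 ms (random side) with a 200 ms raised-cosine width, per-sample noise
SD 10 uV, 500 Hz sampling on a -100..500 ms epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import EpochSet
from .design import RESPONSE_DEADLINE_MS, SCHEDULE_COLUMNS

__all__ = [
    "DEFAULT_CHANNELS",
    "SCALP_CHANNELS",
    "ComponentParams",
    "GroundTruth",
    "RTModel",
    "raised_cosine",
    "pink_white_noise",
    "simulate_epochs",
    "simulate_behavior",
    "simulate_2afc",
]

#: 30 scalp electrodes (extended 10/20 positions) used for decoding features.
SCALP_CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "PO4", "PO8", "Oz",
)

#: Full simulated montage: scalp + ocular channels + earlobe references.
DEFAULT_CHANNELS = SCALP_CHANNELS + ("HEOG", "VEOG", "A1", "A2")

#: Minimal montage for analyses that only need the lateralized pair.
MINIMAL_CHANNELS = ("PO7", "PO8", "HEOG", "VEOG", "A1", "A2")

ANALYSIS_CONDITIONS = (
    ("patterned", "exemplar_match"),
    ("random", "exemplar_match"),
    ("patterned", "foil"),
    ("random", "foil"),
)


@dataclass(frozen=True)
class ComponentParams:
    """Ground-truth parameters for one analysis condition.

    ``amplitude_uv`` is the (non-positive) peak of the injected contralateral
    negativity, ``onset_ms``/``width_ms`` place the raised-cosine pulse,
    ``noise_sd_uv`` is the per-sample noise standard deviation and
    ``artifact_rate`` the probability of injecting an ocular artifact.
    """

    amplitude_uv: float = -2.0
    onset_ms: float = 180.0
    width_ms: float = 200.0
    noise_sd_uv: float = 10.0
    artifact_rate: float = 0.0

    def __post_init__(self):
        if self.amplitude_uv > 0:
            raise ValueError("amplitude_uv must be <= 0 (negative-going component)")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be >= 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Per-condition component parameters plus global noise shaping.

    ``conditions`` maps ``(symbol_position, trial_type)`` over
    {patterned, random} x {exemplar_match, foil}; ``absent`` parameterizes
    Target Absent trials (no lateralized signal, noise/artifacts only).
    ``pink_fraction`` is the share of noise variance given to 1/f-shaped
    noise (the rest is white).
    """

    conditions: dict = field(default_factory=dict)
    absent: ComponentParams = ComponentParams(amplitude_uv=0.0)
    pink_fraction: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.pink_fraction <= 1.0:
            raise ValueError("pink_fraction must be in [0, 1]")

    @classmethod
    def default(
        cls,
        noise_sd_uv: float = 10.0,
        artifact_rate: float = 0.0,
        pink_fraction: float = 0.5,
    ) -> "GroundTruth":
        """Reference conditions: target component -2 uV, foil -0.5 uV; onset
        180 ms on the patterned side vs 240 ms on the random side."""
        base = ComponentParams(noise_sd_uv=noise_sd_uv, artifact_rate=artifact_rate)
        conditions = {
            ("patterned", "exemplar_match"): replace(base, amplitude_uv=-2.0, onset_ms=180.0),
            ("random", "exemplar_match"): replace(base, amplitude_uv=-2.0, onset_ms=240.0),
            ("patterned", "foil"): replace(base, amplitude_uv=-0.5, onset_ms=180.0),
            ("random", "foil"): replace(base, amplitude_uv=-0.5, onset_ms=240.0),
        }
        return cls(
            conditions=conditions,
            absent=replace(base, amplitude_uv=0.0),
            pink_fraction=pink_fraction,
        )

    @classmethod
    def null(cls, noise_sd_uv: float = 10.0, pink_fraction: float = 0.5,
             artifact_rate: float = 0.0) -> "GroundTruth":
        """Noise-only conditions: zero component everywhere (exchangeable labels)."""
        p = ComponentParams(amplitude_uv=0.0, noise_sd_uv=noise_sd_uv,
                            artifact_rate=artifact_rate)
        return cls(
            conditions={c: p for c in ANALYSIS_CONDITIONS},
            absent=p,
            pink_fraction=pink_fraction,
        )

    def lookup(self, symbol_position: str, trial_type: str) -> ComponentParams:
        if trial_type == "target_absent":
            return self.absent
        try:
            return self.conditions[(symbol_position, trial_type)]
        except KeyError:
            raise ValueError(
                f"ground truth lacks parameters for condition "
                f"({symbol_position!r}, {trial_type!r})"
            ) from None


def raised_cosine(times_ms: np.ndarray, onset_ms: float, width_ms: float,
                  amplitude_uv: float) -> np.ndarray:
    """Raised-cosine pulse: ``a/2 * (1 - cos(2*pi*(t-onset)/width))`` on
    ``[onset, onset+width]``, zero elsewhere.  Peak value = ``amplitude_uv``
    at ``onset + width/2``."""
    t = np.asarray(times_ms, dtype=float)
    phase = (t - onset_ms) / width_ms
    pulse = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return np.where((phase >= 0.0) & (phase <= 1.0), amplitude_uv * pulse, 0.0)


def pink_white_noise(rng: np.random.Generator, shape: tuple, sd_uv: float,
                     pink_fraction: float = 0.5) -> np.ndarray:
    """Gaussian noise with a white + 1/f-shaped mixture along the last axis.

    The 1/f component is built by shaping a white spectrum with f^(-1/2)
    amplitude weights (1/f power), normalized per trace to unit SD; the
    mixture allocates ``pink_fraction`` of the variance to it.
    """
    if sd_uv == 0.0:
        return np.zeros(shape)
    n = shape[-1]
    white = rng.standard_normal(shape)
    if pink_fraction == 0.0 or n < 4:
        return sd_uv * white
    spec = np.fft.rfft(rng.standard_normal(shape), axis=-1)
    freqs = np.fft.rfftfreq(n)
    weights = np.zeros_like(freqs)
    weights[1:] = freqs[1:] ** -0.5
    pink = np.fft.irfft(spec * weights, n=n, axis=-1)
    pink_sd = pink.std(axis=-1, keepdims=True)
    pink = pink / np.where(pink_sd == 0, 1.0, pink_sd)
    return sd_uv * (
        np.sqrt(1.0 - pink_fraction) * white + np.sqrt(pink_fraction) * pink
    )


# Ocular artifact amplitudes (uV), chosen to exceed the rejection thresholds
# (25 uV HEOG / 60 uV VEOG) with a wide margin so that thresholding recovers
# the injected set exactly even after filtering.
_ARTIFACT_AMPLITUDE = {"HEOG": 60.0, "VEOG": 100.0}


def simulate_epochs(
    schedule: pd.DataFrame,
    truth: GroundTruth,
    seed=0,
    channels: tuple = DEFAULT_CHANNELS,
    sfreq: float = 500.0,
    tmin_ms: float = -100.0,
    tmax_ms: float = 500.0,
) -> EpochSet:
    """Simulate an epoched recording for one participant's schedule.

    Signal: per non-Target-Absent trial a raised-cosine negativity (per-
    condition amplitude/onset/width) in the channel contralateral to
    ``item_side``; nothing in the ipsilateral channel.  Noise: independent
    pink+white Gaussian noise in every channel.  Artifacts: with probability
    ``artifact_rate`` a 100 ms boxcar excursion on HEOG or VEOG (coin flip)
    within 0-300 ms; flags land in the trial table columns
    ``injected_artifact`` / ``artifact_channel``.
    """
    for ch in ("PO7", "PO8", "HEOG", "VEOG"):
        if ch not in channels:
            raise ValueError(f"simulated montage must include {ch}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dt = 1000.0 / sfreq
    n_samples = int(round((tmax_ms - tmin_ms) / dt)) + 1
    times = tmin_ms + dt * np.arange(n_samples)

    n_trials = len(schedule)
    ch_idx = {c: i for i, c in enumerate(channels)}
    data = np.zeros((n_trials, len(channels), n_samples))

    # Deterministic signal.
    for i, row in enumerate(schedule.itertuples(index=False)):
        params = truth.lookup(row.symbol_position, row.trial_type)
        if row.trial_type == "target_absent" or params.amplitude_uv == 0.0:
            continue
        if params.onset_ms + params.width_ms > tmax_ms + 1e-9 or params.onset_ms < tmin_ms:
            raise ValueError(
                f"component ({params.onset_ms}+{params.width_ms} ms) exceeds the epoch window"
            )
        contra = "PO8" if row.item_side == "left" else "PO7"
        data[i, ch_idx[contra], :] += raised_cosine(
            times, params.onset_ms, params.width_ms, params.amplitude_uv
        )

    # Noise: per-trial noise SD follows the trial's condition parameters.
    noise_sd = np.array(
        [truth.lookup(r.symbol_position, r.trial_type).noise_sd_uv
         for r in schedule.itertuples(index=False)]
    )
    if np.any(noise_sd > 0):
        noise = pink_white_noise(
            rng, (n_trials, len(channels), n_samples), 1.0, truth.pink_fraction
        )
        data += noise * noise_sd[:, None, None]

    # Ocular artifacts with ground-truth flags.
    rates = np.array(
        [truth.lookup(r.symbol_position, r.trial_type).artifact_rate
         for r in schedule.itertuples(index=False)]
    )
    inject = rng.random(n_trials) < rates
    art_channel = np.full(n_trials, "", dtype=object)
    for i in np.flatnonzero(inject):
        ch = "HEOG" if rng.random() < 0.5 else "VEOG"
        art_channel[i] = ch
        center = rng.uniform(75.0, 225.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        mask = (times >= center - 50.0) & (times <= center + 50.0)
        data[i, ch_idx[ch], mask] += sign * _ARTIFACT_AMPLITUDE[ch]

    trials = schedule.reset_index(drop=True).copy()
    trials["injected_artifact"] = inject
    trials["artifact_channel"] = art_channel
    return EpochSet(data=data, channels=list(channels), times=times, sfreq=sfreq, trials=trials)


@dataclass(frozen=True)
class RTModel:
    """Log-normal RT and Bernoulli accuracy per trial type.

    ``mean_ms``/``sd_ms`` parameterize the log-normal by its mean and SD
    (moment matching); ``p_correct`` is the per-type accuracy.  Defaults make
    Exemplar Match responses faster than Foil responses, mirroring the
    behavioral structure of the task.
    """

    mean_ms: dict = field(
        default_factory=lambda: {"exemplar_match": 616.0, "foil": 660.0, "target_absent": 660.0}
    )
    sd_ms: dict = field(
        default_factory=lambda: {"exemplar_match": 150.0, "foil": 160.0, "target_absent": 160.0}
    )
    p_correct: dict = field(
        default_factory=lambda: {"exemplar_match": 0.95, "foil": 0.95, "target_absent": 0.95}
    )
    deadline_ms: float = RESPONSE_DEADLINE_MS

    def __post_init__(self):
        for t, p in self.p_correct.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_correct[{t!r}]={p} outside [0, 1]")


#: The correct present/absent answer per trial type (the target itself only
#: appears on Exemplar Match trials).
_CORRECT_ANSWER = {"exemplar_match": "present", "foil": "absent", "target_absent": "absent"}


def simulate_behavior(schedule: pd.DataFrame, rt_model: RTModel | None = None,
                      seed=0) -> pd.DataFrame:
    """Fill a schedule's ``response``/``correct``/``rt_ms`` columns.

    RTs are sampled per trial type from a moment-matched log-normal; a
    sampled RT beyond the deadline yields no response (``response='none'``,
    ``rt_ms`` missing, ``correct=False``).
    """
    rt_model = rt_model or RTModel()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = schedule.reset_index(drop=True).copy()
    responses, corrects, rts = [], [], []
    for row in out.itertuples(index=False):
        mean = rt_model.mean_ms[row.trial_type]
        sd = rt_model.sd_ms[row.trial_type]
        sigma2 = np.log1p((sd / mean) ** 2)
        rt = float(rng.lognormal(np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)))
        if rt > rt_model.deadline_ms:
            responses.append("none")
            corrects.append(False)
            rts.append(np.nan)
            continue
        answer = _CORRECT_ANSWER[row.trial_type]
        is_correct = bool(rng.random() < rt_model.p_correct[row.trial_type])
        responses.append(answer if is_correct else ("absent" if answer == "present" else "present"))
        corrects.append(is_correct)
        rts.append(rt)
    out["response"] = responses
    out["correct"] = corrects
    out["rt_ms"] = rts
    return out


def simulate_2afc(
    n_trials: int = 60,
    p_correct: float = 0.5,
    seed=0,
    confidence_probs: tuple = (0.1, 0.3, 0.4, 0.2),
) -> pd.DataFrame:
    """Simulate a two-alternative forced-choice recognition block.

    Choices are i.i.d. Bernoulli(``p_correct``); confidence ratings (1-4)
    follow ``confidence_probs``.  Returns a DataFrame with columns
    ``correct`` (bool) and ``confidence`` (int).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 <= p_correct <= 1.0:
        raise ValueError("p_correct must be in [0, 1]")
    probs = np.asarray(confidence_probs, dtype=float)
    if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
        raise ValueError("confidence_probs must be a probability vector over 1..4")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return pd.DataFrame(
        {
            "correct": rng.random(n_trials) < p_correct,
            "confidence": rng.choice(np.arange(1, len(probs) + 1), size=n_trials, p=probs),
        }
    )
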