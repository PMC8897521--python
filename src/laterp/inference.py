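"""Resampling inference: signed-area permutation, cluster t-mass, bootstrapped SME.

Three procedures tailored to lateralized-ERP analyses:

* :func:`signed_area_permutation_test` — within-participant shuffling of the
  symbol-position label (separately for Exemplar Match and Foil trials),
  rebuilding the grand-average difference wave per permutation and measuring
  its signed negative area; significance by the 95th-percentile rule with
  add-one p-values ``(b + 1) / (N + 1)``.
* :func:`cluster_t_mass` / :func:`cluster_permutation_null` — per-time-point
  one-sample t tests against chance, maximal runs of significant points
  scored by their summed t (cluster t mass) and referred to a permutation
  null of maximal masses.
* :func:`bootstrap_sme` — bootstrapped standardized measurement error: the
  standard deviation of an ERP measure across with-replacement resamples of
  one participant's trials, aggregated across participants by
  :func:`rms_aggregate` (root mean square).

All procedures are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import EpochSet
from .measures import (
    BROAD_WINDOW_MS,
    fractional_area_latency,
    negative_area_magnitude,
)
from .waveforms import DifferenceWave, lateralized_trial_traces

__all__ = [
    "PermutationResult",
    "Cluster",
    "ClusterResult",
    "SMEResult",
    "percentile_criterion",
    "signed_area_permutation_test",
    "cluster_t_mass",
    "cluster_permutation_null",
    "bootstrap_sme",
    "rms_aggregate",
]

ANALYSIS_CONDITIONS = (
    ("patterned", "exemplar_match"),
    ("random", "exemplar_match"),
    ("patterned", "foil"),
    ("random", "foil"),
)


# -- permutation machinery --------------------------------------------------


@dataclass
class PermutationResult:
    """An observed statistic with its permutation null distribution."""

    observed: float
    null_distribution: np.ndarray
    p_value: float
    criterion_percentile: float
    critical_value: float
    significant: bool
    n_permutations: int
    seed: int | None = None
    condition: tuple | None = None


def percentile_criterion(
    observed: float, null_distribution, percentile: float = 95.0
) -> tuple[bool, float]:
    """Significance by the nearest-rank percentile rule with an add-one p.

    ``significant`` iff the observed value exceeds the nearest-rank
    ``percentile`` of the null; ``p = (b + 1) / (N + 1)`` where ``b`` counts
    permuted values at least as large as the observed one.
    """
    null = np.asarray(null_distribution, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    if np.any(np.isnan(null)) or np.isnan(observed):
        raise ValueError("NaN in observed value or null distribution")
    rank = int(np.ceil(percentile / 100.0 * null.size))
    critical = float(np.sort(null)[max(rank, 1) - 1])
    b = int(np.sum(null >= observed))
    p = (b + 1) / (null.size + 1)
    return bool(observed > critical), float(p)


def signed_area_permutation_test(
    participants: list,
    window_ms=BROAD_WINDOW_MS,
    n_permutations: int = 500,
    seed: int = 0,
    percentile: float = 95.0,
    shuffle_within_trial_type: bool = True,
) -> dict:
    """Permutation test of the signed negative area of grand-average difference waves.

    ``participants`` is a list of :class:`~laterp.containers.EpochSet`
    (analysis-ready: correct, lateralized trials only).  For each of the four
    ``(symbol_position, trial_type)`` conditions the observed statistic is
    the signed negative area (over ``window_ms``) of the across-participant
    grand average of per-condition contra-minus-ipsi difference waves.  Each
    permutation randomly reassigns the symbol-position label to trials within
    each participant — separately within Exemplar Match and Foil trials when
    ``shuffle_within_trial_type`` (the default; set False to exchange labels
    jointly across trial types) — and recomputes all four grand-average
    areas, building one null distribution per condition.

    Because the patterned stream's side is fixed within a participant, the
    symbol-position label of a trial is one-to-one with its item side; a
    reassigned label therefore also reassigns the *presumed* item side, which
    swaps the contralateral/ipsilateral channels and flips the sign of the
    trial's lateralized trace.  Misassigned trials thus cancel the component
    while trial noise is preserved — the null estimates noise with the signal
    subtracted, and a genuinely lateralized negativity exceeds it.

    Participants lacking both labels within a shuffled stratum are excluded
    with a warning.  Returns ``{condition: PermutationResult}``.
    """
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} gives a coarse p-value grid", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    # shuffling strata: the lateralized trial types actually present
    present = set()
    for ep in participants:
        present |= set(ep.trials["trial_type"].unique())
    trial_types = sorted(present & {c[1] for c in ANALYSIS_CONDITIONS})
    if not trial_types:
        raise ValueError("no lateralized analysis trials (exemplar_match/foil) present")
    conditions = [c for c in ANALYSIS_CONDITIONS if c[1] in trial_types]

    # Per participant and trial type: window-restricted lateralized traces +
    # patterned-label vector.
    prepared = []
    ref_times = None
    for i, ep in enumerate(participants):
        mask = ep.time_mask(window_ms)
        times = ep.times[mask]
        if ref_times is None:
            ref_times = times
        elif times.shape != ref_times.shape or not np.allclose(times, ref_times):
            raise ValueError("participants do not share a common time axis")
        traces = lateralized_trial_traces(ep)[:, mask]
        ttypes = ep.trials["trial_type"].to_numpy()
        labels = ep.trials["symbol_position"].to_numpy() == "patterned"
        # pattern-side-referenced traces: +trace for patterned trials,
        # -trace for random trials (label determines the presumed side)
        signed = np.where(labels[:, None], traces, -traces)
        per_type = {}
        ok = True
        for tt in trial_types:
            sel = ttypes == tt
            lab = labels[sel]
            if sel.sum() == 0 or lab.all() or not lab.any():
                warnings.warn(
                    f"participant {i} lacks one symbol-position label for {tt}; excluded",
                    stacklevel=2,
                )
                ok = False
                break
            per_type[tt] = (signed[sel], lab)
        if ok:
            prepared.append(per_type)
    if len(prepared) < 2:
        raise ValueError("need at least two participants with both labels in every trial type")
    n_parts = len(prepared)
    dt = float(ref_times[1] - ref_times[0])
    n_w = ref_times.size

    # Observed and permuted grand averages, accumulated per condition.
    observed_sum = {c: np.zeros(n_w) for c in conditions}
    null_sum = {c: np.zeros((n_permutations, n_w)) for c in conditions}
    for per_type in prepared:
        if not shuffle_within_trial_type:
            # Joint shuffling: permute labels across the pooled trials, then
            # split back into the original trial-type strata.
            pooled = np.concatenate([per_type[tt][1] for tt in trial_types])
            perms = rng.permuted(
                np.tile(pooled, (n_permutations, 1)), axis=1
            )
            offsets = np.cumsum([0] + [len(per_type[tt][1]) for tt in trial_types])
        for j, tt in enumerate(trial_types):
            T, lab = per_type[tt]
            k = int(lab.sum())
            n = len(lab)
            # a trial assigned "patterned" enters that bin as +trace; one
            # assigned "random" enters the random bin as -trace (its presumed
            # side, hence contra/ipsi assignment, is the opposite one)
            observed_sum[("patterned", tt)] += lab @ T / k
            observed_sum[("random", tt)] += -((~lab) @ T) / (n - k)
            if shuffle_within_trial_type:
                B = rng.permuted(np.tile(lab, (n_permutations, 1)), axis=1)
            else:
                B = perms[:, offsets[j]:offsets[j + 1]]
            kk = B.sum(axis=1, keepdims=True).astype(float)
            null_sum[("patterned", tt)] += (B @ T) / kk
            null_sum[("random", tt)] += -((~B) @ T) / (n - kk)

    results = {}
    for cond in conditions:
        observed = float(negative_area_magnitude(observed_sum[cond] / n_parts, dt))
        null = negative_area_magnitude(null_sum[cond] / n_parts, dt)
        significant, p = percentile_criterion(observed, null, percentile)
        rank = int(np.ceil(percentile / 100.0 * n_permutations))
        results[cond] = PermutationResult(
            observed=observed,
            null_distribution=null,
            p_value=p,
            criterion_percentile=percentile,
            critical_value=float(np.sort(null)[rank - 1]),
            significant=significant,
            n_permutations=n_permutations,
            seed=seed,
            condition=cond,
        )
    return results


# -- cluster-level t mass ---------------------------------------------------


@dataclass
class Cluster:
    """A maximal run of contiguous significant time points."""

    start_ms: float
    end_ms: float
    t_mass: float
    p_value: float | None = None
    significant: bool | None = None


@dataclass
class ClusterResult:
    """Observed clusters with (optionally) their permutation null."""

    clusters: list
    t_values: np.ndarray
    times: np.ndarray
    alpha: float
    null_t_mass: np.ndarray | None = None
    critical_t_mass: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


def _pointwise_t(acc: np.ndarray, chance: float) -> np.ndarray:
    """One-sample t per time point (one-tailed, above chance); zero-variance
    points get +inf when above chance, 0 otherwise (flagged by a warning)."""
    n = acc.shape[0]
    m = acc.mean(axis=0)
    s = acc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m - chance) / (s / np.sqrt(n))
    degenerate = s == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} time points have zero variance across participants",
            stacklevel=3,
        )
        t = np.where(degenerate & (m > chance), np.inf, t)
        t = np.where(degenerate & (m <= chance), 0.0, t)
    return t


def _runs(mask: np.ndarray):
    """Start/stop index pairs of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2] - 1))


def cluster_t_mass(
    accuracies: np.ndarray,
    times: np.ndarray,
    chance: float = 0.5,
    alpha: float = 0.05,
) -> ClusterResult:
    """Observed clusters of above-chance time points and their t masses.

    ``accuracies`` has shape ``(n_participants, n_timepoints)``.  A point is
    significant when its one-tailed one-sample t (against ``chance``) has
    ``p < alpha``; clusters are maximal runs of significant points and
    ``t_mass`` sums the t values inside each run.
    """
    acc = np.asarray(accuracies, dtype=float)
    if acc.ndim != 2 or acc.shape[0] < 3:
        raise ValueError("accuracies must be (n_participants >= 3, n_timepoints)")
    times = np.asarray(times, dtype=float)
    if times.shape != (acc.shape[1],):
        raise ValueError("time axis does not match the accuracy series")
    t = _pointwise_t(acc, chance)
    t_crit = stats.t.isf(alpha, df=acc.shape[0] - 1)
    sig = t > t_crit
    clusters = [
        Cluster(start_ms=float(times[a]), end_ms=float(times[b]),
                t_mass=float(t[a : b + 1].sum()))
        for a, b in _runs(sig)
    ]
    return ClusterResult(clusters=clusters, t_values=t, times=times, alpha=alpha)


def _max_cluster_mass(acc: np.ndarray, chance: float, alpha: float) -> float:
    n = acc.shape[0]
    m = acc.mean(axis=0)
    s = acc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(s > 0, (m - chance) / (s / np.sqrt(n)), 0.0)
    sig = t > stats.t.isf(alpha, df=n - 1)
    best = 0.0
    for a, b in _runs(sig):
        best = max(best, float(t[a : b + 1].sum()))
    return best


def cluster_permutation_null(
    accuracies: np.ndarray,
    times: np.ndarray,
    chance: float = 0.5,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
    n_attempts: int = 60,
    null_sampler=None,
) -> ClusterResult:
    """Cluster inference with a permutation null of maximal t masses.

    By default each iteration draws a chance-level surrogate accuracy matrix
    — per participant and time point, ``Binomial(n_attempts, chance) /
    n_attempts``, the Monte-Carlo model of a decoder scoring ``n_attempts``
    attempts on exchangeable labels — and records its maximal cluster t mass.
    Pass ``null_sampler`` (a callable ``rng -> accuracy matrix``, e.g. one
    that re-runs the decoder with permuted class labels) for an exact
    label-exchange null.  Cluster p-values are add-one proportions of null
    masses at least as large as the observed mass; ``critical_t_mass`` is the
    95th percentile (nearest rank) of the null.
    """
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} gives a coarse p-value grid", stacklevel=2
        )
    observed = cluster_t_mass(accuracies, times, chance, alpha)
    acc = np.asarray(accuracies, dtype=float)
    n_parts, n_points = acc.shape
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        surrogate = (
            null_sampler(rng)
            if null_sampler is not None
            else rng.binomial(n_attempts, chance, size=(n_parts, n_points)) / n_attempts
        )
        null[i] = _max_cluster_mass(np.asarray(surrogate, dtype=float), chance, alpha)
    rank = int(np.ceil(0.95 * n_permutations))
    critical = float(np.sort(null)[rank - 1])
    for cl in observed.clusters:
        b = int(np.sum(null >= cl.t_mass))
        cl.p_value = (b + 1) / (n_permutations + 1)
        cl.significant = bool(cl.t_mass > critical)
    observed.null_t_mass = null
    observed.critical_t_mass = critical
    observed.n_permutations = n_permutations
    observed.seed = seed
    return observed


# -- bootstrapped standardized measurement error ----------------------------


@dataclass
class SMEResult:
    """Bootstrapped standardized measurement error for one participant/condition."""

    bsme: float
    measure: str
    n_trials: int
    n_bootstrap: int
    n_undefined: int = 0
    defined: bool = True
    participant_id: str = ""
    condition: tuple | None = None


def bootstrap_sme(
    trial_waves: np.ndarray,
    times: np.ndarray,
    measure: str = "mean_amplitude",
    window_ms=None,
    n_bootstrap: int = 10000,
    seed: int = 0,
    fraction: float = 0.5,
) -> SMEResult:
    """Bootstrapped SME of an ERP measure for one participant and condition.

    ``trial_waves`` holds the single-trial difference traces
    ``(n_trials, n_samples)``.  Each bootstrap iteration draws ``n_trials``
    trials with replacement, averages them and applies the measure
    (``mean_amplitude``, ``signed_negative_area`` or
    ``fractional_area_latency``); the bSME is the standard deviation of the
    resulting values.  Iterations in which a latency measure is undefined are
    dropped and counted in ``n_undefined``.
    """
    trial_waves = np.asarray(trial_waves, dtype=float)
    if trial_waves.ndim != 2 or trial_waves.shape[0] < 2:
        raise ValueError("need at least two trials (n_trials, n_samples)")
    times = np.asarray(times, dtype=float)
    n_trials = trial_waves.shape[0]
    if window_ms is None:
        window_ms = (200.0, 300.0) if measure == "mean_amplitude" else BROAD_WINDOW_MS
    lo, hi = window_ms
    mask = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    if mask.sum() < 2:
        raise ValueError(f"window {window_ms} holds fewer than two samples")
    wtimes = times[mask]
    dt = float(wtimes[1] - wtimes[0])

    rng = np.random.default_rng(seed)
    # Gather-and-mean (chunked) rather than a weighted matmul: identical
    # trials then yield bitwise-identical bootstrap averages, so zero
    # between-trial variance gives bsme = 0 exactly.
    windowed = trial_waves[:, mask]
    boot_waves = np.empty((n_bootstrap, windowed.shape[1]))
    chunk = 256
    for start in range(0, n_bootstrap, chunk):
        stop = min(start + chunk, n_bootstrap)
        idx = rng.integers(0, n_trials, size=(stop - start, n_trials))
        boot_waves[start:stop] = windowed[idx].mean(axis=1)

    if measure == "mean_amplitude":
        values = boot_waves.mean(axis=1)
    elif measure == "signed_negative_area":
        values = negative_area_magnitude(boot_waves, dt)
    elif measure == "fractional_area_latency":
        values = np.array(
            [
                fractional_area_latency(
                    DifferenceWave(values=w, times=wtimes), window_ms, fraction
                ).value
                for w in boot_waves
            ]
        )
    else:
        raise ValueError(f"unknown measure {measure!r}")

    finite = np.isfinite(values)
    n_undefined = int((~finite).sum())
    if finite.sum() < 2:
        return SMEResult(
            bsme=float("nan"),
            measure=measure,
            n_trials=n_trials,
            n_bootstrap=n_bootstrap,
            n_undefined=n_undefined,
            defined=False,
        )
    return SMEResult(
        bsme=float(values[finite].std(ddof=1)),
        measure=measure,
        n_trials=n_trials,
        n_bootstrap=n_bootstrap,
        n_undefined=n_undefined,
    )


def rms_aggregate(bsme_values) -> float:
    """Root mean square of per-participant bSME values (the group aggregate)."""
    values = np.asarray(list(bsme_values), dtype=float)
    if values.size == 0:
        raise ValueError("no bSME values to aggregate")
    if np.any(values < 0) or np.any(np.isnan(values)):
        raise ValueError("bSME values must be non-negative and defined")
    return float(np.sqrt(np.mean(values**2)))


def sme_from_epochs(
    epochs: EpochSet,
    measure: str,
    window_ms=None,
    n_bootstrap: int = 10000,
    seed: int = 0,
    participant_id: str = "",
) -> dict:
    """Per-condition bootstrap SME for one participant's analysis-ready epochs."""
    out = {}
    traces = lateralized_trial_traces(epochs)
    meta = epochs.trials
    for i, cond in enumerate(ANALYSIS_CONDITIONS):
        pos, tt = cond
        sel = (meta["symbol_position"].to_numpy() == pos) & (
            meta["trial_type"].to_numpy() == tt
        )
        if sel.sum() < 2:
            continue
        res = bootstrap_sme(
            traces[sel], epochs.times, measure, window_ms, n_bootstrap, seed + i
        )
        res.participant_id = participant_id
        res.condition = cond
        out[cond] = res
    return out
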