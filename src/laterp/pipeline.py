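"""End-to-end orchestration: a study object fitted into a results object.

:class:`N2pcStudy` bundles per-participant epoched recordings (simulated via
:meth:`N2pcStudy.from_config`, or supplied from files) with an
:class:`AnalysisConfig` of every pipeline constant.  :meth:`N2pcStudy.fit`
runs preprocessing, lateralized waveforms, component measures, the
signed-area permutation test, the jackknife latency analysis, time-resolved
decoding with cluster inference, bootstrapped SME data quality, and the
behavioral/2AFC summaries, returning an :class:`N2pcResults` whose
``summary()`` prints the whole analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding as _decoding
from . import inference as _inference
from . import measures as _measures
from . import preprocessing as _preprocessing
from . import stats as _stats
from . import waveforms as _waveforms
from .containers import EpochSet
from .design import TrialCounts, generate_design
from .synth import (
    DEFAULT_CHANNELS,
    MINIMAL_CHANNELS,
    GroundTruth,
    RTModel,
    simulate_2afc,
    simulate_behavior,
    simulate_epochs,
)

__all__ = ["AnalysisConfig", "N2pcStudy", "N2pcResults"]

CONDITIONS = _inference.ANALYSIS_CONDITIONS


@dataclass
class AnalysisConfig:
    """Every pipeline constant in one serializable object.

    Analysis defaults follow the study design (500 Hz sampling, -100..500 ms
    epochs, -100..0 ms baseline, 25/60/80 uV rejection thresholds, 200-300 ms
    N2pc window, 150-300 ms broad window, -0.75 uV onset threshold, 50% area
    fraction, 500 permutations, 3-fold x 10-iteration decoding).  The cluster
    permutation count and bootstrap count default to desk-scale values (1000
    and 2000); the study-scale 10000 is one assignment away.
    """

    seed: int = 0
    # acquisition / epoching
    sampling_rate_hz: float = 500.0
    epoch_ms: tuple = (-100.0, 500.0)
    baseline_ms: tuple = (-100.0, 0.0)
    # measurement windows and thresholds
    n2pc_window_ms: tuple = (200.0, 300.0)
    broad_window_ms: tuple = (150.0, 300.0)
    onset_threshold_uv: float = -0.75
    area_fraction: float = 0.5
    # resampling
    n_permutations: int = 500
    n_cluster_permutations: int = 1000
    n_bootstrap: int = 2000
    alpha: float = 0.05
    # decoding
    n_folds: int = 3
    n_iterations: int = 10
    run_decoding: bool = True
    # synthetic cohort
    n_participants: int = 19
    n_blocks: int = 7
    trials_per_block: tuple = (28, 28, 4)
    noise_sd_uv: float = 10.0
    artifact_rate: float = 0.05
    montage: str = "full"  # "full" (30 scalp + EOG + earlobes) or "minimal"
    twoafc_p_correct: float = 0.51
    twoafc_n_trials: int = 60

    def channels(self) -> tuple:
        return DEFAULT_CHANNELS if self.montage == "full" else MINIMAL_CHANNELS

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration, embedded in every output."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("epoch_ms", "baseline_ms", "n2pc_window_ms", "broad_window_ms",
                    "trials_per_block"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class N2pcResults:
    """Fitted study results.

    Attributes hold tidy tables and result objects from every stage; use
    :meth:`summary` for a readable report and :meth:`save` to write the
    bundle (CSV tables + JSON summary) to a directory.
    """

    config: AnalysisConfig
    measures_table: pd.DataFrame
    grand_averages: dict
    permutation: dict
    jackknife: object
    fractional_anova: dict | None
    amplitude_anova: dict | None
    decoding_window: dict
    decoding_clusters: dict
    sme_table: pd.DataFrame
    behavioral: pd.DataFrame | None
    rt_anova: dict | None
    twoafc: object | None
    retention: pd.DataFrame

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Lateralized ERP (N2pc) analysis",
            "=" * 34,
            f"config digest: {cfg.digest()}   seed: {cfg.seed}",
            f"participants: {self.retention.shape[0]}",
            "",
            "Trial retention (per participant mean): "
            f"{self.retention['retained'].mean():.1f} of {self.retention['total'].mean():.1f}",
            "",
            f"Mean amplitude, {cfg.n2pc_window_ms[0]:.0f}-{cfg.n2pc_window_ms[1]:.0f} ms (uV):",
        ]
        amp = self.measures_table[self.measures_table["measure"] == "mean_amplitude"]
        for (pos, tt), grp in amp.groupby(["symbol_position", "trial_type"]):
            lines.append(
                f"  {tt:>14} / {pos:<9} M = {grp['value'].mean():7.3f}  SD = {grp['value'].std(ddof=1):.3f}"
            )
        lines += ["", f"Signed negative area permutation test "
                      f"({cfg.broad_window_ms[0]:.0f}-{cfg.broad_window_ms[1]:.0f} ms, "
                      f"{cfg.n_permutations} permutations):"]
        for cond, res in self.permutation.items():
            lines.append(
                f"  {cond[1]:>14} / {cond[0]:<9} area = {res.observed:8.2f} uV*ms  "
                f"p = {res.p_value:.4f}  {'significant' if res.significant else 'n.s.'}"
            )
        if self.jackknife is not None:
            lines += ["", f"Jackknife onset latency ({cfg.onset_threshold_uv} uV threshold):"]
            for cond, lat in self.jackknife.full_latency.items():
                flag = "" if self.jackknife.defined[cond] else "  [threshold not met]"
                lines.append(f"  {cond[1]:>14} / {cond[0]:<9} onset = {lat:7.1f} ms{flag}")
            for cmp_ in self.jackknife.comparisons:
                lines.append(
                    f"  {cmp_.condition_a} vs {cmp_.condition_b}: "
                    f"t_c({cmp_.df}) = {cmp_.t_corrected:.2f}, p = {cmp_.p_value:.4f}"
                )
        for tt, wa in self.decoding_window.items():
            lines += [
                "",
                f"Decoding ({tt}): window mean = {wa.mean:.3f} "
                f"(chance {wa.chance}), t({wa.df}) = {wa.t:.2f}, p = {wa.p_value:.4f}",
            ]
            clusters = self.decoding_clusters.get(tt)
            if clusters is not None:
                for cl in clusters.clusters:
                    lines.append(
                        f"  cluster {cl.start_ms:.0f}-{cl.end_ms:.0f} ms, "
                        f"t mass = {cl.t_mass:.2f}, p = {cl.p_value:.4f}"
                    )
                if not clusters.clusters:
                    lines.append("  no significant clusters")
        if len(self.sme_table):
            lines += ["", "Data quality (bootstrapped SME, RMS across participants):"]
            for (measure, pos, tt), grp in self.sme_table.groupby(
                ["measure", "symbol_position", "trial_type"]
            ):
                lines.append(
                    f"  {measure:<24} {tt:>14} / {pos:<9} RMS = "
                    f"{_inference.rms_aggregate(grp['bsme']):.3f}"
                )
        if self.behavioral is not None:
            lines += ["", "Behavior (correct-trial RT):"]
            for row in self.behavioral.itertuples(index=False):
                lines.append(
                    f"  {row.trial_type:>14} / {row.symbol_position:<9} "
                    f"RT = {row.rt_mean_ms:6.1f} ms  accuracy = {row.accuracy:.3f}"
                )
        if self.twoafc is not None:
            lines.append(
                f"\n2AFC recognition: proportion = {self.twoafc.proportion_correct:.3f}, "
                f"t({self.twoafc.df}) = {self.twoafc.t:.2f}, p = {self.twoafc.p_value:.3f}, "
                f"mean confidence = {self.twoafc.mean_confidence:.2f}"
            )
        return "\n".join(lines)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.measures_table.to_csv(directory / "measures.csv", index=False)
        self.sme_table.to_csv(directory / "sme.csv", index=False)
        self.retention.to_csv(directory / "retention.csv", index=False)
        if self.behavioral is not None:
            self.behavioral.to_csv(directory / "behavior.csv", index=False)
        for cond, ga in self.grand_averages.items():
            pd.DataFrame({"time_ms": ga.times, "value_uv": ga.values}).to_csv(
                directory / f"grand_average_{cond[0]}_{cond[1]}.csv", index=False
            )
        report = {
            "config": self.config.to_dict(),
            "config_digest": self.config.digest(),
            "permutation": {
                f"{c[0]}|{c[1]}": {
                    "observed": r.observed,
                    "p_value": r.p_value,
                    "significant": r.significant,
                }
                for c, r in self.permutation.items()
            },
            "decoding_window": {
                tt: {"mean": wa.mean, "t": wa.t, "p_value": wa.p_value}
                for tt, wa in self.decoding_window.items()
            },
            "summary": self.summary(),
        }
        (directory / "report.json").write_text(json.dumps(report, indent=2))


class N2pcStudy:
    """A lateralized-ERP study: per-participant epochs plus analysis settings.

    Build with raw :class:`~laterp.containers.EpochSet` objects (one per
    participant, trial metadata attached) or simulate a cohort from the
    configuration with :meth:`from_config`; then call :meth:`fit`.
    """

    def __init__(
        self,
        participants: list,
        config: AnalysisConfig | None = None,
        schedules: list | None = None,
        twoafc: list | None = None,
    ):
        if not participants:
            raise ValueError("a study needs at least one participant")
        self.config = config or AnalysisConfig()
        self.participants = participants
        self.schedules = schedules
        self.twoafc = twoafc

    @classmethod
    def from_config(cls, config: AnalysisConfig, truth: GroundTruth | None = None,
                    rt_model: RTModel | None = None) -> "N2pcStudy":
        """Simulate a full cohort under the configured study conditions.

        The patterned side alternates across participants
        (counterbalancing); ground truth defaults to
        :meth:`GroundTruth.default` at the configured noise and artifact
        levels.
        """
        truth = truth or GroundTruth.default(
            noise_sd_uv=config.noise_sd_uv, artifact_rate=config.artifact_rate
        )
        rng = np.random.default_rng(config.seed)
        participants, schedules, twoafc = [], [], []
        counts = TrialCounts(*config.trials_per_block)
        for i in range(config.n_participants):
            pid = f"P{i + 1:02d}"
            schedule = generate_design(
                n_blocks=config.n_blocks,
                counts=counts,
                pattern_side="left" if i % 2 == 0 else "right",
                seed=rng,
                participant=pid,
            )
            schedule = simulate_behavior(schedule, rt_model, seed=rng)
            epochs = simulate_epochs(
                schedule,
                truth,
                seed=rng,
                channels=config.channels(),
                sfreq=config.sampling_rate_hz,
                tmin_ms=config.epoch_ms[0],
                tmax_ms=config.epoch_ms[1],
            )
            participants.append(epochs)
            schedules.append(schedule)
            twoafc.append(
                simulate_2afc(config.twoafc_n_trials, config.twoafc_p_correct, seed=rng)
            )
        return cls(participants, config, schedules=schedules, twoafc=twoafc)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> N2pcResults:
        cfg = self.config
        clean_sets, retention_rows = [], []
        for i, raw in enumerate(self.participants):
            pid = raw.trials["participant"].iloc[0] if "participant" in raw.trials else f"P{i+1:02d}"
            clean, report = _preprocessing.preprocess(
                raw, baseline_window_ms=cfg.baseline_ms
            )
            clean_sets.append((pid, clean))
            retention_rows.append(
                {"participant": pid, "total": raw.n_trials,
                 "rejected_artifact": int(report.rejected.sum()),
                 "retained": clean.n_trials}
            )
        retention = pd.DataFrame(retention_rows)

        # Per-participant difference waves and measures.
        waves_by_condition = {c: [] for c in CONDITIONS}
        measure_rows = []
        for pid, clean in clean_sets:
            for cond in CONDITIONS:
                erp = _waveforms.condition_average(clean, *cond, participant_id=pid)
                wave = _waveforms.difference_wave(erp)
                waves_by_condition[cond].append(wave)
                for res in (
                    _measures.mean_amplitude(wave, cfg.n2pc_window_ms),
                    _measures.signed_negative_area(wave, cfg.broad_window_ms),
                    _measures.fractional_area_latency(
                        wave, cfg.broad_window_ms, cfg.area_fraction
                    ),
                    _measures.onset_threshold_crossing(
                        wave, cfg.onset_threshold_uv, cfg.broad_window_ms
                    ),
                ):
                    measure_rows.append(
                        {"participant": pid, "symbol_position": cond[0],
                         "trial_type": cond[1], "measure": res.measure,
                         "value": res.value, "defined": res.defined,
                         "units": res.units, "n_trials": erp.n_trials}
                    )
        measures_table = pd.DataFrame(measure_rows)
        grand_averages = {
            c: _waveforms.grand_average(w) for c, w in waves_by_condition.items()
        }

        # Signed-area permutation test.
        permutation = _inference.signed_area_permutation_test(
            [clean for _, clean in clean_sets],
            window_ms=cfg.broad_window_ms,
            n_permutations=cfg.n_permutations,
            seed=cfg.seed + 1,
        )

        # Jackknife onset latency with corrected contrasts.
        jackknife = (
            _measures.jackknife_latency_analysis(
                waves_by_condition, cfg.onset_threshold_uv, cfg.broad_window_ms
            )
            if len(clean_sets) >= 3
            else None
        )

        # Omnibus ANOVAs on mean amplitude and fractional-area latency.
        amplitude_anova = self._anova_from_table(measures_table, "mean_amplitude")
        fractional_anova = self._anova_from_table(measures_table, "fractional_area_latency")

        # Decoding per trial type with cluster inference.
        decoding_window, decoding_clusters = {}, {}
        if cfg.run_decoding and len(clean_sets) >= 3:
            for tt in ("exemplar_match", "foil"):
                tcs = []
                for j, (pid, clean) in enumerate(clean_sets):
                    sub = clean.select_trials(
                        clean.trials["trial_type"].to_numpy() == tt
                    )
                    tcs.append(
                        _decoding.decode_timecourse(
                            sub,
                            n_folds=cfg.n_folds,
                            n_iterations=cfg.n_iterations,
                            seed=cfg.seed + 100 + j,
                            window_ms=cfg.broad_window_ms,
                            participant_id=pid,
                            trial_type=tt,
                        )
                    )
                decoding_window[tt] = _decoding.window_mean_accuracy(
                    tcs, cfg.broad_window_ms
                )
                acc = np.stack([tc.accuracy for tc in tcs])
                decoding_clusters[tt] = _inference.cluster_permutation_null(
                    acc,
                    tcs[0].times,
                    alpha=cfg.alpha,
                    n_permutations=cfg.n_cluster_permutations,
                    seed=cfg.seed + 200,
                    n_attempts=tcs[0].n_attempts_per_point,
                )

        # Bootstrapped SME per participant, condition and measure.
        sme_rows = []
        for j, (pid, clean) in enumerate(clean_sets):
            for measure in ("mean_amplitude", "signed_negative_area",
                            "fractional_area_latency"):
                window = cfg.n2pc_window_ms if measure == "mean_amplitude" else cfg.broad_window_ms
                for cond, res in _inference.sme_from_epochs(
                    clean, measure, window, cfg.n_bootstrap,
                    seed=cfg.seed + 300 + j, participant_id=pid
                ).items():
                    sme_rows.append(
                        {"participant": pid, "measure": measure,
                         "symbol_position": cond[0], "trial_type": cond[1],
                         "bsme": res.bsme, "n_undefined": res.n_undefined}
                    )
        sme_table = pd.DataFrame(sme_rows)

        # Behavior and recognition test.
        behavioral, rt_anova, twoafc_score = None, None, None
        if self.schedules is not None:
            pooled = pd.concat(self.schedules, ignore_index=True)
            behavioral = _stats.behavioral_summaries(pooled)
            rt_tables = []
            for schedule in self.schedules:
                tab = _stats.behavioral_summaries(schedule)
                cell = tab.set_index(["symbol_position", "trial_type"])["rt_mean_ms"]
                rt_tables.append(
                    [[cell.get(("patterned", "exemplar_match"), np.nan),
                      cell.get(("patterned", "foil"), np.nan)],
                     [cell.get(("random", "exemplar_match"), np.nan),
                      cell.get(("random", "foil"), np.nan)]]
                )
            if len(rt_tables) >= 3:
                rt_anova = _stats.rm_anova_2x2(
                    np.asarray(rt_tables), ("symbol_position", "trial_type")
                )
        if self.twoafc is not None:
            props = [df["correct"].mean() for df in self.twoafc]
            twoafc_score = _stats.score_2afc(
                pd.concat(self.twoafc, ignore_index=True), proportions=props
            )

        return N2pcResults(
            config=cfg,
            measures_table=measures_table,
            grand_averages=grand_averages,
            permutation=permutation,
            jackknife=jackknife,
            fractional_anova=fractional_anova,
            amplitude_anova=amplitude_anova,
            decoding_window=decoding_window,
            decoding_clusters=decoding_clusters,
            sme_table=sme_table,
            behavioral=behavioral,
            rt_anova=rt_anova,
            twoafc=twoafc_score,
            retention=retention,
        )

    @staticmethod
    def _anova_from_table(measures_table: pd.DataFrame, measure: str) -> dict | None:
        """2x2 within-subject ANOVA from the tidy measure table (complete cases)."""
        sub = measures_table[measures_table["measure"] == measure]
        if sub.empty:
            return None
        pivot = sub.pivot_table(
            index="participant", columns=["symbol_position", "trial_type"],
            values="value", dropna=False
        )
        try:
            table = np.stack(
                [
                    [[row[("patterned", "exemplar_match")], row[("patterned", "foil")]],
                     [row[("random", "exemplar_match")], row[("random", "foil")]]]
                    for _, row in pivot.iterrows()
                ]
            )
            return _stats.rm_anova_2x2(table, ("symbol_position", "trial_type"))
        except (KeyError, ValueError):
            return None
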