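"""Group-level reporting statistics: 2x2 within-subject ANOVA, behavioral and
recognition-task summaries.

These are standard utilities around the resampling core: a fully-repeated
2x2 ANOVA (each effect 1 df, computed from within-subject contrast scores),
condition-wise reaction-time/accuracy tables, and the two-alternative
forced-choice (2AFC) recognition score against chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AnovaEffect", "rm_anova_2x2", "behavioral_summaries", "score_2afc", "TwoAFCScore"]


@dataclass
class AnovaEffect:
    """One effect of the within-subject 2x2 decomposition."""

    name: str
    F: float
    df: tuple[int, int]
    p_value: float
    partial_eta_sq: float


def rm_anova_2x2(table: np.ndarray, factor_names=("factor_a", "factor_b")) -> dict:
    """Fully repeated-measures 2x2 ANOVA from an ``(n, 2, 2)`` cell table.

    ``table[i, a, b]`` is participant ``i``'s mean in level ``a`` of the
    first factor and ``b`` of the second.  Each effect (two main effects and
    the interaction) has 1 numerator df and is equivalent to a paired t test
    on the corresponding contrast scores: ``F = t^2``,
    ``partial eta^2 = F / (F + n - 1)``.  Rows containing NaN are excluded
    listwise (complete cases only).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 3 or table.shape[1:] != (2, 2):
        raise ValueError("table must have shape (n_participants, 2, 2)")
    complete = ~np.isnan(table).any(axis=(1, 2))
    n_excluded = int((~complete).sum())
    table = table[complete]
    n = table.shape[0]
    if n < 3:
        raise ValueError("need at least three complete participants")

    contrasts = {
        factor_names[0]: table[:, 0, :].mean(axis=1) - table[:, 1, :].mean(axis=1),
        factor_names[1]: table[:, :, 0].mean(axis=1) - table[:, :, 1].mean(axis=1),
        "interaction": (table[:, 0, 0] - table[:, 0, 1]) - (table[:, 1, 0] - table[:, 1, 1]),
    }
    effects = {}
    for name, d in contrasts.items():
        sd = d.std(ddof=1)
        if sd == 0:
            F, p = 0.0, 1.0
            if d.mean() != 0:
                F, p = float("inf"), 0.0
        else:
            t = d.mean() / (sd / np.sqrt(n))
            F = float(t**2)
            p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
        effects[name] = AnovaEffect(
            name=name,
            F=F,
            df=(1, n - 1),
            p_value=p,
            partial_eta_sq=float(F / (F + n - 1)) if np.isfinite(F) else 1.0,
        )
    effects["n_excluded"] = n_excluded
    return effects


def behavioral_summaries(schedule: pd.DataFrame) -> pd.DataFrame:
    """Condition-wise mean/SD reaction time (correct trials only) and accuracy.

    Target Absent trials are excluded; the remaining trials are grouped by
    ``(symbol_position, trial_type)``.  Accuracy counts all responses;
    RT statistics use correct trials with a recorded response.
    """
    if "response" not in schedule.columns:
        raise ValueError("schedule has no behavioral columns; run simulate_behavior first")
    df = schedule[schedule["trial_type"] != "target_absent"]
    if df.empty:
        raise ValueError("no analyzable trials (all Target Absent)")
    rows = []
    for (pos, tt), grp in df.groupby(["symbol_position", "trial_type"], sort=True):
        correct_rt = grp.loc[grp["correct"].astype(bool), "rt_ms"].dropna()
        rows.append(
            {
                "symbol_position": pos,
                "trial_type": tt,
                "n_trials": len(grp),
                "accuracy": float(grp["correct"].astype(bool).mean()),
                "rt_mean_ms": float(correct_rt.mean()) if len(correct_rt) else float("nan"),
                "rt_sd_ms": float(correct_rt.std(ddof=1)) if len(correct_rt) > 1 else
                (0.0 if len(correct_rt) == 1 else float("nan")),
                "n_correct_rt": len(correct_rt),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TwoAFCScore:
    """Recognition-task summary: proportion correct vs chance plus confidence."""

    proportion_correct: float
    t: float
    df: int
    p_value: float
    cohen_d: float
    mean_confidence: float


def score_2afc(responses: pd.DataFrame | None = None, proportions=None,
               chance: float = 0.5) -> TwoAFCScore:
    """Score the 2AFC recognition test against chance.

    Either pass one participant's trial table (columns ``correct``,
    ``confidence``) — the t test then treats trials as the unit — or pass
    ``proportions``, a per-participant vector of proportions correct (the
    group-level test); ``responses`` may then still provide confidences.
    """
    if proportions is not None:
        values = np.asarray(list(proportions), dtype=float)
    elif responses is not None:
        if len(responses) < 2:
            raise ValueError("need at least two responses")
        values = responses["correct"].astype(float).to_numpy()
    else:
        raise ValueError("provide responses or proportions")
    mean_conf = (
        float(responses["confidence"].mean())
        if responses is not None and "confidence" in responses
        else float("nan")
    )
    n = values.size
    sd = values.std(ddof=1)
    if sd == 0:
        t, p, d = (0.0, 1.0, 0.0) if values.mean() == chance else (float("inf"), 0.0, float("inf"))
    else:
        t = float((values.mean() - chance) / (sd / np.sqrt(n)))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
        d = float((values.mean() - chance) / sd)
    return TwoAFCScore(
        proportion_correct=float(values.mean()),
        t=t,
        df=n - 1,
        p_value=p,
        cohen_d=d,
        mean_confidence=mean_conf,
    )
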