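"""Trial-schedule and symbol-stream generation for the two-location search task.

The experiment interleaves a *pattern phase* — streams of runic symbols shown
left and right of fixation, one side structured into fixed triplets, the
other unstructured — with a *search phase* in which a target exemplar, a foil
from the target category, or no relevant item appears on one side.  A block
holds 28 Exemplar Match, 28 Foil and 4 Target Absent trials; the sided types
are split 14/14 between left and right, the patterned side is fixed per
participant, and trial order is randomized within block.

Schedules are plain pandas DataFrames with one row per trial (column
dictionary in :data:`SCHEDULE_COLUMNS`); downstream modules key their
condition logic on the ``symbol_position`` column (``patterned`` when the
search item appears on the patterned side, ``random`` otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_TYPES",
    "SIDES",
    "SYMBOL_ALPHABET",
    "TRIPLET_SYMBOLS",
    "RANDOM_SYMBOLS",
    "SCHEDULE_COLUMNS",
    "TrialCounts",
    "SymbolSequence",
    "make_triplet_inventory",
    "generate_design",
    "generate_symbol_stream",
    "pattern_phase_duration",
]

TRIAL_TYPES = ("exemplar_match", "foil", "target_absent")
SIDES = ("left", "right")

#: 18-symbol alphabet; the first nine form the triplet inventory, the last
#: nine feed the unstructured stream (disjoint sets).
SYMBOL_ALPHABET = tuple(f"R{i:02d}" for i in range(1, 19))
TRIPLET_SYMBOLS = SYMBOL_ALPHABET[:9]
RANDOM_SYMBOLS = SYMBOL_ALPHABET[9:]

SCHEDULE_COLUMNS = {
    "participant": "participant identifier",
    "block": "block index (1-based)",
    "trial": "trial index within block (1-based, post-randomization order)",
    "trial_type": "exemplar_match | foil | target_absent",
    "item_side": "side of the target/foil: left | right | none (none iff target_absent)",
    "pattern_side": "side of the patterned symbol stream (constant per participant)",
    "symbol_position": "patterned if item_side == pattern_side, random otherwise, none for target_absent",
    "symbol_count": "number of pattern-phase symbols: 3 | 6 | 9",
    "response": "present | absent | none (none = no response before deadline)",
    "correct": "response matches target presence",
    "rt_ms": "reaction time in ms; NaN when no response within the deadline",
}

RESPONSE_DEADLINE_MS = 1600.0


@dataclass(frozen=True)
class TrialCounts:
    """Per-block trial counts. The sided types need an even count for the left/right split."""

    exemplar_match: int = 28
    foil: int = 28
    target_absent: int = 4

    def validate(self) -> None:
        for name in ("exemplar_match", "foil", "target_absent"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be >= 0")
        for name in ("exemplar_match", "foil"):
            if getattr(self, name) % 2:
                raise ValueError(
                    f"{name} count {getattr(self, name)} cannot satisfy the equal "
                    "left/right side split; use an even count"
                )


@dataclass(frozen=True)
class SymbolSequence:
    """A pattern-phase symbol stream.

    ``patterned`` streams concatenate whole triplets from a fixed
    three-triplet inventory; ``random`` streams draw from a disjoint symbol
    set with back-to-back repeats forbidden.
    """

    mode: str
    symbols: tuple[str, ...]
    triplet_inventory: tuple[tuple[str, str, str], ...] | None = None

    def __post_init__(self):
        if self.mode not in ("patterned", "random"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "patterned":
            if self.triplet_inventory is None:
                raise ValueError("patterned sequence requires a triplet inventory")
            allowed = {t for t in self.triplet_inventory}
            chunks = [tuple(self.symbols[i : i + 3]) for i in range(0, len(self.symbols), 3)]
            if len(self.symbols) % 3 or any(c not in allowed for c in chunks):
                raise ValueError("patterned sequence must concatenate whole inventory triplets")
        else:
            for a, b in zip(self.symbols, self.symbols[1:]):
                if a == b:
                    raise ValueError("random sequence contains a back-to-back repeat")


def make_triplet_inventory(seed_or_rng=0) -> tuple[tuple[str, str, str], ...]:
    """Partition the nine triplet symbols into three fixed ordered triplets.

    The inventory is fixed per participant; draw it once per simulated
    participant and reuse it for every patterned stream.
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator
    ) else seed_or_rng
    order = rng.permutation(len(TRIPLET_SYMBOLS))
    syms = [TRIPLET_SYMBOLS[i] for i in order]
    return tuple(tuple(syms[i : i + 3]) for i in range(0, 9, 3))


def generate_design(
    n_blocks: int = 7,
    counts: TrialCounts | None = None,
    pattern_side: str = "left",
    seed=0,
    participant: str = "P01",
) -> pd.DataFrame:
    """Generate a trial schedule for one participant.

    Per block: ``counts.exemplar_match`` Exemplar Match trials (half with the
    target left, half right), ``counts.foil`` Foil trials (same split) and
    ``counts.target_absent`` Target Absent trials; all trials shuffled within
    block.  ``symbol_count`` is drawn uniformly from {3, 6, 9} per trial.

    Returns a DataFrame with :data:`SCHEDULE_COLUMNS`; behavioral columns are
    placeholders (``response='none'``) until :func:`laterp.synth.simulate_behavior`
    fills them.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if pattern_side not in SIDES:
        raise ValueError(f"pattern_side must be one of {SIDES}")
    counts = counts or TrialCounts()
    counts.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    rows = []
    for block in range(1, n_blocks + 1):
        block_rows = []
        for ttype, n in (
            ("exemplar_match", counts.exemplar_match),
            ("foil", counts.foil),
        ):
            for side in SIDES:
                block_rows += [(ttype, side)] * (n // 2)
        block_rows += [("target_absent", "none")] * counts.target_absent
        order = rng.permutation(len(block_rows))
        for trial, idx in enumerate(order, start=1):
            ttype, side = block_rows[idx]
            rows.append(
                {
                    "participant": participant,
                    "block": block,
                    "trial": trial,
                    "trial_type": ttype,
                    "item_side": side,
                    "pattern_side": pattern_side,
                    "symbol_position": (
                        "none"
                        if side == "none"
                        else ("patterned" if side == pattern_side else "random")
                    ),
                    "symbol_count": int(rng.choice([3, 6, 9])),
                    "response": "none",
                    "correct": False,
                    "rt_ms": np.nan,
                }
            )
    return pd.DataFrame(rows, columns=list(SCHEDULE_COLUMNS))


def generate_symbol_stream(
    n_triplets: int,
    mode: str,
    seed=0,
    triplet_inventory: tuple[tuple[str, str, str], ...] | None = None,
) -> SymbolSequence:
    """Generate one pattern-phase symbol stream of ``3 * n_triplets`` symbols.

    ``patterned`` streams concatenate ``n_triplets`` whole triplets sampled
    uniformly with replacement from the inventory (adjacent duplicates of a
    whole triplet allowed; the structure lives in the within-triplet order).
    ``random`` streams draw symbols from the disjoint nine-symbol random set
    with immediate repeats forbidden.
    """
    if n_triplets not in (1, 2, 3):
        raise ValueError("n_triplets must be 1, 2 or 3")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if mode == "patterned":
        inventory = triplet_inventory or make_triplet_inventory(rng)
        picks = rng.integers(0, len(inventory), size=n_triplets)
        symbols = tuple(s for i in picks for s in inventory[i])
        return SymbolSequence(mode="patterned", symbols=symbols, triplet_inventory=tuple(inventory))
    if mode == "random":
        symbols: list[str] = []
        for _ in range(3 * n_triplets):
            choices = [s for s in RANDOM_SYMBOLS if not symbols or s != symbols[-1]]
            symbols.append(choices[rng.integers(0, len(choices))])
        return SymbolSequence(mode="random", symbols=tuple(symbols))
    raise ValueError(f"unknown mode {mode!r}")


def pattern_phase_duration(n_triplets: int, symbol_duration_ms: float = 400.0) -> float:
    """Duration of a pattern phase in ms: ``3 * n_triplets * symbol_duration_ms``.

    With the 400 ms default, three triplets (nine symbols) last 3600 ms.
    """
    if n_triplets < 1:
        raise ValueError("n_triplets must be >= 1")
    if symbol_duration_ms <= 0:
        raise ValueError("symbol_duration_ms must be positive")
    return 3.0 * n_triplets * symbol_duration_ms
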