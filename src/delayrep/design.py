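"""Stimulus interval sets and trial schedules for delayed reproduction experiments.

A session presents a small set of geometrically spaced sample intervals,
each repeated a fixed number of times under each retention-period
condition.  Retention conditions are either *blocked* (one block per
retention period, block order randomized between participants) or
*mixed* (all retention periods interleaved within every block).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "IntervalSet",
    "DesignSpec",
    "build_interval_set",
    "generate_schedule",
    "design_presets",
    "load_design",
    "dump_design",
    "TRIAL_COLUMNS",
]

#: Column order of a trial-schedule table (one row per trial).
TRIAL_COLUMNS = [
    "participant",
    "experiment_id",
    "block",
    "trial_index",
    "retention_s",
    "sample_ms",
    "foreperiod_s",
]


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class IntervalSet:
    """A geometric ladder of sample intervals around a central duration.

    ``values_ms`` holds the exact (unrounded) durations
    ``center_ms * 10**((k - half_width) * log_step)``; rounding to the
    nearest millisecond happens only for display and serialization.
    """

    center_ms: float
    log_step: float
    half_width: int
    values_ms: tuple[float, ...]

    @property
    def rounded_ms(self) -> tuple[int, ...]:
        """Nearest-millisecond values, for display only."""
        return tuple(_round_half_away(v) for v in self.values_ms)

    def __len__(self) -> int:
        return len(self.values_ms)


def build_interval_set(
    center_ms: float = 640.0, log_step: float = 0.15, half_width: int = 3
) -> IntervalSet:
    """Construct the geometric interval set.

    Parameters
    ----------
    center_ms : central sample interval in milliseconds (> 0).
    log_step : spacing between neighbours in log10 units (> 0 when
        ``half_width`` > 0).
    half_width : number of steps on each side of the center, so the set
        has ``2*half_width + 1`` members.
    """
    if not center_ms > 0:
        raise ValueError(f"center_ms must be positive, got {center_ms}")
    if half_width < 0:
        raise ValueError(f"half_width must be >= 0, got {half_width}")
    if half_width > 0 and not log_step > 0:
        raise ValueError(f"log_step must be positive, got {log_step}")
    values = tuple(
        center_ms * 10.0 ** ((k - half_width) * log_step)
        for k in range(2 * half_width + 1)
    )
    return IntervalSet(center_ms, log_step, half_width, values)


@dataclass
class DesignSpec:
    """Parameters of one experiment's trial schedule.

    ``structure`` is ``"blocked"`` (each retention period occupies one
    block) or ``"mixed"`` (every block interleaves all retention
    periods).  The foreperiod — the random fixation delay before the
    sample — is generated and stored so simulated tables mirror the real
    schema, but the analysis never uses it.
    """

    experiment_id: str
    retention_periods_s: tuple[float, ...]
    structure: str  # "blocked" | "mixed"
    reps_per_interval: int = 10
    n_participants: int = 35
    foreperiod_range_s: tuple[float, float] = (0.5, 1.2)
    seed: int = 0
    interval_center_ms: float = 640.0
    interval_log_step: float = 0.15
    interval_half_width: int = 3

    def __post_init__(self) -> None:
        self.retention_periods_s = tuple(float(r) for r in self.retention_periods_s)
        self.foreperiod_range_s = tuple(float(f) for f in self.foreperiod_range_s)
        if self.structure not in ("blocked", "mixed"):
            raise ValueError(f"structure must be 'blocked' or 'mixed', got {self.structure!r}")
        if any(r <= 0 for r in self.retention_periods_s):
            raise ValueError("retention periods must be positive")
        if self.reps_per_interval < 0:
            raise ValueError("reps_per_interval must be >= 0")
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        lo, hi = self.foreperiod_range_s
        if not lo < hi:
            raise ValueError("foreperiod range must satisfy min < max")

    def interval_set(self) -> IntervalSet:
        return build_interval_set(
            self.interval_center_ms, self.interval_log_step, self.interval_half_width
        )


def design_presets() -> dict[str, DesignSpec]:
    """Named design presets for the three standard experiments.

    exp1: blocked retention periods 0.4/2/4 s, 36 participants.
    exp2: blocked retention periods 0.4/2/8 s, 35 participants.
    exp3: retention periods 0.4/2/8 s mixed within every block, 35
    participants.  All use 7 intervals x 10 repetitions per retention
    condition (210 trials per participant).
    """
    return {
        "exp1": DesignSpec("exp1", (0.4, 2.0, 4.0), "blocked", n_participants=36),
        "exp2": DesignSpec("exp2", (0.4, 2.0, 8.0), "blocked", n_participants=35),
        "exp3": DesignSpec("exp3", (0.4, 2.0, 8.0), "mixed", n_participants=35),
    }


def _mixed_block_counts(
    pairs: list, n_reps: int, n_blocks: int, rng: np.random.Generator
) -> dict:
    """Split each (retention, interval) pair's repetitions across blocks as
    evenly as possible, steering remainders to the least-loaded blocks so
    block totals stay balanced (exactly equal whenever the total trial
    count divides evenly over blocks)."""
    base, extra = divmod(n_reps, n_blocks)
    counts = {pair: np.full(n_blocks, base, dtype=int) for pair in pairs}
    if extra:
        load = np.zeros(n_blocks, dtype=int)
        for pair in rng.permutation(len(pairs)):
            pair = pairs[pair]
            # random tie-break among equally loaded blocks
            order = rng.permutation(n_blocks)
            chosen = order[np.argsort(load[order], kind="stable")][:extra]
            counts[pair][chosen] += 1
            load[chosen] += 1
    return counts


def generate_schedule(spec: DesignSpec, interval_set: IntervalSet | None = None) -> pd.DataFrame:
    """Generate the full trial schedule for all participants of a design.

    Counts are exact: every (retention period, interval) pair occurs
    ``spec.reps_per_interval`` times per participant.  Within-block trial
    order is a seeded random permutation; blocked designs additionally
    randomize block order per participant.  Sample intervals are stored
    unrounded.
    """
    if interval_set is None:
        interval_set = spec.interval_set()
    rng = np.random.default_rng(spec.seed)
    n_blocks = len(spec.retention_periods_s)
    lo, hi = spec.foreperiod_range_s

    rows: list[dict] = []
    for p in range(spec.n_participants):
        participant = f"P{p + 1:03d}"
        if spec.structure == "blocked":
            block_order = rng.permutation(n_blocks)
            blocks = [
                [(spec.retention_periods_s[ret_idx], s)
                 for s in interval_set.values_ms
                 for _ in range(spec.reps_per_interval)]
                for ret_idx in block_order
            ]
        else:  # mixed: every block interleaves all retention periods
            blocks = [[] for _ in range(n_blocks)]
            pairs = [(ret, s) for ret in spec.retention_periods_s
                     for s in interval_set.values_ms]
            counts = _mixed_block_counts(pairs, spec.reps_per_interval, n_blocks, rng)
            for pair, per_block in counts.items():
                for b, c in enumerate(per_block):
                    blocks[b].extend([pair] * c)
        trial_index = 0
        for b, block_trials in enumerate(blocks):
            order = rng.permutation(len(block_trials))
            for k in order:
                ret, s = block_trials[k]
                rows.append(
                    {
                        "participant": participant,
                        "experiment_id": spec.experiment_id,
                        "block": b,
                        "trial_index": trial_index,
                        "retention_s": ret,
                        "sample_ms": s,
                        "foreperiod_s": lo + (hi - lo) * rng.random(),
                    }
                )
                trial_index += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def dump_design(spec: DesignSpec, path) -> None:
    """Write a design spec to a YAML config file (lossless round-trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(spec), fh, sort_keys=False)


def load_design(path) -> DesignSpec:
    """Read a design spec from a YAML config file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    for key in ("retention_periods_s", "foreperiod_range_s"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return DesignSpec(**raw)
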