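"""Experimental design: interval sets, sequence construction, sessions, feedback.

The task is auditory temporal-pattern reproduction: on each trial a listener
hears five beeps demarcating four intervals (total 2.8 s) and reproduces the
pattern by tapping.  Two four-interval sets share the same mean (700 ms) and
sample SD (294.39 ms); a sequence presents one set in ascending order
(decelerating rhythm, DS), descending order (accelerating, AS), or a random
non-monotone order (RS).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Arithmetic mean of every interval set, the fixed anchor of the ensemble prior.
DESIGN_MEAN_MS: float = 700.0
#: Total duration of every four-interval sequence.
SEQUENCE_TOTAL_MS: float = 2800.0

#: Canonical interval sets, ascending order.
INTERVAL_SETS: dict[int, tuple[float, ...]] = {
    1: (400.0, 500.0, 900.0, 1000.0),
    2: (400.0, 600.0, 700.0, 1100.0),
}

CONDITIONS: tuple[str, ...] = ("AS", "DS", "RS")

N_BLOCKS: int = 6
TRIALS_PER_BLOCK: int = 44
TRIALS_PER_SESSION: int = N_BLOCKS * TRIALS_PER_BLOCK  # 264

#: Relative-error bands of the trial feedback display (closed on the inner band).
ACCURATE_BAND: float = 0.15
MODERATE_BAND: float = 0.50

#: Columns of the long-format trial table (one row per trial x position).
TRIAL_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "block",
    "trial",
    "condition",
    "set_id",
    "position",
    "sample_ms",
)


@dataclass(frozen=True)
class IntervalSet:
    """One of the two canonical four-interval stimulus sets, ascending order."""

    set_id: int
    intervals_ms: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.set_id not in INTERVAL_SETS:
            raise ValueError(f"unknown set_id {self.set_id!r}; expected 1 or 2")
        if tuple(float(x) for x in self.intervals_ms) != INTERVAL_SETS[self.set_id]:
            raise ValueError(
                f"intervals {self.intervals_ms!r} do not match canonical set "
                f"{self.set_id}: {INTERVAL_SETS[self.set_id]}"
            )

    @classmethod
    def canonical(cls, set_id: int) -> "IntervalSet":
        if set_id not in INTERVAL_SETS:
            raise ValueError(f"unknown set_id {set_id!r}; expected 1 or 2")
        return cls(set_id=set_id, intervals_ms=INTERVAL_SETS[set_id])

    @property
    def mean_ms(self) -> float:
        return float(np.mean(self.intervals_ms))

    @property
    def sd_ms(self) -> float:
        """Sample SD (n-1 denominator); 294.39 ms for both canonical sets."""
        return float(np.std(self.intervals_ms, ddof=1))


def _admissible_rs_permutations(intervals: Sequence[float]) -> list[tuple[float, ...]]:
    asc = tuple(sorted(intervals))
    desc = asc[::-1]
    return [p for p in itertools.permutations(asc) if p != asc and p != desc]


#: The 22 admissible random-order permutations per set, fixed enumeration order.
RS_PERMUTATIONS: dict[int, list[tuple[float, ...]]] = {
    sid: _admissible_rs_permutations(vals) for sid, vals in INTERVAL_SETS.items()
}


@dataclass(frozen=True)
class TrialSpec:
    """One presented sequence: condition, set, and the four intervals in order."""

    participant_id: str
    block: int
    trial_in_block: int
    condition: str
    set_id: int
    order: tuple[int, ...]  # presented position of each canonical (ascending) index
    sample_ms: tuple[float, ...]

    @property
    def trial(self) -> int:
        """Session-global trial number, 1-based."""
        return (self.block - 1) * TRIALS_PER_BLOCK + self.trial_in_block


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def build_sequence(interval_set, condition: str, rng_seed=None) -> tuple[float, ...]:
    """Order one interval set according to the sequence type.

    DS presents intervals short-to-long (a decelerating rhythm), AS long-to-short,
    and RS draws uniformly from the 22 permutations that are neither fully
    ascending nor fully descending.  Deterministic given an integer seed or a
    ``numpy.random.Generator``.
    """
    if isinstance(interval_set, int):
        interval_set = IntervalSet.canonical(interval_set)
    asc = tuple(sorted(interval_set.intervals_ms))
    if condition == "DS":
        return asc
    if condition == "AS":
        return asc[::-1]
    if condition == "RS":
        rng = _as_rng(rng_seed)
        perms = RS_PERMUTATIONS[interval_set.set_id]
        return perms[int(rng.integers(len(perms)))]
    raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


def generate_session(
    participant_id: str, rng_seed, n_trials: int = TRIALS_PER_SESSION
) -> list[TrialSpec]:
    """Generate one participant's randomized session of trials.

    The 264-trial session allocates 88 trials to each sequence type, split
    44/44 between the two interval sets, with trial order shuffled uniformly;
    blocks of 44 are then cut from the shuffled order.  ``n_trials`` < 264
    truncates the shuffled session (used for reduced synthetic designs).
    """
    if not 1 <= n_trials <= TRIALS_PER_SESSION:
        raise ValueError(f"n_trials must be in [1, {TRIALS_PER_SESSION}]")
    rng = _as_rng(rng_seed)
    cells = [
        (cond, sid)
        for cond in CONDITIONS
        for sid in INTERVAL_SETS
        for _ in range(TRIALS_PER_SESSION // (len(CONDITIONS) * len(INTERVAL_SETS)))
    ]
    order = rng.permutation(len(cells))
    trials: list[TrialSpec] = []
    for idx, cell_idx in enumerate(order[:n_trials]):
        cond, sid = cells[cell_idx]
        iset = IntervalSet.canonical(sid)
        seq = build_sequence(iset, cond, rng)
        asc = list(iset.intervals_ms)
        perm = tuple(asc.index(v) for v in seq)
        trials.append(
            TrialSpec(
                participant_id=str(participant_id),
                block=idx // TRIALS_PER_BLOCK + 1,
                trial_in_block=idx % TRIALS_PER_BLOCK + 1,
                condition=cond,
                set_id=sid,
                order=perm,
                sample_ms=seq,
            )
        )
    return trials


def feedback_category(sample_ms: float, reproduced_ms: float) -> str:
    """Classify a reproduced interval by relative error, as on the feedback display.

    ``accurate`` (gray disk) for |error| <= 15%, ``moderate`` (yellow) for
    |error| in (15%, 50%], ``poor`` (red) beyond 50%; bands are closed on the
    inner side.
    """
    if sample_ms <= 0:
        raise ValueError("sample_ms must be positive")
    e = abs((reproduced_ms - sample_ms) / sample_ms)
    if e <= ACCURATE_BAND:
        return "accurate"
    if e <= MODERATE_BAND:
        return "moderate"
    return "poor"


def trials_to_frame(trials: Iterable[TrialSpec]) -> pd.DataFrame:
    """Serialize trials to the long-format table, one row per (trial, position)."""
    rows = {c: [] for c in TRIAL_COLUMNS}
    for t in trials:
        for pos, d in enumerate(t.sample_ms, start=1):
            rows["participant_id"].append(t.participant_id)
            rows["block"].append(t.block)
            rows["trial"].append(t.trial)
            rows["condition"].append(t.condition)
            rows["set_id"].append(t.set_id)
            rows["position"].append(pos)
            rows["sample_ms"].append(d)
    return pd.DataFrame(rows)
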