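"""Gear-specific vulnerability scoring of repeated fishing trials.

Trawl trials end in one of four outcomes of increasing severity —
``E_B`` (escaped beyond/under the net), ``E_F`` (escaped in front of the
net), ``C_N`` (caught in the net body) and ``C_C`` (caught in the cod-end
retention area) — scored 50/100/200/300, with an extra time penalty
``600 - t`` seconds for cod-end captures (earlier entry = more vulnerable).
The per-fish index sums penalty plus time term over the three trials, so
valid scores span 150 (three E_B) to 2700 (three C_C at t = 0).

Trap trials are binary captures; captures are weighted by trial (3 for
trial 1, 2 for trial 2, 1 for trial 3; earlier capture weighs more to
discount learning), giving scores in 0..6.

High/low vulnerability groups are the top/bottom quartiles of the score
distribution, optionally stratified (e.g. per holding tank).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRAWL_PENALTIES",
    "TRAP_TRIAL_WEIGHTS",
    "TRIAL_DURATION_S",
    "TrawlTrial",
    "TrapTrial",
    "VulnerabilityIndex",
    "trawl_penalty",
    "trawl_vulnerability",
    "trap_vulnerability",
    "score_trials_table",
    "assign_vulnerability_groups",
]

logger = logging.getLogger(__name__)

#: Penalty per trawl outcome, least to most severe.
TRAWL_PENALTIES: Mapping[str, int] = {"E_B": 50, "E_F": 100, "C_N": 200, "C_C": 300}

#: Weight earned by a trap capture in trials 1, 2, 3.
TRAP_TRIAL_WEIGHTS: Mapping[int, int] = {1: 3, 2: 2, 3: 1}

#: Trial duration in seconds ("each trial lasted for 10 min").
TRIAL_DURATION_S: float = 600.0


def _normalize_outcome(outcome: str) -> str:
    code = str(outcome).strip().upper().replace("-", "_")
    if "_" not in code and len(code) == 2:  # accept "EB", "CC", ...
        code = code[0] + "_" + code[1]
    return code


@dataclass(frozen=True)
class TrawlTrial:
    """One fish x one trawl trial: outcome code plus cod-end entry time."""

    outcome: str
    trial_index: int
    capture_time: float | None = None

    def __post_init__(self) -> None:
        code = _normalize_outcome(self.outcome)
        if code not in TRAWL_PENALTIES:
            raise ValueError(
                f"unknown trawl outcome {self.outcome!r}; "
                f"expected one of {sorted(TRAWL_PENALTIES)}"
            )
        object.__setattr__(self, "outcome", code)
        if self.trial_index not in (1, 2, 3):
            raise ValueError(f"trial_index must be 1..3, got {self.trial_index}")
        if code == "C_C":
            if self.capture_time is None:
                raise ValueError("C_C outcome requires a capture_time")
            if not 0 <= self.capture_time <= TRIAL_DURATION_S:
                raise ValueError(
                    f"capture_time must lie in [0, {TRIAL_DURATION_S:g}] s, "
                    f"got {self.capture_time}"
                )
        elif self.capture_time is not None:
            raise ValueError("capture_time is only defined for C_C outcomes")


@dataclass(frozen=True)
class TrapTrial:
    """One fish x one trap trial: was the fish in a trap at trial end?"""

    captured: bool
    trial_index: int

    def __post_init__(self) -> None:
        if self.trial_index not in (1, 2, 3):
            raise ValueError(f"trial_index must be 1..3, got {self.trial_index}")


@dataclass
class VulnerabilityIndex:
    """Per-fish vulnerability score with its quartile group label."""

    fish_id: str
    gear: str
    score: float
    group: str = "unassigned"

    GROUPS = ("high", "low", "middle", "unassigned")

    def __post_init__(self) -> None:
        if self.group not in self.GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


def trawl_penalty(outcome: str) -> int:
    """Penalty score of a single trawl outcome (E_B=50 ... C_C=300)."""
    code = _normalize_outcome(outcome)
    try:
        return TRAWL_PENALTIES[code]
    except KeyError:
        raise ValueError(
            f"unknown trawl outcome {outcome!r}; expected one of "
            f"{sorted(TRAWL_PENALTIES)}"
        ) from None


def _check_three_trials(trials: Sequence, gear: str) -> None:
    if len(trials) != 3:
        raise ValueError(f"{gear} vulnerability needs exactly 3 trials, got {len(trials)}")
    idx = [t.trial_index for t in trials]
    if sorted(idx) != [1, 2, 3]:
        raise ValueError(f"trial indices must be a permutation of 1,2,3, got {idx}")


def trawl_vulnerability(
    trials: Sequence[TrawlTrial], fish_id: str = "", tank: str | None = None
) -> VulnerabilityIndex:
    """Trawl vulnerability index V = sum_i (y_i + x_i) over the 3 trials.

    y_i is the outcome penalty and x_i = 600 - capture_time for cod-end
    captures (0 otherwise), so V ranges from 150 to 2700.
    """
    _check_three_trials(trials, "trawl")
    total = 0.0
    for t in trials:
        total += trawl_penalty(t.outcome)
        if t.outcome == "C_C":
            total += TRIAL_DURATION_S - t.capture_time
    return VulnerabilityIndex(fish_id=fish_id, gear="trawl", score=total)


def trap_vulnerability(
    trials: Sequence[TrapTrial], fish_id: str = ""
) -> VulnerabilityIndex:
    """Trap vulnerability: sum of weights (3/2/1) of trials with a capture.

    A fish never captured scores 0; captured in all three trials scores 6.
    """
    _check_three_trials(trials, "trap")
    total = sum(TRAP_TRIAL_WEIGHTS[t.trial_index] for t in trials if t.captured)
    return VulnerabilityIndex(fish_id=fish_id, gear="trap", score=float(total))


def score_trials_table(trials: pd.DataFrame) -> list[VulnerabilityIndex]:
    """Score a long-format trial table (one row per fish x trial).

    Columns: fish_id, gear, trial_index, and either outcome/capture_time_s
    (trawl rows) or captured (trap rows).  Fish with fewer or more than
    three trials are skipped with a logged warning.
    """
    indices: list[VulnerabilityIndex] = []
    for (fish_id, gear), grp in trials.groupby(["fish_id", "gear"], sort=False):
        if len(grp) != 3:
            logger.warning(
                "fish %s (%s) has %d trials, expected 3; excluded",
                fish_id,
                gear,
                len(grp),
            )
            continue
        if gear == "trawl":
            recs = [
                TrawlTrial(
                    outcome=row.outcome,
                    trial_index=int(row.trial_index),
                    capture_time=(
                        float(row.capture_time_s)
                        if _normalize_outcome(row.outcome) == "C_C"
                        else None
                    ),
                )
                for row in grp.itertuples()
            ]
            indices.append(trawl_vulnerability(recs, fish_id=str(fish_id)))
        elif gear == "trap":
            recs = [
                TrapTrial(captured=bool(row.captured), trial_index=int(row.trial_index))
                for row in grp.itertuples()
            ]
            indices.append(trap_vulnerability(recs, fish_id=str(fish_id)))
        else:
            raise ValueError(f"unknown gear {gear!r}")
    return indices


def assign_vulnerability_groups(
    indices: Iterable[VulnerabilityIndex],
    fraction: float = 0.25,
    stratify_by: Mapping[str, Hashable] | None = None,
    seed: int | None = None,
) -> list[VulnerabilityIndex]:
    """Label the top/bottom ``fraction`` of each stratum high/low.

    Within each stratum the ``ceil(fraction * n)`` highest scores are
    labelled ``high``, the same number of lowest scores ``low``, and the
    rest ``middle``.  Ties at a quartile boundary are broken by stable
    fish-id order, after an optional seeded shuffle so the break is
    reproducible but not id-biased.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError(f"fraction must lie in (0, 0.5], got {fraction}")
    indices = list(indices)
    strata: dict[Hashable, list[int]] = {}
    for pos, idx in enumerate(indices):
        key = stratify_by.get(idx.fish_id) if stratify_by is not None else None
        strata.setdefault(key, []).append(pos)

    out: list[VulnerabilityIndex] = list(indices)
    for key, members in strata.items():
        n = len(members)
        if n < 4:
            raise ValueError(f"stratum {key!r} has {n} fish; need at least 4")
        scores = np.array([indices[p].score for p in members])
        if np.ptp(scores) == 0:
            raise ValueError(
                f"stratum {key!r}: all scores identical; quartile groups undefined"
            )
        # tie-break rank: fish-id order, optionally seeded-shuffled first so
        # boundary ties are reproducible but not biased toward low ids
        order = sorted(range(n), key=lambda j: indices[members[j]].fish_id)
        if seed is not None:
            rng = np.random.default_rng(seed)
            rng.shuffle(order)
        by_score = sorted(order, key=lambda j: scores[j])  # stable on ties
        n_tail = math.ceil(fraction * n)
        low = {members[j] for j in by_score[:n_tail]}
        high = {members[j] for j in by_score[-n_tail:]}
        if low & high:
            raise ValueError(
                f"stratum {key!r}: tails overlap (n={n}, fraction={fraction})"
            )
        tied_boundaries = (
            scores[by_score[n_tail - 1]] == scores[by_score[n_tail]]
            or scores[by_score[-n_tail]] == scores[by_score[-n_tail - 1]]
        )
        if tied_boundaries:
            logger.info(
                "stratum %r: quartile boundary falls inside a tie; broken by "
                "%s fish-id order",
                key,
                "seeded" if seed is not None else "stable",
            )
        for p in members:
            group = "high" if p in high else "low" if p in low else "middle"
            out[p] = replace(indices[p], group=group)
    return out
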