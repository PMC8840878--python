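"""Vulnerability scoring: penalties, index bounds, quartile groups."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gearmorph.scoring import (
    TrapTrial,
    TrawlTrial,
    assign_vulnerability_groups,
    trap_vulnerability,
    trawl_penalty,
    trawl_vulnerability,
    VulnerabilityIndex,
)

OUTCOMES = ["E_B", "E_F", "C_N", "C_C"]


@pytest.mark.parametrize(
    "outcome,score", [("E_B", 50), ("E_F", 100), ("C_N", 200), ("C_C", 300)]
)
def test_trawl_penalties(outcome, score):
    assert trawl_penalty(outcome) == score


def test_penalty_normalizes_input():
    assert trawl_penalty(" EB ") == 50
    assert trawl_penalty("c_c") == 300
    with pytest.raises(ValueError, match="unknown"):
        trawl_penalty("X_Y")


def _trawl(outcomes, times=(None, None, None)):
    return [
        TrawlTrial(outcome=o, trial_index=i + 1, capture_time=t)
        for i, (o, t) in enumerate(zip(outcomes, times))
    ]


@pytest.mark.parametrize(
    "outcomes,times,expected",
    [
        (("C_C",) * 3, (0.0, 0.0, 0.0), 2700),  # maximum achievable score
        (("E_B",) * 3, (None,) * 3, 150),  # minimum
        (("E_F", "C_N", "E_B"), (None,) * 3, 350),
        (("C_C", "E_B", "E_F"), (300.0, None, None), 750),  # (300+300)+50+100
        (("C_C",) * 3, (600.0, 600.0, 600.0), 900),  # capture at the bell: no time term
    ],
)
def test_trawl_vulnerability_values(outcomes, times, expected):
    assert trawl_vulnerability(_trawl(outcomes, times)).score == expected


def test_trawl_trial_validation():
    with pytest.raises(ValueError, match="capture_time"):
        TrawlTrial("C_C", 1)  # C_C needs a time
    with pytest.raises(ValueError, match="capture_time"):
        TrawlTrial("E_B", 1, capture_time=10.0)  # escapes have none
    with pytest.raises(ValueError):
        TrawlTrial("C_C", 1, capture_time=601.0)
    with pytest.raises(ValueError, match="3 trials"):
        trawl_vulnerability(_trawl(("E_B", "E_B")))


def test_trawl_bounds_exhaustive():
    """V stays in [150, 2700] over all outcome combinations x gridded times."""
    times = [0.0, 150.0, 300.0, 450.0, 600.0]
    for combo in itertools.product(OUTCOMES, repeat=3):
        for ts in itertools.product(times, repeat=3):
            trial_times = [t if o == "C_C" else None for o, t in zip(combo, ts)]
            v = trawl_vulnerability(_trawl(combo, trial_times)).score
            assert 150 <= v <= 2700


def test_trawl_monotone_in_severity():
    """Upgrading any outcome to a more severe one never lowers V."""
    order = {o: i for i, o in enumerate(OUTCOMES)}
    rng = np.random.default_rng(0)
    for _ in range(200):
        combo = rng.choice(OUTCOMES, 3)
        ts = [rng.uniform(0, 600) if o == "C_C" else None for o in combo]
        v = trawl_vulnerability(_trawl(combo, ts)).score
        slot = rng.integers(3)
        cur = order[combo[slot]]
        if cur == 3:
            # decreasing capture time never decreases V
            t2 = list(ts)
            t2[slot] = ts[slot] / 2
            assert trawl_vulnerability(_trawl(combo, t2)).score >= v
        else:
            up = list(combo)
            up[slot] = OUTCOMES[cur + 1]
            t2 = list(ts)
            t2[slot] = 600.0 if up[slot] == "C_C" else None
            assert trawl_vulnerability(_trawl(up, t2)).score >= v


@pytest.mark.parametrize(
    "captured,expected",
    [((True, True, True), 6), ((False, False, False), 0), ((False, True, False), 2),
     ((True, False, True), 4)],
)
def test_trap_vulnerability(captured, expected):
    trials = [TrapTrial(c, i + 1) for i, c in enumerate(captured)]
    assert trap_vulnerability(trials).score == expected


@given(st.lists(st.booleans(), min_size=3, max_size=3))
@settings(deadline=None)
def test_trap_bounds(captures):
    trials = [TrapTrial(c, i + 1) for i, c in enumerate(captures)]
    assert 0 <= trap_vulnerability(trials).score <= 6


def _indices(scores, gear="trawl"):
    return [
        VulnerabilityIndex(fish_id=f"f{i:02d}", gear=gear, score=s)
        for i, s in enumerate(scores)
    ]


def test_group_assignment_counts():
    """8 distinct scores at fraction 0.25 -> 2 high, 2 low, 4 middle."""
    out = assign_vulnerability_groups(_indices([10, 20, 30, 40, 50, 60, 70, 80]))
    groups = [i.group for i in out]
    assert groups.count("high") == 2 and groups.count("low") == 2
    assert groups.count("middle") == 4
    by_score = {i.score: i.group for i in out}
    assert by_score[80] == "high" and by_score[10] == "low"


def test_group_assignment_partitions_and_balance():
    rng = np.random.default_rng(3)
    scores = rng.integers(0, 2000, 24).tolist()
    out = assign_vulnerability_groups(_indices(scores), fraction=0.25, seed=1)
    counts = {g: sum(i.group == g for i in out) for g in ("high", "low", "middle")}
    assert counts["high"] == counts["low"] == 6  # n*fraction integral
    assert sum(counts.values()) == 24


def test_group_assignment_tie_break_reproducible():
    """A 3-way tie across the lower boundary yields ceil(2.5)=3 low fish,
    reproducibly under a fixed seed."""
    scores = [5, 5, 5, 10, 20, 30, 40, 50, 60, 70]
    out1 = assign_vulnerability_groups(_indices(scores), seed=7)
    out2 = assign_vulnerability_groups(_indices(scores), seed=7)
    lows1 = sorted(i.fish_id for i in out1 if i.group == "low")
    lows2 = sorted(i.fish_id for i in out2 if i.group == "low")
    assert len(lows1) == 3 and lows1 == lows2
    assert {i.fish_id for i in out1 if i.score == 5} >= set(lows1)


def test_group_assignment_errors():
    with pytest.raises(ValueError, match="identical"):
        assign_vulnerability_groups(_indices([5, 5, 5, 5]))
    with pytest.raises(ValueError, match="at least 4"):
        assign_vulnerability_groups(_indices([1, 2, 3]))
    with pytest.raises(ValueError, match="fraction"):
        assign_vulnerability_groups(_indices([1, 2, 3, 4]), fraction=0.8)


def test_group_assignment_stratified():
    """Quartiles computed within each tank, not pooled."""
    idx = _indices(list(range(8)) + [100 + s for s in range(8)])
    tanks = {i.fish_id: ("T1" if int(i.fish_id[1:]) < 8 else "T2") for i in idx}
    out = assign_vulnerability_groups(idx, stratify_by=tanks)
    t1 = [i for i in out if tanks[i.fish_id] == "T1"]
    assert sum(i.group == "high" for i in t1) == 2  # high fish exist in the low tank
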