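"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive quantities by direct enumeration (scanning runs
minute by minute, counting transitions pair by pair) so that tests never
share code paths with the implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

ACTIVE, INACTIVE, MISSING = 1, 0, -1


def brute_force_bouts(states, min_bout):
    """Enumerate maximal runs of consecutive inactive minutes by direct scan."""
    bouts = []
    run_start = None
    for i, s in enumerate(list(states) + [ACTIVE]):  # sentinel terminates last run
        if s == INACTIVE:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= min_bout:
                bouts.append((run_start, i - run_start))
            run_start = None
    return bouts


def brute_force_phase_metrics(states, phases, min_bout):
    """Per-phase (total, n_episodes, max_episode) by direct re-computation."""
    bouts = brute_force_bouts(states, min_bout)
    out = {}
    for phase in ("LP", "DP"):
        total = n_epi = max_epi = 0
        for start, dur in bouts:
            seg = [phases[i] == phase for i in range(start, start + dur)]
            overlap = sum(seg)
            if overlap == 0:
                continue
            total += overlap
            if phases[start] == phase:
                n_epi += 1
            best = cur = 0
            for inp in seg:
                cur = cur + 1 if inp else 0
                best = max(best, cur)
            max_epi = max(max_epi, best)
        out[phase] = (total, n_epi, max_epi)
    return out


def brute_force_transitions(states, window=None):
    """Pairwise transition/opportunity counts by explicit iteration."""
    nw = ow = nd = od = 0
    for t in range(len(states) - 1):
        if window is not None and not window[t]:
            continue
        a, b = states[t], states[t + 1]
        if a == MISSING or b == MISSING:
            continue
        if a == INACTIVE:
            ow += 1
            nw += b == ACTIVE
        else:
            od += 1
            nd += b == INACTIVE
    return nw, ow, nd, od


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def small_screen():
    """A small simulated screen reused by IO/pipeline tests."""
    from sleepscreen.simulate import SimulationConfig, simulate_screen

    return simulate_screen(SimulationConfig(n_drivers=3, flies_per_genotype=4, seed=7))
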