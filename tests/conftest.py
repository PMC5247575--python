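from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from matesort.config import SimConfig
from matesort.network import ChoiceNetwork


@pytest.fixture
def default_config() -> SimConfig:
    return SimConfig()


@pytest.fixture
def small_config() -> SimConfig:
    """Six lines, six replicates: fast enough for repeated-simulation tests."""
    return SimConfig(n_lines=6, n_reps_per_pair=6)


def net_from_prefs(prefs: dict[tuple[str, str], float]) -> ChoiceNetwork:
    return ChoiceNetwork.from_preferences(prefs)


def transitive_net(lines: list[str], p_win: float = 0.9) -> ChoiceNetwork:
    """Fully transitive network: earlier lines beat later ones."""
    prefs = {}
    for a, b in combinations(lines, 2):
        prefs[(a, b)] = p_win
    return ChoiceNetwork.from_preferences(prefs)


def random_tournament_net(n_lines: int, rng: np.random.Generator) -> ChoiceNetwork:
    """Complete network with uniformly random edge orientations."""
    lines = [f"L{i:02d}" for i in range(n_lines)]
    prefs = {}
    for a, b in combinations(lines, 2):
        prefs[(a, b)] = 0.9 if rng.random() < 0.5 else 0.1
    return ChoiceNetwork.from_preferences(prefs)


def brute_force_triads(net: ChoiceNetwork) -> tuple[int, int, int]:
    """Independent triple-by-triple classifier used as the census oracle."""
    n_tr = n_cy = n_tie = 0
    for a, b, c in combinations(sorted(net.lines), 2 + 1):
        winners = []
        any_tie = False
        for x, y in ((a, b), (b, c), (a, c)):
            w = net.orientation(x, y)
            if w is None:
                any_tie = True
            winners.append(w)
        if any_tie:
            n_tie += 1
            continue
        beats = {l: sum(1 for w in winners if w == l) for l in (a, b, c)}
        if sorted(beats.values()) == [0, 1, 2]:
            n_tr += 1
        else:
            n_cy += 1
    return n_tr, n_cy, n_tie
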