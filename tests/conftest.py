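"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import pytest

from offpop.cfd import load_penalties, uniform_tables
from offpop.datasets import (
    load_demo_candidates,
    load_demo_guide,
    load_demo_site_variants,
)
from offpop.guide import GuideRNA, SPACER_LEN


@pytest.fixture(scope="session")
def guide() -> GuideRNA:
    return load_demo_guide()


@pytest.fixture(scope="session")
def tables():
    return load_penalties()


@pytest.fixture(scope="session")
def uniform():
    return uniform_tables(0.5)


@pytest.fixture(scope="session")
def demo_candidates():
    sites, expected = load_demo_candidates()
    return sites, expected


@pytest.fixture(scope="session")
def demo_site_variants():
    return load_demo_site_variants()


def brute_force_align(spacer: str, raw_seq: str):
    """Independent alignment oracle: enumerate every legal gap placement.

    Returns (indels, mismatches) minimal under lexicographic order, for
    candidates whose protospacer differs from the spacer length by at
    most two.  Completely independent of the banded DP.
    """
    proto = raw_seq[:-3]
    n, m = len(proto), len(spacer)
    k = n - m
    best = None
    if k == 0:
        placements = [((), ())]
    elif k > 0:  # k inserted bases in the target: drop k target indices
        placements = [((), idx) for idx in combinations(range(n), k)]
    else:  # -k deleted guide positions
        placements = [(idx, ()) for idx in combinations(range(m), -k)]
    for del_guide, ins_target in placements:
        g = [b for i, b in enumerate(spacer) if i not in del_guide]
        t = [b for j, b in enumerate(proto) if j not in ins_target]
        assert len(g) == len(t)
        mm = sum(1 for a, b in zip(g, t) if a != b)
        cost = (abs(k), mm)
        if best is None or cost < best:
            best = cost
    return best
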