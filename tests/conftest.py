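"""Shared fixtures: random-BOE generators and an independent combination oracle.

The brute-force oracle works on explicit frozensets over the full power set
and never touches the package's bit-set encoding, so it is an independent
check of Dempster's rule, not a re-derivation.
"""

from __future__ import annotations

from itertools import chain, combinations

import numpy as np
import pytest

from ncarbs.construction import ControlParameterSet, FIT_BOUNDS
from ncarbs.evidence import FrameOfDiscernment, MassFunction


def powerset_nonempty(labels):
    labels = tuple(labels)
    return [
        frozenset(c)
        for c in chain.from_iterable(
            combinations(labels, r) for r in range(1, len(labels) + 1)
        )
    ]


def brute_force_combine(m1: MassFunction, m2: MassFunction) -> dict[frozenset, float]:
    """Dense double loop over the full power set; returns a focal->mass dict."""
    labels = m1.frame.labels
    subsets = powerset_nonempty(labels)
    d1 = {s: 0.0 for s in subsets}
    d2 = {s: 0.0 for s in subsets}
    for s, v in m1.items():
        d1[s] = v
    for s, v in m2.items():
        d2[s] = v
    out = {s: 0.0 for s in subsets}
    conflict = 0.0
    for s1 in subsets:
        for s2 in subsets:
            product = d1[s1] * d2[s2]
            inter = s1 & s2
            if inter:
                out[inter] += product
            else:
                conflict += product
    return {s: v / (1.0 - conflict) for s, v in out.items()}


def random_mass_function(
    rng: np.random.Generator, frame: FrameOfDiscernment, max_focal: int | None = None
) -> MassFunction:
    """A random BOE: Dirichlet masses over a random subset of focal elements."""
    subsets = powerset_nonempty(frame.labels)
    n_focal = int(rng.integers(1, (max_focal or len(subsets)) + 1))
    chosen = rng.choice(len(subsets), size=min(n_focal, len(subsets)), replace=False)
    weights = rng.dirichlet(np.ones(len(chosen)))
    # keep a sliver of mass on the full frame so any pair stays combinable
    masses = {subsets[i]: 0.95 * w for i, w in zip(chosen, weights)}
    full = frozenset(frame.labels)
    masses[full] = masses.get(full, 0.0) + 0.05
    return MassFunction(frame, masses)


def random_frame(rng: np.random.Generator, min_size: int = 2, max_size: int = 4):
    size = int(rng.integers(min_size, max_size + 1))
    return FrameOfDiscernment(tuple(f"d{i + 1}" for i in range(size)))


def random_parameter_set(
    rng: np.random.Generator, frame: FrameOfDiscernment, characteristics
) -> ControlParameterSet:
    """Quadruples drawn uniformly within the fit-time box constraints."""
    n_char = len(characteristics)
    lows = np.array([b[0] for b in FIT_BOUNDS])
    highs = np.array([b[1] for b in FIT_BOUNDS])
    values = rng.uniform(lows, highs, size=(n_char, frame.size, 4))
    return ControlParameterSet(values=values, frame=frame, characteristics=characteristics)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def abc_frame():
    return FrameOfDiscernment(("a", "b", "c"))


@pytest.fixture
def ab_frame():
    return FrameOfDiscernment(("a", "b"))
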