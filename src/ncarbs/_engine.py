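"""Vectorised numeric core of the classifier.

The object-level algebra in :mod:`ncarbs.evidence` is the reference
implementation; this module re-expresses the whole pipeline (confidence ->
constituent masses -> state BOEs -> object BOE -> pignistic vector ->
objective) as dense numpy array operations so that the evolutionary fit,
which evaluates the objective tens of thousands of times, stays fast.
Equivalence of the two routes is asserted by the test suite, not at runtime.

Representation: a BOE over an nD-state frame is a dense vector of length
2**nD indexed by the bit-set encoding of its focal element (index 0, the
empty set, always carries zero mass).  Constituent and state BOEs only ever
occupy the three slots {d_h}, complement, full frame and are kept as
"triplet" arrays; folding state BOEs for different states populates
arbitrary subsets, handled by a precomputed intersection tensor.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .construction import ControlParameterSet

__all__ = [
    "constituent_mass_arrays",
    "state_triplets",
    "object_dense",
    "betp_matrix",
    "objective_from_betp",
    "intersection_tensor",
    "pignistic_matrix",
]

_CONFLICT_TOL = 1e-12


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def constituent_mass_arrays(
    values: np.ndarray, params: ControlParameterSet
) -> np.ndarray:
    """Constituent masses for every (subject, characteristic, state).

    ``values`` has shape (n, nC) with NaN marking missing entries; the result
    has shape (n, nC, nD, 3) with last axis ({d_h}, complement, frame).
    Missing entries yield the vacuous triplet (0, 0, 1).
    """
    v = np.asarray(values, dtype=float)
    k = params.values[:, :, 0]
    theta = params.values[:, :, 1]
    A = np.minimum(params.values[:, :, 2], 1.0 - 1e-12)
    B = params.values[:, :, 3]

    missing = np.isnan(v)
    v_filled = np.where(missing, 0.0, v)
    cf = _sigmoid(k[None, :, :] * (v_filled[:, :, None] - theta[None, :, :]))
    m_state = np.maximum(0.0, B * (cf - A) / (1.0 - A))
    m_comp = np.maximum(0.0, B * (1.0 - A - cf) / (1.0 - A))
    masses = np.stack([m_state, m_comp, 1.0 - m_state - m_comp], axis=-1)
    masses[missing] = (0.0, 0.0, 1.0)
    return masses


def _combine_triplets(
    first: np.ndarray, second: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Dempster-combine two stacks of triplet BOEs sharing the same state.

    The triplet family ({d}, {not-d}, frame) is closed under conjunctive
    combination, with conflict K = a1*b2 + b1*a2.  Returns the combined
    triplets and a boolean mask of total-conflict entries (those rows are
    returned vacuous so the caller can decide how to handle them).
    """
    a1, b1, c1 = first[..., 0], first[..., 1], first[..., 2]
    a2, b2, c2 = second[..., 0], second[..., 1], second[..., 2]
    conflict = a1 * b2 + b1 * a2
    denom = 1.0 - conflict
    bad = denom <= _CONFLICT_TOL
    safe = np.where(bad, 1.0, denom)
    out = np.stack(
        [
            (a1 * a2 + a1 * c2 + c1 * a2) / safe,
            (b1 * b2 + b1 * c2 + c1 * b2) / safe,
            (c1 * c2) / safe,
        ],
        axis=-1,
    )
    out[bad] = (0.0, 0.0, 1.0)
    return out, bad


def state_triplets(masses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fold constituent masses over characteristics into state BOEs.

    Input shape (n, nC, nD, 3); output shape (n, nD, 3) plus an (n,) mask of
    subjects that hit total conflict along the way.
    """
    n, n_char = masses.shape[:2]
    result = masses[:, 0]
    bad_any = np.zeros(n, dtype=bool)
    for j in range(1, n_char):
        result, bad = _combine_triplets(result, masses[:, j])
        bad_any |= bad.any(axis=-1)
    return result, bad_any


@lru_cache(maxsize=8)
def intersection_tensor(n_states: int) -> np.ndarray:
    """T[s1, s2, x] = 1 where the bit-sets s1 and s2 intersect to x."""
    n_subsets = 1 << n_states
    tensor = np.zeros((n_subsets, n_subsets, n_subsets))
    for s1 in range(n_subsets):
        for s2 in range(n_subsets):
            tensor[s1, s2, s1 & s2] = 1.0
    return tensor


@lru_cache(maxsize=8)
def pignistic_matrix(n_states: int) -> np.ndarray:
    """P[s, h] = (d_h in s) / |s|, so BetP rows are dense @ P."""
    n_subsets = 1 << n_states
    matrix = np.zeros((n_subsets, n_states))
    for s in range(1, n_subsets):
        size = s.bit_count()
        for h in range(n_states):
            if s >> h & 1:
                matrix[s, h] = 1.0 / size
    return matrix


def _dense_from_triplet(triplet: np.ndarray, h: int, n_states: int) -> np.ndarray:
    """Scatter an (n, 3) state-h triplet into dense (n, 2**nD) layout."""
    n = triplet.shape[0]
    full = (1 << n_states) - 1
    singleton = 1 << h
    dense = np.zeros((n, 1 << n_states))
    dense[:, singleton] = triplet[:, 0]
    dense[:, full ^ singleton] += triplet[:, 1]
    dense[:, full] += triplet[:, 2]
    return dense


def object_dense(
    values: np.ndarray, params: ControlParameterSet
) -> tuple[np.ndarray, np.ndarray]:
    """Object BOEs for every subject, as dense (n, 2**nD) mass vectors.

    Also returns an (n,) boolean mask of subjects whose evidence was totally
    conflicting at some combination step (their rows are vacuous).
    """
    n_states = params.frame.size
    masses = constituent_mass_arrays(values, params)
    triplets, bad = state_triplets(masses)
    tensor = intersection_tensor(n_states)
    dense = _dense_from_triplet(triplets[:, 0], 0, n_states)
    for h in range(1, n_states):
        other = _dense_from_triplet(triplets[:, h], h, n_states)
        combined = np.einsum("ns,nt,stx->nx", dense, other, tensor)
        conflict = combined[:, 0]
        denom = 1.0 - conflict
        step_bad = denom <= _CONFLICT_TOL
        bad |= step_bad
        denom = np.where(step_bad, 1.0, denom)
        combined /= denom[:, None]
        combined[:, 0] = 0.0
        if np.any(step_bad):
            combined[step_bad] = 0.0
            combined[step_bad, (1 << n_states) - 1] = 1.0
        dense = combined
    return dense, bad


def betp_matrix(
    values: np.ndarray, params: ControlParameterSet
) -> tuple[np.ndarray, np.ndarray]:
    """Pignistic probabilities (n, nD) for every subject, plus conflict mask."""
    dense, bad = object_dense(values, params)
    return dense @ pignistic_matrix(params.frame.size), bad


def objective_from_betp(
    betp: np.ndarray, associations: np.ndarray, normaliser: str = "standard"
) -> float:
    """Mean Euclidean distance between pignistic and known association vectors.

    ``normaliser='standard'`` divides by nD * nO (range [0, sqrt(2)/nD]);
    ``'per-object'`` divides by nO only (range [0, sqrt(2)]).
    """
    distances = np.sqrt(((betp - associations) ** 2).sum(axis=1))
    n, n_states = associations.shape
    if normaliser == "standard":
        return float(distances.sum() / (n_states * n))
    if normaliser == "per-object":
        return float(distances.sum() / n)
    raise ValueError(f"unknown normaliser {normaliser!r}")
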