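"""Dempster-Shafer evidence algebra.

This module implements the small algebra every other part of the package is
built on: frames of discernment, mass functions (bodies of evidence, BOEs),
Dempster's rule of combination, the pignistic probability transform, and the
barycentric coordinates used for simplex plots.

A *frame of discernment* is an ordered set of mutually exclusive, exhaustive
states (e.g. the surgery types ``LA``, ``PA``, ``NP``).  A *mass function*
assigns exact belief to non-empty subsets of the frame (*focal elements*);
mass on a non-singleton subset represents evidence unable to discern among
its members, and mass on the whole frame is total ignorance.

Focal elements are encoded internally as bit-sets over the ordered frame
labels, which makes subset intersection a bitwise AND and keeps combination
O(F1 * F2) in the number of focal elements.  Publicly they surface as
``frozenset``s of labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "FrameOfDiscernment",
    "MassFunction",
    "PignisticVector",
    "FrameMismatchError",
    "TotalConflictError",
    "vacuous",
    "combine",
    "combine_all",
    "pignistic",
    "simplex_coordinates",
    "MASS_SUM_TOL",
    "CONFLICT_TOL",
]

#: tolerance on "masses sum to one" validation
MASS_SUM_TOL = 1e-9
#: 1 - K at or below this value is treated as total conflict
CONFLICT_TOL = 1e-12

FocalLike = Union[str, Iterable[str]]


class FrameMismatchError(ValueError):
    """Two mass functions over different frames cannot be combined."""


class TotalConflictError(ValueError):
    """Dempster combination of totally conflicting evidence (K = 1)."""


@dataclass(frozen=True)
class FrameOfDiscernment:
    """Ordered set of mutually exclusive states d_1, ..., d_nD (nD >= 2).

    The label order is fixed for the lifetime of a model: it defines the
    bit-set encoding of focal elements, the layout of control-parameter
    arrays and the component order of pignistic vectors.
    """

    labels: tuple[str, ...]

    def __init__(self, labels: Iterable[str]):
        labels = tuple(str(lab) for lab in labels)
        if len(labels) < 2:
            raise ValueError("a frame of discernment needs at least 2 states")
        if len(set(labels)) != len(labels):
            raise ValueError(f"frame labels must be unique, got {labels!r}")
        object.__setattr__(self, "labels", labels)

    @property
    def size(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    @property
    def full_mask(self) -> int:
        return (1 << len(self.labels)) - 1

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"state {label!r} not in frame {self.labels!r}") from None

    def mask_of(self, members: FocalLike) -> int:
        """Bit-set encoding of a subset of the frame."""
        if isinstance(members, str):
            members = (members,)
        mask = 0
        for lab in members:
            mask |= 1 << self.index(lab)
        return mask

    def members_of(self, mask: int) -> frozenset[str]:
        return frozenset(
            lab for i, lab in enumerate(self.labels) if mask >> i & 1
        )


class MassFunction:
    """A body of evidence: masses on non-empty subsets of a frame.

    Masses must be non-negative and sum to one within ``MASS_SUM_TOL``.
    Zero-mass entries are dropped (canonical form), so iteration only ever
    yields genuine focal elements.  Equality is numeric with tolerance
    ``MASS_SUM_TOL`` per focal element.
    """

    __slots__ = ("frame", "_masses")

    def __init__(self, frame: FrameOfDiscernment, masses: Mapping[FocalLike, float]):
        canonical: dict[int, float] = {}
        for focal, value in masses.items():
            mask = focal if isinstance(focal, int) else frame.mask_of(focal)
            if mask == 0:
                raise ValueError("the empty set cannot carry mass")
            if mask > frame.full_mask:
                raise ValueError("focal element is not a subset of the frame")
            value = float(value)
            if value < 0.0:
                raise ValueError(f"negative mass {value!r} on {frame.members_of(mask)!r}")
            if value > 0.0:
                canonical[mask] = canonical.get(mask, 0.0) + value
        total = math.fsum(canonical.values())
        if abs(total - 1.0) > MASS_SUM_TOL:
            raise ValueError(f"masses sum to {total!r}, expected 1 within {MASS_SUM_TOL}")
        self.frame = frame
        self._masses = canonical

    # -- access -----------------------------------------------------------
    def mass(self, focal: FocalLike) -> float:
        """Mass on a focal element (0.0 if absent)."""
        return self._masses.get(self.frame.mask_of(focal), 0.0)

    def __getitem__(self, focal: FocalLike) -> float:
        return self.mass(focal)

    def items(self) -> Iterator[tuple[frozenset[str], float]]:
        for mask, value in self._masses.items():
            yield self.frame.members_of(mask), value

    @property
    def focal_elements(self) -> list[frozenset[str]]:
        return [self.frame.members_of(mask) for mask in self._masses]

    def mask_items(self) -> Iterator[tuple[int, float]]:
        """(bit-set, mass) pairs -- the internal encoding."""
        return iter(self._masses.items())

    def to_dense(self) -> np.ndarray:
        """Dense mass vector indexed by bit-set (length 2**nD, entry 0 is 0)."""
        dense = np.zeros(1 << self.frame.size)
        for mask, value in self._masses.items():
            dense[mask] = value
        return dense

    @classmethod
    def from_dense(cls, frame: FrameOfDiscernment, dense: Sequence[float]) -> "MassFunction":
        dense = np.asarray(dense, dtype=float)
        if dense.shape != (1 << frame.size,):
            raise ValueError("dense vector length must be 2**nD")
        return cls(frame, {mask: dense[mask] for mask in range(1, len(dense)) if dense[mask] != 0.0})

    # -- comparison -------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MassFunction):
            return NotImplemented
        if self.frame.labels != other.frame.labels:
            return False
        masks = set(self._masses) | set(other._masses)
        return all(
            abs(self._masses.get(m, 0.0) - other._masses.get(m, 0.0)) <= MASS_SUM_TOL
            for m in masks
        )

    __hash__ = None  # type: ignore[assignment]

    def __repr__(self) -> str:
        parts = ", ".join(
            f"{{{','.join(sorted(members))}}}: {value:.6g}" for members, value in self.items()
        )
        return f"MassFunction({parts})"


def vacuous(frame: FrameOfDiscernment) -> MassFunction:
    """The total-ignorance BOE: all mass on the full frame.

    It is the identity of Dempster combination and the representation of a
    missing characteristic value.
    """
    return MassFunction(frame, {frame.full_mask: 1.0})


def combine(m1: MassFunction, m2: MassFunction) -> MassFunction:
    """Dempster's rule of combination (conjunctive, conflict-renormalised).

    For every pair of focal elements the intersection receives the product of
    their masses; mass landing on the empty set (the conflict K) is discarded
    and the rest renormalised by 1 - K.

    Raises
    ------
    FrameMismatchError
        if the two BOEs live on different frames.
    TotalConflictError
        if 1 - K <= ``CONFLICT_TOL`` (irreconcilable evidence).
    """
    if m1.frame.labels != m2.frame.labels:
        raise FrameMismatchError(
            f"cannot combine BOEs over {m1.frame.labels!r} and {m2.frame.labels!r}"
        )
    accum: dict[int, float] = {}
    conflict = 0.0
    for mask1, v1 in m1.mask_items():
        for mask2, v2 in m2.mask_items():
            inter = mask1 & mask2
            product = v1 * v2
            if inter == 0:
                conflict += product
            else:
                accum[inter] = accum.get(inter, 0.0) + product
    denom = 1.0 - conflict
    if denom <= CONFLICT_TOL:
        raise TotalConflictError(f"total conflict in combination (K = {conflict!r})")
    return MassFunction(m1.frame, {mask: v / denom for mask, v in accum.items()})


def combine_all(boes: Iterable[MassFunction]) -> MassFunction:
    """Left-fold of :func:`combine`; order-independent by associativity."""
    result: MassFunction | None = None
    for m in boes:
        result = m if result is None else combine(result, m)
    if result is None:
        raise ValueError("combine_all needs at least one BOE")
    return result


@dataclass(frozen=True)
class PignisticVector:
    """Per-state pignistic probabilities BetP(d_h), summing to one."""

    frame: FrameOfDiscernment
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.shape != (self.frame.size,):
            raise ValueError("one probability per frame state required")
        if np.any(probs < -MASS_SUM_TOL) or abs(probs.sum() - 1.0) > MASS_SUM_TOL:
            raise ValueError("pignistic probabilities must be non-negative and sum to 1")

    def prob(self, label: str) -> float:
        return float(self.probs[self.frame.index(label)])

    def __getitem__(self, label: str) -> float:
        return self.prob(label)

    def to_dict(self) -> dict[str, float]:
        return {lab: float(p) for lab, p in zip(self.frame.labels, self.probs)}

    def __repr__(self) -> str:
        inner = ", ".join(f"{lab}: {p:.6g}" for lab, p in self.to_dict().items())
        return f"PignisticVector({inner})"


def pignistic(m: MassFunction) -> PignisticVector:
    """The pignistic (betting) probability transform.

    Each focal element's mass is split equally among its members:
    BetP(d_h) = sum over focal elements s containing d_h of m(s) / |s|.
    A Bayesian BOE (all singletons) is returned unchanged; the vacuous BOE
    becomes the uniform distribution.
    """
    probs = np.zeros(m.frame.size)
    for mask, value in m.mask_items():
        size = mask.bit_count()
        share = value / size
        for i in range(m.frame.size):
            if mask >> i & 1:
                probs[i] += share
    return PignisticVector(m.frame, probs)


#: height of the unit-side equilateral triangle
_SIMPLEX_HEIGHT = math.sqrt(3.0) / 2.0


def simplex_coordinates(triple: Sequence[float], *, atol: float = 1e-8) -> tuple[float, float]:
    """Barycentric position of a mass triple in the unit-side simplex plot.

    The triple (v1, v2, v3) must be non-negative and sum to one; the triangle
    vertices are (1, 0) for v1 = 1, (0, 0) for v2 = 1 and (0.5, sqrt(3)/2)
    for v3 = 1, with x = v1 + 0.5 v3 and y = (sqrt(3)/2) v3.

    For a constituent BOE the triple is (m({d}), m({not-d}), m(frame)); for a
    three-state prediction it is the pignistic triple in frame order.
    """
    v = np.asarray(triple, dtype=float)
    if v.shape != (3,):
        raise ValueError("simplex coordinates require exactly three mass values")
    if np.any(v < -atol) or abs(v.sum() - 1.0) > atol:
        raise ValueError(f"mass triple must be non-negative and sum to 1, got {v!r}")
    x = float(v[0] + 0.5 * v[2])
    y = float(_SIMPLEX_HEIGHT * v[2])
    return x, y
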