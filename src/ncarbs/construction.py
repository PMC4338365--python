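"""Constituent-BOE construction from characteristic values.

A standardised characteristic value v is turned into evidence about one state
d_h in two stages:

1. a sigmoid confidence function
   cf(v) = 1 / (1 + exp(-k (v - theta)))
   with slope k and centre theta, both on the standardised characteristic
   scale;

2. a clipped linear mapping of the confidence onto a three-focal-element BOE
   over {d_h}, {not-d_h} and the whole frame:

   m({d_h})     = max(0, B/(1-A) * cf - A*B/(1-A))
   m({not-d_h}) = max(0, -B/(1-A) * cf + B)
   m(frame)     = 1 - m({d_h}) - m({not-d_h})

   A in [0, 1) is the confidence knot below which no directed mass is
   assigned, and B in [0, 0.6) caps the directed mass.

With A < 0.5 there is a confidence interval (A, 1-A) on which both clipping
branches are inactive and the ignorance mass sits on a constant plateau
1 - B(1-2A)/(1-A); with A > 0.5 the two branches overlap and the interval
(1-A, A) carries total ignorance (m(frame) = 1).

A missing value contributes the vacuous BOE, the identity of Dempster
combination, so incomplete records need no imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .evidence import FrameOfDiscernment, MassFunction, vacuous

__all__ = [
    "ControlQuadruple",
    "ControlParameterSet",
    "ConstituentEvidence",
    "FIT_BOUNDS",
    "confidence",
    "mass_triplet",
    "constituent_boe",
    "constituent_for_value",
]

#: fit-time box constraints on (k, theta, A, B), in that order.  They assume
#: characteristics standardised to mean 0 / SD 1 and are enforced by the
#: optimiser; user-supplied parameter sets may exceed them (validation mode
#: only), e.g. when drawing contribution curves for hypothetical parameters.
FIT_BOUNDS: tuple[tuple[float, float], ...] = (
    (-5.0, 5.0),   # k: sigmoid slope
    (-3.0, 3.0),   # theta: sigmoid centre
    (0.0, 1.0),    # A: lower confidence knot (strictly < 1)
    (0.0, 0.6),    # B: maximum directed mass (strictly < 0.6)
)


class ControlQuadruple(NamedTuple):
    """The four control parameters shaping one (characteristic, state) item
    of evidence."""

    k: float
    theta: float
    A: float
    B: float

    def violations(self) -> list[str]:
        """Names of fit-time constraints this quadruple breaks (may be empty)."""
        out = []
        for name, value, (lo, hi) in zip(self._fields, self, FIT_BOUNDS):
            strict_hi = name in ("A", "B")
            if value < lo or value > hi or (strict_hi and value == hi):
                out.append(f"{name}={value!r} outside [{lo}, {hi}{')' if strict_hi else ']'}")
        return out


def confidence(v: float | np.ndarray, q: ControlQuadruple) -> float | np.ndarray:
    """Sigmoid confidence cf(v) = 1/(1 + exp(-k (v - theta))), overflow-safe."""
    return _sigmoid(q.k * (np.asarray(v, dtype=float) - q.theta))


def _sigmoid(z: np.ndarray) -> float | np.ndarray:
    # evaluate on the branch whose exp argument is non-positive
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return float(out) if out.ndim == 0 else out


def mass_triplet(
    cf: float | np.ndarray, A: float, B: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The clipped linear mass equations, vectorised over ``cf``.

    Returns (m({d}), m({not-d}), m(frame)).  Raises if A >= 1, where the
    mapping is undefined.
    """
    if A >= 1.0:
        raise ValueError(f"control parameter A must be < 1, got {A!r}")
    cf = np.asarray(cf, dtype=float)
    m_state = np.maximum(0.0, B * (cf - A) / (1.0 - A))
    m_complement = np.maximum(0.0, B * (1.0 - A - cf) / (1.0 - A))
    m_ignorance = 1.0 - m_state - m_complement
    return m_state, m_complement, m_ignorance


@dataclass(frozen=True)
class ConstituentEvidence:
    """One constituent BOE: evidence from a single characteristic value about
    a single state (``cf`` is None for a missing value)."""

    boe: MassFunction
    state: str
    cf: float | None = None
    characteristic: str | None = None


def constituent_boe(
    cf: float,
    q: ControlQuadruple,
    state: str,
    frame: FrameOfDiscernment,
    characteristic: str | None = None,
) -> ConstituentEvidence:
    """Stage (b): map a confidence value onto the {d}, {not-d}, frame triplet."""
    m_state, m_complement, m_ignorance = mass_triplet(cf, q.A, q.B)
    state_mask = 1 << frame.index(state)
    masses = {
        state_mask: float(m_state),
        frame.full_mask ^ state_mask: float(m_complement),
        frame.full_mask: float(m_ignorance),
    }
    return ConstituentEvidence(
        boe=MassFunction(frame, masses),
        state=state,
        cf=float(cf),
        characteristic=characteristic,
    )


def constituent_for_value(
    v: float | None,
    j: int,
    h: int,
    params: "ControlParameterSet",
) -> ConstituentEvidence:
    """Stages (a)+(b) for one (subject value, characteristic, state) triple.

    ``v`` may be None or NaN (missing), in which case the vacuous BOE is
    returned: absent evidence is neutral under combination.
    """
    state = params.frame.labels[h]
    name = params.characteristics[j]
    if v is None or (isinstance(v, float) and math.isnan(v)) or np.isnan(v):
        return ConstituentEvidence(boe=vacuous(params.frame), state=state, cf=None, characteristic=name)
    q = params.quadruple(j, h)
    return constituent_boe(confidence(float(v), q), q, state, params.frame, characteristic=name)


@dataclass(frozen=True)
class ControlParameterSet:
    """The full learned model: one ControlQuadruple per (characteristic,
    state) pair, stored as an array of shape (nC, nD, 4) with last-axis order
    (k, theta, A, B)."""

    values: np.ndarray
    frame: FrameOfDiscernment
    characteristics: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "characteristics", tuple(self.characteristics))
        expected = (len(self.characteristics), self.frame.size, 4)
        if values.shape != expected:
            raise ValueError(f"parameter array must have shape {expected}, got {values.shape}")

    @property
    def n_characteristics(self) -> int:
        return len(self.characteristics)

    @property
    def n_parameters(self) -> int:
        return self.values.size

    def quadruple(self, j: int, h: int) -> ControlQuadruple:
        return ControlQuadruple(*self.values[j, h])

    def to_vector(self) -> np.ndarray:
        """Flatten to the optimiser's vector layout: C-order over (j, h, param)."""
        return self.values.ravel().copy()

    @classmethod
    def from_vector(
        cls,
        vector: Sequence[float],
        frame: FrameOfDiscernment,
        characteristics: Iterable[str],
    ) -> "ControlParameterSet":
        characteristics = tuple(characteristics)
        values = np.asarray(vector, dtype=float).reshape(len(characteristics), frame.size, 4)
        return cls(values=values, frame=frame, characteristics=characteristics)

    @classmethod
    def fit_bounds(
        cls, n_characteristics: int, n_states: int
    ) -> list[tuple[float, float]]:
        """Box constraints for the flattened vector, in vector layout order."""
        return list(FIT_BOUNDS) * (n_characteristics * n_states)

    def violations(self) -> list[str]:
        """Fit-time constraint violations across all quadruples."""
        out = []
        for j in range(self.n_characteristics):
            for h in range(self.frame.size):
                for msg in self.quadruple(j, h).violations():
                    out.append(f"({self.characteristics[j]}, {self.frame.labels[h]}): {msg}")
        return out
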