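"""Synthetic Trendelenburg-style cohorts with known class structure.

The clinical dataset the classifier was designed around (43 subjects, three
Trendelenburg-stance characteristics, three classes: lateral-approach THA
``LA``, posterior-approach THA ``PA``, no pathology ``NP``) is not publicly
deposited.  This module generates cohorts that emulate its *structure* —
class sizes 14/13/16, per-class Gaussian characteristic distributions,
optional missing values — so every pipeline stage can be exercised end to
end with a known ground truth.

Only the frontal-plane hip moment (C2) means and SDs for the LA and PA
classes are published (0.49 +/- 0.22 and 0.59 +/- 0.34 Nm/kg); every other
default distribution below is an invented, moderately overlapping value and
must not be read as a property of the clinical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .construction import ControlParameterSet
from .evidence import FrameOfDiscernment
from .model import SubjectDataset

__all__ = [
    "ClassSpec",
    "CohortSpec",
    "generate",
    "default_cohort_spec",
    "separated_cohort_spec",
    "WorkedFixture",
    "worked_fixture",
]


@dataclass(frozen=True)
class ClassSpec:
    """One class: label, size, per-characteristic Gaussian location/scale."""

    label: str
    size: int
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", tuple(float(x) for x in self.means))
        object.__setattr__(self, "sds", tuple(float(x) for x in self.sds))
        if self.size < 1:
            raise ValueError(f"class {self.label!r} needs size >= 1")
        if len(self.means) != len(self.sds):
            raise ValueError("means and sds must have equal length")
        if any(s <= 0 for s in self.sds):
            raise ValueError(f"class {self.label!r} scales must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort: classes, characteristic names, a
    missingness rate in [0, 1) and the generation seed."""

    classes: tuple[ClassSpec, ...]
    characteristics: tuple[str, ...]
    missingness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "characteristics", tuple(self.characteristics))
        if len(self.classes) < 2:
            raise ValueError("a cohort needs at least two classes")
        labels = [c.label for c in self.classes]
        if len(set(labels)) != len(labels):
            raise ValueError("class labels must be unique")
        for c in self.classes:
            if len(c.means) != len(self.characteristics):
                raise ValueError(
                    f"class {c.label!r} has {len(c.means)} means for "
                    f"{len(self.characteristics)} characteristics"
                )
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must be in [0, 1)")

    @property
    def frame(self) -> FrameOfDiscernment:
        return FrameOfDiscernment(c.label for c in self.classes)

    @property
    def n_subjects(self) -> int:
        return sum(c.size for c in self.classes)

    def to_dict(self) -> dict[str, object]:
        return {
            "characteristics": list(self.characteristics),
            "missingness": self.missingness,
            "seed": self.seed,
            "classes": [
                {
                    "label": c.label,
                    "size": c.size,
                    "means": list(c.means),
                    "sds": list(c.sds),
                }
                for c in self.classes
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "CohortSpec":
        try:
            classes = tuple(
                ClassSpec(
                    label=str(c["label"]),
                    size=int(c["size"]),
                    means=tuple(c["means"]),
                    sds=tuple(c["sds"]),
                )
                for c in data["classes"]  # type: ignore[index]
            )
            return cls(
                classes=classes,
                characteristics=tuple(data["characteristics"]),  # type: ignore[arg-type]
                missingness=float(data.get("missingness", 0.0)),  # type: ignore[union-attr]
                seed=int(data.get("seed", 0)),  # type: ignore[union-attr]
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed cohort spec: {exc}") from exc


def generate(spec: CohortSpec, seed: int | None = None) -> SubjectDataset:
    """Draw a cohort: per-class independent Gaussians per characteristic,
    crisp unit-vector associations, missing cells injected uniformly at
    random at ``spec.missingness``.  Reproducible for a fixed seed
    (``seed`` overrides ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frame = spec.frame
    blocks, ids, assoc_rows = [], [], []
    for h, cls in enumerate(spec.classes):
        block = rng.normal(
            loc=cls.means, scale=cls.sds, size=(cls.size, len(spec.characteristics))
        )
        blocks.append(block)
        ids.extend(f"{cls.label}{i + 1:02d}" for i in range(cls.size))
        unit = np.zeros(frame.size)
        unit[h] = 1.0
        assoc_rows.extend([unit] * cls.size)
    values = np.vstack(blocks)
    if spec.missingness > 0.0:
        values[rng.random(values.shape) < spec.missingness] = np.nan
    return SubjectDataset(
        ids=ids,
        values=values,
        frame=frame,
        characteristics=spec.characteristics,
        associations=np.vstack(assoc_rows),
    )


def default_cohort_spec(missingness: float = 0.0, seed: int = 0) -> CohortSpec:
    """The Trendelenburg-style default cohort: 14 LA / 13 PA / 16 NP subjects
    over C1 pelvic obliquity (deg), C2 frontal-plane hip moment (Nm/kg) and
    C3 frontal-plane hip power (W/kg) at 30 s of single-leg stance.

    The C2 Gaussians for LA and PA are the published cohort summaries
    (0.49 +/- 0.22 and 0.59 +/- 0.34); all other values are invented
    moderate-overlap defaults.
    """
    return CohortSpec(
        classes=(
            ClassSpec("LA", 14, means=(-0.8, 0.49, 0.05), sds=(2.0, 0.22, 0.15)),
            ClassSpec("PA", 13, means=(1.0, 0.59, 0.12), sds=(2.0, 0.34, 0.18)),
            ClassSpec("NP", 16, means=(2.2, 0.85, 0.28), sds=(2.0, 0.30, 0.22)),
        ),
        characteristics=("C1_pelvic_obliquity", "C2_frontal_moment", "C3_frontal_power"),
        missingness=missingness,
        seed=seed,
    )


def separated_cohort_spec(
    separation: float,
    sizes: Sequence[int] = (14, 13, 16),
    labels: Sequence[str] = ("LA", "PA", "NP"),
    n_characteristics: int = 3,
    seed: int = 0,
) -> CohortSpec:
    """Three-class cohort with adjacent class means ``separation`` pooled SDs
    apart on every characteristic (unit within-class SD) — the dial used to
    study accuracy as a function of class overlap."""
    if len(sizes) != len(labels):
        raise ValueError("one size per label required")
    names = tuple(f"c{j + 1}" for j in range(n_characteristics))
    classes = tuple(
        ClassSpec(
            label,
            size,
            means=(g * float(separation),) * n_characteristics,
            sds=(1.0,) * n_characteristics,
        )
        for g, (label, size) in enumerate(zip(labels, sizes))
    )
    return CohortSpec(classes=classes, characteristics=names, seed=seed)


# ---------------------------------------------------------------------------
# Worked fixture: a fully hand-checkable 2-subject, 2-characteristic,
# 2-state instance.  The expected values below were computed with an
# independent brute-force implementation (explicit subset dictionaries,
# scalar arithmetic) and are frozen as the regression baseline.
# ---------------------------------------------------------------------------

_FIXTURE_VALUES = np.array([[0.5, -1.0], [-0.25, 0.8]])
_FIXTURE_ASSOC = np.array([[1.0, 0.0], [0.0, 1.0]])
# (j, h) -> (k, theta, A, B)
_FIXTURE_QUADS = np.array(
    [
        [[2.0, 0.0, 0.2, 0.5], [-1.5, 0.3, 0.1, 0.4]],
        [[1.0, -0.5, 0.3, 0.55], [-2.5, 0.1, 0.25, 0.5]],
    ]
)

_FIXTURE_EXPECTED: dict[str, object] = {
    # cf[i][j][h]
    "cf": np.array(
        [
            [[0.7310585786300049, 0.425557483188341],
             [0.3775406687981454, 0.9399133498259924]],
            [[0.3775406687981454, 0.6952966693475654],
             [0.7858349830425586, 0.14804719803168945]],
        ]
    ),
    # constituent masses [i][j][h] -> (m({d_h}), m({not d_h}), m(frame))
    "constituent_masses": np.array(
        [
            [
                [[0.33191161164375305, 0.043088388356246954, 0.625],
                 [0.1446922147503738, 0.21086334080518176, 0.6444444444444445]],
                [[0.060924811198542844, 0.25336090308717146, 0.6857142857142857],
                 [0.4599422332173283, 0.0, 0.5400577667826717]],
            ],
            [
                [[0.1109629179988409, 0.2640370820011591, 0.625],
                 [0.26457629748780687, 0.0909792580677487, 0.6444444444444444]],
                [[0.3817274866762961, 0.0, 0.6182725133237039],
                 [0.0, 0.4013018679788737, 0.5986981320211263]],
            ],
        ]
    ),
    # object BOEs keyed by focal-element label tuples
    "object_boes": (
        {("A",): 0.2675684562395564, ("B",): 0.5117685804190624,
         ("A", "B"): 0.22066296334138136},
        {("A",): 0.5672706362486466, ("B",): 0.21706012832624685,
         ("A", "B"): 0.2156692354251064},
    ),
    "betp": np.array(
        [
            [0.37789993791024706, 0.622100062089753],
            [0.6751052539611998, 0.3248947460388001],
        ]
    ),
    "objective_standard": 0.4586313377854337,
    "objective_per_object": 0.9172626755708674,
}


@dataclass(frozen=True)
class WorkedFixture:
    """Dataset + parameters + oracle-computed intermediates for regression
    tests.  ``expected`` keys: ``cf``, ``constituent_masses``,
    ``object_boes``, ``betp``, ``objective_standard``,
    ``objective_per_object``."""

    dataset: SubjectDataset
    params: ControlParameterSet
    expected: dict[str, object]


def worked_fixture() -> WorkedFixture:
    """A tiny instance whose every intermediate value is known exactly.

    The characteristic values are already on the standardised scale; the
    dataset carries no standardisation statistics on purpose so the pipeline
    consumes the values verbatim.
    """
    frame = FrameOfDiscernment(("A", "B"))
    dataset = SubjectDataset(
        ids=["o1", "o2"],
        values=_FIXTURE_VALUES.copy(),
        frame=frame,
        characteristics=("c1", "c2"),
        associations=_FIXTURE_ASSOC.copy(),
    )
    params = ControlParameterSet(
        values=_FIXTURE_QUADS.copy(), frame=frame, characteristics=("c1", "c2")
    )
    return WorkedFixture(dataset=dataset, params=params, expected=dict(_FIXTURE_EXPECTED))
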