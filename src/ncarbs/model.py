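"""The NCaRBS classifier: datasets, BOE assembly, fitting and evaluation.

The workflow is: standardise the characteristic matrix, turn every
(subject, characteristic, state) triple into a constituent BOE, fold the
constituents with Dempster's rule into an *object* BOE per subject (via state
BOEs by default; via characteristic BOEs or a flat fold equivalently), take
the pignistic transform to get per-state probabilities, and classify by
dominant pignistic probability.  The control parameters (k, theta, A, B) per
(characteristic, state) are configured by minimising the mean Euclidean
distance between pignistic vectors and known association vectors with
Trigonometric Differential Evolution, keeping the best of several runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import _engine
from .construction import ControlParameterSet, constituent_for_value
from .evidence import (
    FrameOfDiscernment,
    MassFunction,
    PignisticVector,
    TotalConflictError,
    combine_all,
    pignistic,
    simplex_coordinates,
)
from .tde import OptimisationTrace, TDEConfig, optimise

__all__ = [
    "Standardisation",
    "SubjectDataset",
    "FitResult",
    "FitRun",
    "PredictionRecord",
    "Classification",
    "EvaluationResult",
    "standardise",
    "apply_standardisation",
    "state_boe",
    "characteristic_boe",
    "object_boe",
    "predict",
    "objective",
    "classify",
    "evaluate",
    "fit",
    "mass_contribution_curves",
    "betp_contribution_curves",
]

#: objective value substituted for totally-conflicting or non-finite
#: evaluations during the evolutionary search; far above the objective's
#: attainable range so such parameter vectors are never selected
_PENALTY = 10.0


@dataclass(frozen=True)
class Standardisation:
    """Per-characteristic location/scale used to map raw values to z-scores."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise ValueError("mean and sd must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.sd))):
            raise ValueError("standardisation statistics must be finite")
        if np.any(self.sd <= 0):
            raise ValueError("standardisation scale must be positive")


@dataclass
class SubjectDataset:
    """A subject-by-characteristic table with optional known associations.

    ``values`` is (n_subjects, n_characteristics) with NaN marking missing
    entries; ``associations`` is (n_subjects, n_states) of non-negative
    weights summing to one per row (crisp labels are unit vectors), or None
    for unlabelled data.  ``standardisation`` records the raw-scale statistics
    when the values have been standardised.
    """

    ids: list[str]
    values: np.ndarray
    frame: FrameOfDiscernment
    characteristics: tuple[str, ...]
    associations: np.ndarray | None = None
    standardisation: Standardisation | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = [str(i) for i in self.ids]
        self.characteristics = tuple(self.characteristics)
        n, n_char = self.values.shape
        if n < 1:
            raise ValueError("dataset needs at least one subject")
        if len(self.ids) != n:
            raise ValueError("one id per subject required")
        if len(set(self.ids)) != n:
            raise ValueError("subject ids must be unique")
        if len(self.characteristics) != n_char:
            raise ValueError("one name per characteristic column required")
        if self.associations is not None:
            self.associations = np.asarray(self.associations, dtype=float)
            if self.associations.shape != (n, self.frame.size):
                raise ValueError("associations must be (n_subjects, n_states)")
            if np.any(self.associations < 0) or np.any(
                np.abs(self.associations.sum(axis=1) - 1.0) > 1e-9
            ):
                raise ValueError("association rows must be non-negative and sum to 1")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_characteristics(self) -> int:
        return self.values.shape[1]

    def labels(self) -> list[str]:
        """Crisp class labels from the association vectors (argmax rows)."""
        if self.associations is None:
            raise ValueError("dataset has no known associations")
        return [self.frame.labels[h] for h in self.associations.argmax(axis=1)]

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.characteristics))
        frame.insert(0, "id", self.ids)
        if self.associations is not None:
            frame.insert(1, "label", self.labels())
        return frame


def standardise(dataset: SubjectDataset) -> SubjectDataset:
    """Standardise every characteristic to mean 0, sample SD 1 (ddof = 1).

    Statistics are computed from the observed (non-missing) entries only and
    stored on the returned dataset for reuse on prediction inputs.  Raises on
    characteristics with fewer than two observed values or zero spread.
    """
    values = dataset.values
    means = np.empty(dataset.n_characteristics)
    sds = np.empty(dataset.n_characteristics)
    for j, name in enumerate(dataset.characteristics):
        observed = values[:, j][~np.isnan(values[:, j])]
        if observed.size < 2:
            raise ValueError(f"characteristic {name!r} has fewer than 2 observed values")
        means[j] = observed.mean()
        sds[j] = observed.std(ddof=1)
        if sds[j] == 0.0:
            raise ValueError(f"characteristic {name!r} is degenerate (zero spread)")
    stats = Standardisation(mean=means, sd=sds)
    return apply_standardisation(dataset, stats)


def apply_standardisation(dataset: SubjectDataset, stats: Standardisation) -> SubjectDataset:
    """Map raw values through previously computed statistics (predict time)."""
    if stats.mean.shape != (dataset.n_characteristics,):
        raise ValueError("standardisation statistics do not match the dataset width")
    return SubjectDataset(
        ids=list(dataset.ids),
        values=(dataset.values - stats.mean) / stats.sd,
        frame=dataset.frame,
        characteristics=dataset.characteristics,
        associations=None if dataset.associations is None else dataset.associations.copy(),
        standardisation=stats,
    )


# ---------------------------------------------------------------------------
# BOE assembly (object-level reference route)
# ---------------------------------------------------------------------------

def _check_frames(dataset: SubjectDataset, params: ControlParameterSet) -> None:
    if dataset.frame.labels != params.frame.labels:
        raise ValueError(
            f"dataset frame {dataset.frame.labels!r} does not match "
            f"model frame {params.frame.labels!r}"
        )
    if dataset.characteristics != params.characteristics:
        raise ValueError(
            f"dataset characteristics {dataset.characteristics!r} do not match "
            f"model characteristics {params.characteristics!r}"
        )


def state_boe(
    dataset: SubjectDataset, i: int, h: int, params: ControlParameterSet
) -> MassFunction:
    """Evidence for state d_h: constituents of subject i folded over
    characteristics."""
    _check_frames(dataset, params)
    return combine_all(
        constituent_for_value(dataset.values[i, j], j, h, params).boe
        for j in range(dataset.n_characteristics)
    )


def characteristic_boe(
    dataset: SubjectDataset, i: int, j: int, params: ControlParameterSet
) -> MassFunction:
    """Evidence from characteristic c_j: constituents of subject i folded
    over states (up to 2**nD - 1 focal elements)."""
    _check_frames(dataset, params)
    return combine_all(
        constituent_for_value(dataset.values[i, j], j, h, params).boe
        for h in range(dataset.frame.size)
    )


def object_boe(
    dataset: SubjectDataset,
    i: int,
    params: ControlParameterSet,
    route: Literal["state", "characteristic", "flat"] = "state",
) -> MassFunction:
    """All of subject i's evidence in one BOE.

    The three routes (fold state BOEs, fold characteristic BOEs, or fold all
    constituents flat) agree by associativity/commutativity of Dempster's
    rule; ``state`` is the default narrative route.
    """
    _check_frames(dataset, params)
    if route == "state":
        return combine_all(
            state_boe(dataset, i, h, params) for h in range(dataset.frame.size)
        )
    if route == "characteristic":
        return combine_all(
            characteristic_boe(dataset, i, j, params)
            for j in range(dataset.n_characteristics)
        )
    if route == "flat":
        return combine_all(
            constituent_for_value(dataset.values[i, j], j, h, params).boe
            for j in range(dataset.n_characteristics)
            for h in range(dataset.frame.size)
        )
    raise ValueError(f"unknown route {route!r}")


# ---------------------------------------------------------------------------
# Prediction and classification
# ---------------------------------------------------------------------------

class Classification(NamedTuple):
    label: str
    ambiguous: bool


def classify(betp: PignisticVector | Sequence[float], frame: FrameOfDiscernment | None = None) -> Classification:
    """Dominant-association label: the state with maximal pignistic
    probability.  Ties go to the earliest label in frame order and are
    flagged ambiguous."""
    if isinstance(betp, PignisticVector):
        frame = betp.frame
        probs = betp.probs
    else:
        if frame is None:
            raise ValueError("a frame is required when passing a bare probability vector")
        probs = np.asarray(betp, dtype=float)
    winner = int(np.argmax(probs))
    ambiguous = bool(np.sum(np.isclose(probs, probs[winner], rtol=0.0, atol=1e-12)) > 1)
    return Classification(label=frame.labels[winner], ambiguous=ambiguous)


@dataclass(frozen=True)
class PredictionRecord:
    """One subject's prediction: object BOE, pignistic vector, simplex
    position (3-state frames only), dominant label and, when the truth is
    known, a correctness flag."""

    id: str
    boe: MassFunction
    betp: PignisticVector
    simplex: tuple[float, float] | None
    label: str
    ambiguous: bool
    truth: str | None = None

    @property
    def correct(self) -> bool | None:
        return None if self.truth is None else self.label == self.truth


def predict(
    dataset: SubjectDataset,
    params: ControlParameterSet,
    standardisation: Standardisation | None = None,
) -> list[PredictionRecord]:
    """Predict every subject's association to the frame states.

    Pass the training-set ``standardisation`` when ``dataset`` holds raw
    values; an already-standardised dataset is used as-is.  For three-state
    frames each record carries the simplex coordinate of its pignistic triple.
    """
    if standardisation is not None:
        dataset = apply_standardisation(dataset, standardisation)
    _check_frames(dataset, params)
    dense, bad = _engine.object_dense(dataset.values, params)
    if np.any(bad):
        culprit = dataset.ids[int(np.flatnonzero(bad)[0])]
        raise TotalConflictError(
            f"total evidential conflict for subject {culprit!r}; "
            "the control parameters are irreconcilable with its values"
        )
    truths = dataset.labels() if dataset.associations is not None else [None] * dataset.n_subjects
    records = []
    for i, subject_id in enumerate(dataset.ids):
        boe = MassFunction.from_dense(dataset.frame, dense[i])
        betp = pignistic(boe)
        label, ambiguous = classify(betp)
        simplex = (
            simplex_coordinates(betp.probs) if dataset.frame.size == 3 else None
        )
        records.append(
            PredictionRecord(
                id=subject_id,
                boe=boe,
                betp=betp,
                simplex=simplex,
                label=label,
                ambiguous=ambiguous,
                truth=truths[i],
            )
        )
    return records


def predictions_to_dataframe(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    """Tabular view of predictions (BetP columns, simplex x/y, labels)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"id": rec.id}
        for lab, p in rec.betp.to_dict().items():
            row[f"betp_{lab}"] = p
        if rec.simplex is not None:
            row["simplex_x"], row["simplex_y"] = rec.simplex
        row["predicted"] = rec.label
        row["ambiguous"] = rec.ambiguous
        if rec.truth is not None:
            row["truth"] = rec.truth
            row["correct"] = rec.correct
        rows.append(row)
    return pd.DataFrame(rows)


def objective(
    dataset: SubjectDataset,
    params: ControlParameterSet,
    normaliser: Literal["standard", "per-object"] = "standard",
) -> float:
    """The fit objective: mean Euclidean distance between each subject's
    pignistic vector and its known association vector.

    With the ``standard`` normaliser the sum is divided by nD * nO and the
    value lies in [0, sqrt(2)/nD]; ``per-object`` divides by nO only.
    Zero iff the pignistic vectors reproduce the associations exactly.
    """
    if dataset.associations is None:
        raise ValueError("objective requires known associations")
    _check_frames(dataset, params)
    betp, bad = _engine.betp_matrix(dataset.values, params)
    if np.any(bad):
        culprit = dataset.ids[int(np.flatnonzero(bad)[0])]
        raise TotalConflictError(f"total evidential conflict for subject {culprit!r}")
    return _engine.objective_from_betp(betp, dataset.associations, normaliser)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Confusion matrix (rows = actual, columns = predicted) and the derived
    rates.  ``precision`` entries are NaN when a class is never predicted
    (division by zero), with the affected classes listed in
    ``undefined_precision``."""

    confusion: pd.DataFrame
    overall_accuracy: float
    per_class_accuracy: dict[str, float]
    precision: dict[str, float]
    undefined_precision: list[str]
    n: int

    @classmethod
    def from_confusion(cls, confusion: pd.DataFrame) -> "EvaluationResult":
        counts = confusion.to_numpy(dtype=float)
        n = int(counts.sum())
        diag = np.diag(counts)
        row_totals = counts.sum(axis=1)
        col_totals = counts.sum(axis=0)
        per_class = {
            lab: float(diag[i] / row_totals[i]) if row_totals[i] else float("nan")
            for i, lab in enumerate(confusion.index)
        }
        precision = {}
        undefined = []
        for i, lab in enumerate(confusion.columns):
            if col_totals[i]:
                precision[lab] = float(diag[i] / col_totals[i])
            else:
                precision[lab] = float("nan")
                undefined.append(lab)
        return cls(
            confusion=confusion,
            overall_accuracy=float(diag.sum() / n),
            per_class_accuracy=per_class,
            precision=precision,
            undefined_precision=undefined,
            n=n,
        )

    def to_dict(self) -> dict[str, object]:
        return {
            "n": self.n,
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "precision": {
                k: (None if math.isnan(v) else v) for k, v in self.precision.items()
            },
            "confusion": {
                str(actual): {str(col): int(self.confusion.loc[actual, col]) for col in self.confusion.columns}
                for actual in self.confusion.index
            },
        }


def evaluate(
    truths: Sequence[str],
    predicted: Sequence[str],
    frame: FrameOfDiscernment,
) -> EvaluationResult:
    """Confusion counts and accuracy/precision rates for crisp labels.

    Per-class accuracy is diagonal / actual-class count; precision is
    diagonal / predicted-class count (as conventionally reported).
    """
    if len(truths) != len(predicted):
        raise ValueError("truths and predictions must align")
    index = {lab: i for i, lab in enumerate(frame.labels)}
    counts = np.zeros((frame.size, frame.size), dtype=int)
    for t, p in zip(truths, predicted):
        counts[index[t], index[p]] += 1
    confusion = pd.DataFrame(counts, index=list(frame.labels), columns=list(frame.labels))
    confusion.index.name = "actual"
    confusion.columns.name = "predicted"
    return EvaluationResult.from_confusion(confusion)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitRun:
    seed: int
    best_objective: float
    n_generations: int
    n_evaluations: int
    trace: OptimisationTrace


@dataclass
class FitResult:
    """Outcome of a best-of-n TDE configuration of the control parameters."""

    params: ControlParameterSet
    objective: float
    normaliser: str
    standardisation: Standardisation
    runs: list[FitRun]

    @property
    def best_run(self) -> FitRun:
        return min(self.runs, key=lambda run: run.best_objective)


def fit(
    dataset: SubjectDataset,
    config: TDEConfig | None = None,
    n_runs: int = 5,
    seed: int = 0,
    normaliser: Literal["standard", "per-object"] = "standard",
) -> FitResult:
    """Configure the control parameters by best-of-``n_runs`` TDE.

    The dataset is standardised first (unless it already carries
    standardisation statistics) and must have known associations.  Each run
    starts from an independent seed derived deterministically from ``seed``;
    the parameter set with the smallest objective across runs is returned
    together with a per-run diary.  Parameter vectors whose evidence is
    totally conflicting receive a large finite penalty during the search.
    """
    if dataset.associations is None:
        raise ValueError("fitting requires known associations")
    if dataset.standardisation is None:
        dataset = standardise(dataset)
    frame = dataset.frame
    characteristics = dataset.characteristics
    values = dataset.values
    associations = dataset.associations
    bounds = ControlParameterSet.fit_bounds(len(characteristics), frame.size)

    def vector_objective(vector: np.ndarray) -> float:
        params = ControlParameterSet.from_vector(vector, frame, characteristics)
        betp, bad = _engine.betp_matrix(values, params)
        if np.any(bad) or not np.all(np.isfinite(betp)):
            return _PENALTY
        return _engine.objective_from_betp(betp, associations, normaliser)

    run_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(n_runs) >> 1]
    runs: list[FitRun] = []
    best = None
    for run_seed in run_seeds:
        if config is None:
            run_config = TDEConfig(bounds=bounds, seed=run_seed)
        else:
            run_config = TDEConfig(
                bounds=bounds,
                F=config.F,
                CR=config.CR,
                Mt=config.Mt,
                NP=config.NP,
                max_generations=config.max_generations,
                seed=run_seed,
                stall_generations=config.stall_generations,
                stall_tol=config.stall_tol,
            )
        result = optimise(vector_objective, run_config)
        runs.append(
            FitRun(
                seed=run_seed,
                best_objective=result.fun,
                n_generations=result.trace.n_generations,
                n_evaluations=result.trace.n_evaluations,
                trace=result.trace,
            )
        )
        if best is None or result.fun < best.fun:
            best = result
    assert best is not None
    params = ControlParameterSet.from_vector(best.x, frame, characteristics)
    return FitResult(
        params=params,
        objective=best.fun,
        normaliser=normaliser,
        standardisation=dataset.standardisation,
        runs=runs,
    )


# ---------------------------------------------------------------------------
# Contribution curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MassCurves:
    """Constituent-BOE mass curves for one (characteristic, state) pair over
    a grid of standardised characteristic values."""

    grid: np.ndarray
    m_state: np.ndarray
    m_complement: np.ndarray
    m_ignorance: np.ndarray
    characteristic: str
    state: str


def mass_contribution_curves(
    params: ControlParameterSet, j: int, h: int, grid: Sequence[float]
) -> MassCurves:
    """Mass values of the general constituent BOE m_{.,j,h} along ``grid``.

    Pointwise identical to running a single value through the construction
    pipeline; the three curves sum to one everywhere.
    """
    grid = np.asarray(grid, dtype=float)
    single = ControlParameterSet(
        values=params.values[j : j + 1], frame=params.frame,
        characteristics=params.characteristics[j : j + 1],
    )
    masses = _engine.constituent_mass_arrays(grid[:, None], single)[:, 0, h, :]
    return MassCurves(
        grid=grid,
        m_state=masses[:, 0],
        m_complement=masses[:, 1],
        m_ignorance=masses[:, 2],
        characteristic=params.characteristics[j],
        state=params.frame.labels[h],
    )


@dataclass(frozen=True)
class BetPCurves:
    """Pignistic contribution of one characteristic: per-state BetP of the
    characteristic BOE along a grid of standardised values."""

    grid: np.ndarray
    probs: np.ndarray  # (len(grid), nD), rows sum to 1
    frame: FrameOfDiscernment
    characteristic: str


def betp_contribution_curves(
    params: ControlParameterSet, j: int, grid: Sequence[float]
) -> BetPCurves:
    """BetP curves from the characteristic BOE of c_j along ``grid``.

    Each grid point is treated as a virtual subject whose other
    characteristics are missing (vacuous evidence), so the object BOE reduces
    to the characteristic BOE of c_j.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.full((grid.size, params.n_characteristics), np.nan)
    values[:, j] = grid
    betp, bad = _engine.betp_matrix(values, params)
    if np.any(bad):
        raise TotalConflictError(
            f"total conflict in characteristic BOE of {params.characteristics[j]!r}"
        )
    return BetPCurves(
        grid=grid, probs=betp, frame=params.frame, characteristic=params.characteristics[j]
    )
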