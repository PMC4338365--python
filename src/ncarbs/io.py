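"""File formats: dataset CSV, model JSON, cohort-spec YAML, predictions CSV.

Dataset dialect: comma-separated UTF-8 with a mandatory header; an ``id``
column, an optional ``label`` column holding crisp class names, and one
numeric column per characteristic.  Empty cells and the sentinel ``NA`` mark
missing values.  Models are versioned JSON documents serialised at full
precision, so read(write(model)) round-trips exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .construction import ControlParameterSet
from .evidence import FrameOfDiscernment
from .model import (
    FitResult,
    PredictionRecord,
    Standardisation,
    SubjectDataset,
    predictions_to_dataframe,
)
from .synthetic import CohortSpec

__all__ = [
    "read_dataset",
    "write_dataset",
    "ModelDocument",
    "write_model",
    "read_model",
    "write_predictions",
    "read_cohort_spec",
    "write_cohort_spec",
    "MODEL_SCHEMA_VERSION",
]

MODEL_SCHEMA_VERSION = 1
_MISSING_SENTINELS = {"", "NA"}


def read_dataset(
    path: str | Path,
    id_column: str = "id",
    label_column: str = "label",
    states: Sequence[str] | None = None,
) -> SubjectDataset:
    """Load a subject-by-characteristic CSV.

    Every column other than ``id_column`` and ``label_column`` is a
    characteristic.  When a label column is present, crisp labels are
    expanded to unit association vectors over a frame whose state order is
    ``states`` if given, else the order of first appearance in the file.
    Without a label column the dataset loads unlabelled (predict accepts it,
    fit refuses it) and ``states`` must be supplied.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    if id_column not in table.columns:
        raise ValueError(f"{path}: missing required column {id_column!r}")
    has_labels = label_column in table.columns
    char_cols = [c for c in table.columns if c not in (id_column, label_column)]
    if not char_cols:
        raise ValueError(f"{path}: no characteristic columns found")

    ids = table[id_column].tolist()
    dupes = table[id_column][table[id_column].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate subject ids {sorted(set(dupes))!r}")

    values = np.empty((len(table), len(char_cols)))
    for j, col in enumerate(char_cols):
        for i, cell in enumerate(table[col]):
            cell = cell.strip()
            if cell in _MISSING_SENTINELS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} in column {col!r}, row {i + 2}"
                ) from None

    associations = None
    if has_labels:
        labels = [cell.strip() for cell in table[label_column]]
        if states is None:
            states = list(dict.fromkeys(labels))
        frame = FrameOfDiscernment(states)
        associations = np.zeros((len(table), frame.size))
        for i, lab in enumerate(labels):
            try:
                associations[i, frame.index(lab)] = 1.0
            except KeyError:
                raise ValueError(
                    f"{path}: unknown label {lab!r} in row {i + 2}; "
                    f"expected one of {tuple(frame.labels)!r}"
                ) from None
    else:
        if states is None:
            raise ValueError(
                f"{path}: no {label_column!r} column; pass the state names explicitly"
            )
        frame = FrameOfDiscernment(states)

    return SubjectDataset(
        ids=ids,
        values=values,
        frame=frame,
        characteristics=tuple(char_cols),
        associations=associations,
    )


def write_dataset(dataset: SubjectDataset, path: str | Path) -> Path:
    """Write a dataset in the package's CSV dialect (NaN -> ``NA``)."""
    path = Path(path)
    frame = dataset.to_dataframe()
    frame.to_csv(path, index=False, na_rep="NA")
    return path


# ---------------------------------------------------------------------------
# Model documents
# ---------------------------------------------------------------------------

class ModelDocument(dict):
    """A fitted model as a plain JSON-serialisable mapping (schema v1)."""


_REQUIRED_MODEL_FIELDS = {
    "schema_version": int,
    "frame": list,
    "characteristics": list,
    "standardisation": dict,
    "parameters": list,
}


def _model_document(
    params: ControlParameterSet,
    standardisation: Standardisation | None,
    fit_metadata: dict | None,
) -> ModelDocument:
    doc = ModelDocument(
        schema_version=MODEL_SCHEMA_VERSION,
        frame=list(params.frame.labels),
        characteristics=list(params.characteristics),
        standardisation={
            "mean": [] if standardisation is None else standardisation.mean.tolist(),
            "sd": [] if standardisation is None else standardisation.sd.tolist(),
        },
        parameters=params.values.tolist(),
    )
    if fit_metadata:
        doc["fit"] = fit_metadata
    return doc


def write_model(
    result: FitResult | ControlParameterSet,
    path: str | Path,
    standardisation: Standardisation | None = None,
) -> Path:
    """Serialise a fit result (or bare parameter set) to versioned JSON."""
    if isinstance(result, FitResult):
        params = result.params
        standardisation = result.standardisation
        fit_metadata = {
            "objective": result.objective,
            "normaliser": result.normaliser,
            "runs": [
                {
                    "seed": run.seed,
                    "best_objective": run.best_objective,
                    "n_generations": run.n_generations,
                    "n_evaluations": run.n_evaluations,
                }
                for run in result.runs
            ],
        }
    else:
        params = result
        fit_metadata = None
    path = Path(path)
    path.write_text(json.dumps(_model_document(params, standardisation, fit_metadata), indent=2))
    return path


def read_model(path: str | Path) -> tuple[ControlParameterSet, Standardisation | None, dict]:
    """Load a model document; returns (params, standardisation, metadata).

    Control parameters outside the fit-time bounds draw a warning, not an
    error: the bounds constrain the optimiser, not the mathematics.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid JSON ({exc})") from exc
    for name, kind in _REQUIRED_MODEL_FIELDS.items():
        if name not in doc:
            raise ValueError(f"{path}: model document missing field {name!r}")
        if not isinstance(doc[name], kind):
            raise ValueError(f"{path}: field {name!r} must be a {kind.__name__}")
    if doc["schema_version"] != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: unsupported schema version {doc['schema_version']!r} "
            f"(this package reads version {MODEL_SCHEMA_VERSION})"
        )
    frame = FrameOfDiscernment(doc["frame"])
    params = ControlParameterSet(
        values=np.asarray(doc["parameters"], dtype=float),
        frame=frame,
        characteristics=tuple(doc["characteristics"]),
    )
    violations = params.violations()
    if violations:
        warnings.warn(
            f"{path}: {len(violations)} control parameter(s) outside the usual "
            f"fit bounds (first: {violations[0]})",
            stacklevel=2,
        )
    std = doc["standardisation"]
    standardisation = None
    if std.get("mean"):
        standardisation = Standardisation(
            mean=np.asarray(std["mean"], dtype=float),
            sd=np.asarray(std["sd"], dtype=float),
        )
    metadata = doc.get("fit", {})
    return params, standardisation, metadata


def write_predictions(records: Sequence[PredictionRecord], path: str | Path) -> Path:
    path = Path(path)
    predictions_to_dataframe(records).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Cohort specs (YAML)
# ---------------------------------------------------------------------------

def read_cohort_spec(path: str | Path) -> CohortSpec:
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: cohort spec must be a mapping")
    return CohortSpec.from_dict(data)


def write_cohort_spec(spec: CohortSpec, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))
    return path
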