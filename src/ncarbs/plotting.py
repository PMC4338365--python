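"""Simplex and characteristic-contribution plots.

All figure data series come straight from the deterministic computation
layer (:mod:`ncarbs.model`), so for fixed inputs the plotted series are
byte-stable; only the rendering is matplotlib's business.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .construction import ControlParameterSet
from .model import (
    PredictionRecord,
    SubjectDataset,
    betp_contribution_curves,
    mass_contribution_curves,
)

__all__ = ["render_simplex", "render_contributions", "DEFAULT_GRID_POINTS"]

#: grid resolution for contribution curves between the observed min and max
DEFAULT_GRID_POINTS = 512

_H = math.sqrt(3.0) / 2.0
# simplex vertices for mass triples (v1, v2, v3): v1=1, v2=1, v3=1
_VERTICES = np.array([[1.0, 0.0], [0.0, 0.0], [0.5, _H]])
_CENTROID = _VERTICES.mean(axis=0)


def _dominance_region(h: int) -> np.ndarray:
    """Polygon (in simplex coordinates) where state h's share is maximal."""
    others = [i for i in range(3) if i != h]
    mid_a = (_VERTICES[h] + _VERTICES[others[0]]) / 2.0
    mid_b = (_VERTICES[h] + _VERTICES[others[1]]) / 2.0
    return np.array([_VERTICES[h], mid_a, _CENTROID, mid_b])


def render_simplex(
    predictions: Sequence[PredictionRecord],
    out_path: str | Path,
    group_by_truth: bool = True,
) -> Path:
    """Simplex plot(s) of predicted associations with the dominant-association
    region of each panel's class shaded grey.

    With ``group_by_truth`` (and known truths) one panel is drawn per actual
    class, mirroring how a cohort's fit is usually inspected; otherwise a
    single panel shows all subjects.  Requires a three-state frame.
    """
    predictions = list(predictions)
    if not predictions:
        raise ValueError("no predictions to plot")
    frame = predictions[0].betp.frame
    if frame.size != 3:
        raise ValueError("simplex plots require exactly three states")
    if group_by_truth and all(p.truth is not None for p in predictions):
        groups = [(lab, [p for p in predictions if p.truth == lab]) for lab in frame.labels]
    else:
        groups = [(None, predictions)]

    fig, axes = plt.subplots(1, len(groups), figsize=(4.0 * len(groups), 3.8), squeeze=False)
    for ax, (lab, records) in zip(axes[0], groups):
        ax.add_patch(plt.Polygon(_VERTICES, closed=True, fill=False, edgecolor="black", lw=1.0))
        if lab is not None:
            ax.add_patch(
                plt.Polygon(
                    _dominance_region(frame.index(lab)),
                    closed=True, facecolor="0.82", edgecolor="none", zorder=0,
                )
            )
        xy = np.array([rec.simplex for rec in records]) if records else np.empty((0, 2))
        if len(xy):
            ax.plot(xy[:, 0], xy[:, 1], "o", ms=5, mfc="white", mec="black")
        for vert, state in zip(_VERTICES, frame.labels):
            offset = np.sign(vert - _CENTROID) * 0.05
            ax.text(vert[0] + offset[0], vert[1] + offset[1], state,
                    ha="center", va="center", fontsize=9)
        ax.set_title("all subjects" if lab is None else f"actual {lab}", fontsize=10)
        ax.set_xlim(-0.12, 1.12)
        ax.set_ylim(-0.12, _H + 0.12)
        ax.set_aspect("equal")
        ax.axis("off")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def _overlay_rug_and_box(ax, observed: np.ndarray, y: float) -> None:
    """Data points plus a notched box summary above a contribution panel."""
    if observed.size == 0:
        return
    ax.plot(observed, np.full(observed.size, y), "|", color="black", ms=8, alpha=0.6)
    if observed.size >= 5:
        ax.boxplot(
            observed,
            positions=[y + 0.09],
            orientation="horizontal",
            widths=0.07,
            notch=observed.size >= 10,
            manage_ticks=False,
            flierprops={"ms": 3},
        )


def render_contributions(
    params: ControlParameterSet,
    dataset: SubjectDataset | None,
    j: int,
    out_path: str | Path,
    grid: Sequence[float] | None = None,
    n_points: int = DEFAULT_GRID_POINTS,
) -> Path:
    """Contribution figure for characteristic ``j``: one mass-curve panel per
    state (m({d}), m({not-d}), m(frame) vs the characteristic value) and one
    pignistic panel (per-state BetP of the characteristic BOE).

    The grid spans the observed min..max of the characteristic (dataset
    values are assumed to be on the same, standardised, scale as the model);
    with no dataset an explicit ``grid`` is required and no rug is drawn.
    """
    if grid is None:
        if dataset is None:
            raise ValueError("either a dataset or an explicit grid is required")
        observed = dataset.values[:, j]
        observed = observed[~np.isnan(observed)]
        if observed.size == 0:
            raise ValueError("characteristic has no observed values to set the grid")
        grid = np.linspace(observed.min(), observed.max(), n_points)
    else:
        grid = np.asarray(grid, dtype=float)
        observed = np.empty(0)
        if dataset is not None:
            observed = dataset.values[:, j]
            observed = observed[~np.isnan(observed)]

    n_states = params.frame.size
    fig, axes = plt.subplots(1, n_states + 1, figsize=(3.6 * (n_states + 1), 3.2))
    for h in range(n_states):
        curves = mass_contribution_curves(params, j, h, grid)
        ax = axes[h]
        ax.plot(curves.grid, curves.m_state, label=f"m({{{curves.state}}})")
        ax.plot(curves.grid, curves.m_complement, label="m(complement)")
        ax.plot(curves.grid, curves.m_ignorance, label="m(frame)", ls="--")
        _overlay_rug_and_box(ax, observed, 1.02)
        ax.set_ylim(-0.02, 1.25)
        ax.set_title(f"evidence about {curves.state}", fontsize=10)
        ax.set_xlabel(params.characteristics[j])
        ax.legend(fontsize=7)
    betp = betp_contribution_curves(params, j, grid)
    ax = axes[-1]
    for h, lab in enumerate(params.frame.labels):
        ax.plot(betp.grid, betp.probs[:, h], label=f"BetP({lab})")
    _overlay_rug_and_box(ax, observed, 1.02)
    ax.set_ylim(-0.02, 1.25)
    ax.set_title("pignistic contribution", fontsize=10)
    ax.set_xlabel(params.characteristics[j])
    ax.legend(fontsize=7)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
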