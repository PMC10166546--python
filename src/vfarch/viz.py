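"""Rendering of archetype maps and per-visit decomposition panels.

Maps use the 24-2 grid layout with a continuous grayscale dB ramp clipped to
[-41, +7] dB (darkest = deepest loss), the conventional display range for
total-deviation values.  Output is deterministic for fixed inputs (fixed
figure geometry and dpi, no timestamps in metadata).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless backend; must precede pyplot import
import matplotlib.pyplot as plt
import numpy as np

from .decomposition import Decomposition
from .grid import GRID
from .model import ArchetypeModel
from .records import VisualFieldRecord


@dataclass
class RenderSpec:
    vmin_db: float = -41.0
    vmax_db: float = 7.0
    cmap: str = "gray"
    dpi: int = 100
    marker_size: float = 120.0

    def __post_init__(self) -> None:
        if self.vmin_db >= self.vmax_db:
            raise ValueError("color scale bounds must be ordered")


def _plot_field(ax, td: np.ndarray, spec: RenderSpec) -> None:
    coords = GRID.active_coords
    ax.scatter(
        coords[:, 0],
        coords[:, 1],
        c=np.clip(td, spec.vmin_db, spec.vmax_db),
        cmap=spec.cmap,
        vmin=spec.vmin_db,
        vmax=spec.vmax_db,
        s=spec.marker_size,
        marker="s",
        edgecolors="none",
    )
    ax.set_xlim(-30, 30)
    ax.set_ylim(-27, 27)
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])


def render_model(
    model: ArchetypeModel,
    path: str | Path,
    spec: RenderSpec | None = None,
) -> Path:
    """One map per archetype, in descending-RW order, annotated with its RW
    and average TD.  Returns the written file path."""
    spec = spec or RenderSpec()
    k = model.k
    ncols = min(k, 5)
    nrows = int(np.ceil(k / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(2.2 * ncols, 2.6 * nrows), squeeze=False
    )
    for j in range(nrows * ncols):
        ax = axes[j // ncols][j % ncols]
        if j >= k:
            ax.axis("off")
            continue
        _plot_field(ax, model.archetypes[j], spec)
        ax.set_title(
            f"AT{j + 1}\nRW {model.relative_weights[j]:.1f}%  "
            f"TD̄ {model.average_td[j]:.1f} dB",
            fontsize=8,
        )
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=spec.dpi, metadata={"Software": None})
    plt.close(fig)
    return path


def render_trajectory(
    records: list[VisualFieldRecord],
    decompositions: list[Decomposition],
    path: str | Path,
    spec: RenderSpec | None = None,
    show_below_cutoff: bool = True,
) -> Path:
    """One row per visit: the field's TD map plus its meaningful archetypes
    with integer PW labels; sub-cutoff archetypes shown grayed when
    ``show_below_cutoff`` (largest first, up to one)."""
    if not records:
        raise ValueError("need at least one visit")
    if len(records) != len(decompositions):
        raise ValueError("records and decompositions must align")
    spec = spec or RenderSpec()
    order = np.argsort([r.visit_day for r in records], kind="stable")
    nrows = len(records)
    fig, axes = plt.subplots(nrows, 2, figsize=(6.5, 2.4 * nrows), squeeze=False)
    for row, idx in enumerate(order):
        rec, dec = records[idx], decompositions[idx]
        ax_map, ax_txt = axes[row]
        _plot_field(ax_map, rec.td, spec)
        ax_map.set_title(
            f"{rec.eye_id} day {rec.visit_day} ({rec.visit_type})  MD {rec.md:.1f} dB",
            fontsize=8,
        )
        lines = []
        meaningful = sorted(dec.meaningful_set, key=lambda j: -dec.pw[j - 1])
        for j in meaningful:
            lines.append((f"AT{j}: {round(dec.pw[j - 1]):d}%", "black"))
        if show_below_cutoff:
            below = [
                j + 1
                for j in np.argsort(-dec.pw)
                if (j + 1) not in dec.meaningful_set and dec.pw[j] >= 1
            ]
            for j in below[:1]:
                lines.append(
                    (f"AT{j}: {round(dec.pw[j - 1]):d}% (below cutoff)", "gray")
                )
        ax_txt.axis("off")
        for i, (text, color) in enumerate(lines):
            ax_txt.text(0.02, 0.9 - 0.16 * i, text, color=color, fontsize=9,
                        transform=ax_txt.transAxes)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=spec.dpi, metadata={"Software": None})
    plt.close(fig)
    return path


def render_rss_curve(curve, path: str | Path, dpi: int = 100) -> Path:
    """k versus mean train/test RSS with per-fold spread."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ks = np.asarray(curve.ks)
    ax.plot(ks, curve.train_rss, "o-", label="train RSS (mean)")
    mean_t = curve.mean_test_rss
    sd_t = curve.sd_test_rss
    ax.errorbar(ks, mean_t, yerr=sd_t, fmt="s-", capsize=3, label="test RSS (CV)")
    if curve.chosen_k is not None:
        ax.axvline(curve.chosen_k, color="gray", ls="--", lw=1,
                   label=f"suggested k={curve.chosen_k}")
    ax.set_xlabel("number of archetypes k")
    ax.set_ylabel("RSS")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=dpi, metadata={"Software": None})
    plt.close(fig)
    return path
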