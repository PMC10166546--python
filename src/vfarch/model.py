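"""Frozen archetype models: the basis used for decomposition.

An :class:`ArchetypeModel` stores the archetype vectors together with their
relative weights (RW, mean percent weight over the training set, in descending
order), average TD per archetype, and fit provenance (seed, options, restart,
RSS, any condition-guard ridges, the left-eye mirroring flag).  Models
serialise to a documented JSON container so a decomposition can be run years
later against exactly the basis that was fitted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .grid import GRID, N_ACTIVE

FORMAT_VERSION = 1


@dataclass
class ArchetypeModel:
    archetypes: np.ndarray  # (k, 52), descending-RW order
    relative_weights: np.ndarray  # (k,), percent, sums to ~100
    average_td: np.ndarray  # (k,), dB
    mirrored: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.archetypes = np.atleast_2d(np.asarray(self.archetypes, dtype=float))
        self.relative_weights = np.asarray(self.relative_weights, dtype=float)
        self.average_td = np.asarray(self.average_td, dtype=float)
        if self.archetypes.shape[1] != N_ACTIVE:
            raise ValueError(
                f"archetypes must have {N_ACTIVE} values, got {self.archetypes.shape[1]}"
            )
        k = self.archetypes.shape[0]
        if self.relative_weights.shape != (k,) or self.average_td.shape != (k,):
            raise ValueError("relative_weights/average_td must have one entry per archetype")

    @property
    def k(self) -> int:
        return self.archetypes.shape[0]

    @property
    def normal_index(self) -> int:
        """0-based index of the normal archetype: highest average TD.

        In practice this is also the highest-RW archetype (index 0); if the
        two designations disagree a warning is raised.
        """
        idx = int(np.argmax(self.average_td))
        if idx != int(np.argmax(self.relative_weights)):
            warnings.warn(
                "highest-average-TD and highest-RW archetypes differ; using "
                "highest average TD as the normal pattern",
                RuntimeWarning,
            )
        return idx

    def labels(self) -> list[str]:
        return [f"AT{i + 1}" for i in range(self.k)]

    # ------------------------------------------------------------------
    @classmethod
    def from_estimator(cls, est, opts=None, mirrored: bool = False) -> "ArchetypeModel":
        meta = {
            "k": est.n_archetypes,
            "rss": est.rss_,
            "n_iter": est.n_iter_,
            "restart_index": est.restart_index_,
            "ridge_events": list(map(float, est.ridge_events_)),
            "seed": getattr(opts, "seed", None) if opts is not None else est.random_state
            if isinstance(est.random_state, int)
            else None,
            "options": asdict(opts) if opts is not None else est.get_params(),
        }
        return cls(
            archetypes=est.archetypes_,
            relative_weights=est.relative_weights_,
            average_td=est.average_td_,
            mirrored=mirrored,
            metadata=meta,
        )

    @classmethod
    def from_vectors(
        cls,
        archetypes: np.ndarray,
        relative_weights: np.ndarray | None = None,
        mirrored: bool = False,
        metadata: dict | None = None,
    ) -> "ArchetypeModel":
        """Build a model directly from archetype vectors (e.g. planted
        templates), with uniform RW when none is supplied."""
        Z = np.atleast_2d(np.asarray(archetypes, dtype=float))
        k = Z.shape[0]
        if relative_weights is None:
            relative_weights = np.full(k, 100.0 / k)
        return cls(
            archetypes=Z,
            relative_weights=np.asarray(relative_weights, dtype=float),
            average_td=Z.mean(axis=1),
            mirrored=mirrored,
            metadata=metadata or {},
        )

    # ------------------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "vfarch-archetype-model",
            "version": FORMAT_VERSION,
            "grid": {
                "n_points": len(GRID.points),
                "blind_spot_indices": sorted(GRID.blind_spot_indices),
                "active_indices": list(GRID.active_indices),
            },
            "mirrored": self.mirrored,
            "k": self.k,
            "archetypes": self.archetypes.tolist(),
            "relative_weights": self.relative_weights.tolist(),
            "average_td": self.average_td.tolist(),
            "metadata": self.metadata,
        }
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "ArchetypeModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "vfarch-archetype-model":
            raise ValueError(f"{path} is not an archetype-model file")
        return cls(
            archetypes=np.array(payload["archetypes"], dtype=float),
            relative_weights=np.array(payload["relative_weights"], dtype=float),
            average_td=np.array(payload["average_td"], dtype=float),
            mirrored=bool(payload.get("mirrored", False)),
            metadata=payload.get("metadata", {}),
        )
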