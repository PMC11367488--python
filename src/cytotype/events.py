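"""Per-event intensity container shared by every pipeline stage.

An :class:`EventTable` holds the marker-intensity matrix for one or more
cytometry samples together with per-event metadata (sample of origin,
cluster labels, cell-type annotations) and per-sample metadata (line,
batch, acquisition day).  The ``space_tag`` records which intensity space
the values live in and may only move forward along
``raw -> transformed -> aligned -> retro``; the harmonization operations
enforce the transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SPACE_ORDER = ("raw", "transformed", "aligned", "retro")


class SpaceTagError(ValueError):
    """Raised when an operation is applied to data in the wrong space."""


@dataclass
class EventTable:
    """Marker intensities for a merged set of cytometry samples.

    Parameters
    ----------
    intensities
        ``(n_events, n_markers)`` float array of fluorescence area values.
    markers
        Marker names, one per column; unique.
    sample_id
        Per-event sample identifier, length ``n_events``.
    sample_meta
        Per-sample attributes indexed by sample id (line, batch, ...).
        May be empty; missing samples are added with no attributes.
    space_tag
        One of ``raw``, ``transformed``, ``aligned``, ``retro``.
    obs
        Optional per-event annotations (cluster, cell-type labels...).
    scatter
        Optional ``(n_events, n_scatter)`` scatter-channel values, kept
        for completeness but excluded from all downstream mathematics.
    """

    intensities: np.ndarray
    markers: list[str]
    sample_id: np.ndarray
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    space_tag: str = "raw"
    obs: pd.DataFrame | None = None
    scatter: np.ndarray | None = None
    scatter_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        self.markers = list(self.markers)
        self.sample_id = np.asarray(self.sample_id)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        n, m = self.intensities.shape
        if len(self.markers) != m:
            raise ValueError(
                f"{len(self.markers)} marker names for {m} intensity columns"
            )
        if len(set(self.markers)) != m:
            raise ValueError("marker names must be unique")
        if self.sample_id.shape[0] != n:
            raise ValueError("sample_id length does not match event count")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        if self.space_tag not in SPACE_ORDER:
            raise ValueError(f"unknown space_tag {self.space_tag!r}")
        present = pd.unique(self.sample_id)
        if self.sample_meta is None or self.sample_meta.empty:
            self.sample_meta = pd.DataFrame(index=pd.Index(present, name="sample_id"))
        else:
            missing = [s for s in present if s not in self.sample_meta.index]
            if missing:
                extra = pd.DataFrame(index=pd.Index(missing, name="sample_id"))
                self.sample_meta = pd.concat([self.sample_meta, extra])
        if self.obs is not None and len(self.obs) != n:
            raise ValueError("obs length does not match event count")

    # ------------------------------------------------------------------
    @property
    def n_events(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_markers(self) -> int:
        return self.intensities.shape[1]

    @property
    def samples(self) -> list:
        """Sample ids in first-appearance order."""
        return list(pd.unique(self.sample_id))

    def marker_index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in table") from None

    def column(self, marker: str) -> np.ndarray:
        return self.intensities[:, self.marker_index(marker)]

    def sample_mask(self, sample: object) -> np.ndarray:
        return np.asarray(self.sample_id == sample)

    # ------------------------------------------------------------------
    def copy(self, **overrides) -> "EventTable":
        kwargs = dict(
            intensities=self.intensities.copy(),
            markers=list(self.markers),
            sample_id=self.sample_id.copy(),
            sample_meta=self.sample_meta.copy(),
            space_tag=self.space_tag,
            obs=None if self.obs is None else self.obs.copy(),
            scatter=None if self.scatter is None else self.scatter.copy(),
            scatter_names=list(self.scatter_names),
        )
        kwargs.update(overrides)
        return EventTable(**kwargs)

    def select(self, mask: np.ndarray) -> "EventTable":
        """Row subset preserving order; mask is boolean or integer index."""
        mask = np.asarray(mask)
        return self.copy(
            intensities=self.intensities[mask],
            sample_id=self.sample_id[mask],
            obs=None if self.obs is None else self.obs.iloc[mask].reset_index(drop=True),
            scatter=None if self.scatter is None else self.scatter[mask],
        )

    def with_obs(self, name: str, values: Iterable) -> "EventTable":
        out = self.copy()
        if out.obs is None:
            out.obs = pd.DataFrame(index=pd.RangeIndex(self.n_events))
        out.obs[name] = np.asarray(list(values) if not isinstance(values, np.ndarray) else values)
        return out

    def advance_space(self, new_tag: str) -> None:
        """Move the space tag forward; backwards transitions are errors."""
        if SPACE_ORDER.index(new_tag) <= SPACE_ORDER.index(self.space_tag):
            raise SpaceTagError(
                f"cannot move from space {self.space_tag!r} to {new_tag!r}"
            )
        self.space_tag = new_tag

    def require_space(self, *tags: str) -> None:
        if self.space_tag not in tags:
            raise SpaceTagError(
                f"operation requires space {' or '.join(tags)}, data is "
                f"{self.space_tag!r}"
            )

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Tabular view: sample_id column, one column per marker, obs columns."""
        df = pd.DataFrame(self.intensities, columns=self.markers)
        df.insert(0, "sample_id", self.sample_id)
        if self.obs is not None:
            for col in self.obs.columns:
                df[col] = self.obs[col].to_numpy()
        return df

    @classmethod
    def concat(cls, tables: Sequence["EventTable"]) -> "EventTable":
        """Stack tables sharing the same marker set (order of first table)."""
        if not tables:
            raise ValueError("no tables to concatenate")
        first = tables[0]
        for t in tables[1:]:
            if set(t.markers) != set(first.markers):
                missing = sorted(set(first.markers) ^ set(t.markers))
                raise ValueError(
                    "tables have asymmetric marker sets; differing channels: "
                    + ", ".join(missing)
                )
            if t.space_tag != first.space_tag:
                raise SpaceTagError("cannot concatenate tables from different spaces")
        order = [ [t.markers.index(m) for m in first.markers] for t in tables ]
        X = np.vstack([t.intensities[:, idx] for t, idx in zip(tables, order)])
        sid = np.concatenate([t.sample_id for t in tables])
        meta = pd.concat([t.sample_meta for t in tables])
        meta = meta[~meta.index.duplicated(keep="first")]
        obs = None
        if all(t.obs is not None for t in tables):
            obs = pd.concat([t.obs for t in tables], ignore_index=True)
        scatter = None
        scatter_names: list[str] = []
        if all(
            t.scatter is not None and t.scatter_names == first.scatter_names
            for t in tables
        ):
            scatter = np.vstack([t.scatter for t in tables])
            scatter_names = list(first.scatter_names)
        return cls(
            intensities=X,
            markers=list(first.markers),
            sample_id=sid,
            sample_meta=meta,
            space_tag=first.space_tag,
            obs=obs,
            scatter=scatter,
            scatter_names=scatter_names,
        )


def make_sample_meta(records: Mapping[str, Mapping[str, object]]) -> pd.DataFrame:
    """Build a sample_meta frame from ``{sample_id: {attr: value}}``."""
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "sample_id"
    return df
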