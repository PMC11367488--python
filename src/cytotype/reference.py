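"""Building the cell type x marker expected-expression reference matrix.

The correlation-based annotation needs, for every candidate cell type, a
profile of relative expression over the antibody panel.  Profiles are
fused from heterogeneous sources -- mean transcript levels from brain and
organoid single-cell datasets (via gene surrogates for the antibodies) and
mean fluorescence from sorted or cultured populations.  Each source is
z-scored per marker across cell types and min-max scaled to [0, 1]; brain
RNA sources are averaged, organoid RNA sources are averaged, the two RNA
summaries are averaged and re-normalized, and finally averaged 1:1 with
the normalized fluorescence table where fluorescence rows exist (cell
types absent from fluorescence sources keep their RNA-only profile).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SourceTable",
    "ReferenceMatrix",
    "normalize_source",
    "build_reference",
    "load_reference",
    "panel_reference",
    "load_marker_gene_map",
]

SOURCE_CLASSES = ("rna_brain", "rna_organoid", "fc")


@dataclass
class SourceTable:
    """One mean-expression table: cell types (rows) x markers (columns)."""

    values: pd.DataFrame
    source_class: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.source_class not in SOURCE_CLASSES:
            raise ValueError(
                f"source_class must be one of {SOURCE_CLASSES}, got {self.source_class!r}"
            )
        self.values = self.values.astype(float)
        if (self.values.to_numpy() < 0).any():
            raise ValueError(f"source {self.name!r} contains negative values")


@dataclass
class ReferenceMatrix:
    """Cell type x marker matrix of expected relative expression in [0, 1]."""

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        v = self.values.to_numpy()
        finite = v[np.isfinite(v)]
        if ((finite < -1e-9) | (finite > 1 + 1e-9)).any():
            raise ValueError("reference values must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.index)

    @property
    def markers(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="cell_type")


def normalize_source(values: pd.DataFrame, order: str = "z_then_minmax") -> pd.DataFrame:
    """Per-marker z-score across cell types followed by min-max to [0, 1].

    ``order='minmax_then_z'`` flips the two steps (the final user-facing
    scale is then restored by a trailing min-max); NaNs are ignored.
    """
    def zscore(df: pd.DataFrame) -> pd.DataFrame:
        sd = df.std(axis=0, ddof=0).replace(0.0, 1.0)
        return (df - df.mean(axis=0)) / sd

    def minmax(df: pd.DataFrame) -> pd.DataFrame:
        lo, hi = df.min(axis=0), df.max(axis=0)
        span = (hi - lo).replace(0.0, 1.0)
        return (df - lo) / span

    if order == "z_then_minmax":
        return minmax(zscore(values))
    if order == "minmax_then_z":
        return minmax(zscore(minmax(values)))
    raise ValueError(f"unknown normalization order {order!r}")


def _mean_of(tables: list[pd.DataFrame], index, columns) -> pd.DataFrame | None:
    if not tables:
        return None
    aligned = [t.reindex(index=index, columns=columns) for t in tables]
    return pd.concat(aligned).groupby(level=0).mean().reindex(index)


def build_reference(
    sources: Sequence[SourceTable],
    markers: Iterable[str] | None = None,
    order: str = "z_then_minmax",
) -> ReferenceMatrix:
    """Fuse normalized sources into one [0, 1] reference matrix.

    RNA brain and RNA organoid sources are each averaged, their mean is
    re-normalized, and combined 1:1 with the averaged fluorescence table
    for cell types that have fluorescence data; other cell types keep the
    RNA-only profile.  A marker requested via ``markers`` but absent from
    every source is an error.
    """
    if not sources:
        raise ValueError("at least one source table is required")
    all_types = list(dict.fromkeys(t for s in sources for t in s.values.index))
    all_markers = list(dict.fromkeys(m for s in sources for m in s.values.columns))
    if markers is not None:
        missing = [m for m in markers if m not in all_markers]
        if missing:
            raise ValueError(
                "markers absent from every source: " + ", ".join(missing)
            )
        all_markers = list(markers)

    norm = {
        cls: [
            normalize_source(s.values.reindex(columns=[c for c in all_markers if c in s.values.columns]), order)
            for s in sources
            if s.source_class == cls
        ]
        for cls in SOURCE_CLASSES
    }
    brain = _mean_of(norm["rna_brain"], all_types, all_markers)
    organoid = _mean_of(norm["rna_organoid"], all_types, all_markers)
    fc = _mean_of(norm["fc"], all_types, all_markers)

    rna_parts = [t for t in (brain, organoid) if t is not None]
    if rna_parts:
        rna = normalize_source(
            pd.concat(rna_parts).groupby(level=0).mean().reindex(all_types), order
        )
    else:
        rna = None

    if rna is not None and fc is not None:
        final = pd.concat([rna, fc]).groupby(level=0).mean().reindex(all_types)
        # cell types with no fluorescence data keep the RNA-only profile
        fc_missing = fc.isna().all(axis=1)
        final.loc[fc_missing] = rna.loc[fc_missing]
    else:
        final = rna if rna is not None else fc

    empty = final.isna().all(axis=1)
    if empty.any():
        raise ValueError(
            "cell types with no data in any source: "
            + ", ".join(final.index[empty])
        )
    dead = final.isna().all(axis=0)
    if dead.any():
        raise ValueError(
            "markers absent from every source: " + ", ".join(final.columns[dead])
        )
    # final rescale to [0, 1] per marker
    lo, hi = final.min(axis=0), final.max(axis=0)
    span = (hi - lo).replace(0.0, 1.0)
    final = (final - lo) / span

    provenance = {
        t: sorted(
            {s.source_class for s in sources if t in s.values.index}
        )
        for t in all_types
    }
    return ReferenceMatrix(final, provenance=provenance)


def load_reference(path: str | Path) -> ReferenceMatrix:
    """Load a final-scaled reference CSV (rows = cell types, cols = markers)."""
    df = pd.read_csv(path, index_col=0)
    v = df.to_numpy(dtype=float)
    bad = v[np.isfinite(v) & ((v < 0) | (v > 1))]
    if bad.size:
        raise ValueError(
            f"{path}: reference values outside [0, 1] (e.g. {bad.flat[0]}); "
            "prebuilt references must be final-scaled"
        )
    return ReferenceMatrix(df)


# ----------------------------------------------------------------------
# packaged panel fixture
# ----------------------------------------------------------------------

#: the 13-antibody neural panel and the 9 cell types it was designed for
PANEL_MARKERS = [
    "CD24", "CD56", "CD29", "CD15", "CD184", "CD133", "CD71",
    "CD44", "GLAST", "AQP4", "HepaCAM", "CD140a", "O4",
]
PANEL_CELL_TYPES = [
    "Astrocytes", "Endothelial", "Epithelial", "Neurons", "NPC",
    "Oligodendrocytes", "OPC", "RadialGlia", "StemCell",
]


def panel_reference(seed: int = 20230913) -> ReferenceMatrix:
    """Synthetic stand-in reference with the panel's 9 x 13 layout.

    The layout (cell types and markers) matches the neural antibody panel;
    the values are regenerated deterministically from synthetic toy
    sources via :func:`build_reference` -- they are NOT measured data.
    Users analysing real experiments must supply their own reference.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.0, 10.0, size=(len(PANEL_CELL_TYPES), len(PANEL_MARKERS)))

    def jitter(scale: float) -> pd.DataFrame:
        noisy = np.clip(base + rng.normal(0, scale, base.shape), 0, None)
        return pd.DataFrame(noisy, index=PANEL_CELL_TYPES, columns=PANEL_MARKERS)

    sources = [
        SourceTable(jitter(0.5), "rna_brain", "synthetic brain RNA"),
        SourceTable(jitter(0.5), "rna_organoid", "synthetic organoid RNA"),
        # fluorescence covers a subset of cell types, as in real panels
        SourceTable(jitter(0.8).drop(index=["Endothelial", "Epithelial", "RadialGlia"]),
                    "fc", "synthetic fluorescence"),
    ]
    return build_reference(sources)


def load_marker_gene_map() -> pd.DataFrame:
    """Marker -> gene surrogate mapping shipped with the package.

    Glycoprotein epitopes without a coding gene use correlated surrogates
    (O4 -> NKX6-2, SSEA-4 -> its synthase gene ST3GAL2).
    """
    with importlib.resources.files("cytotype.data").joinpath(
        "marker_gene_map.csv"
    ).open() as fh:
        return pd.read_csv(fh)
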