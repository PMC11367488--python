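"""Synthetic antibody-panel cytometry data with known ground truth.

The generator emulates the data model the pipeline assumes: each cell
belongs to a planted type; its transformed (asinh-scale) intensity on
marker ``m`` is ``mu0 + span * ref[type, m]`` plus a per-sample batch
offset and Gaussian noise; the raw intensity is ``sinh`` of that, so the
default biexponential transform exactly inverts generation.  Additive
Gaussian noise in asinh space corresponds to multiplicative-like noise on
the raw scale, matching the character of fluorescence measurements.
Doublets and debris are not simulated: the pipeline consumes pre-gated
live single cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .events import EventTable
from .reference import ReferenceMatrix

__all__ = ["SimSpec", "simulate", "write_fcs_fixture", "dominant_marker_reference"]

#: defaults for mapping reference values in [0,1] into asinh-intensity space
DEFAULT_MU0 = 1.0
DEFAULT_SPAN = 3.0
#: default within-type spread on the asinh scale, a realistic stain width
DEFAULT_NOISE_SD = 0.35


@dataclass
class SimSpec:
    """Full description of one simulated experiment.

    Parameters
    ----------
    reference
        Cell type x marker expected expression in [0, 1].
    proportions
        Per sample, cell-type proportion vector (sums to 1) in the order
        of ``reference.cell_types``.
    n_cells
        Per sample event count.
    batch_shift
        Optional per-sample additive offsets in transformed space, either
        a scalar per sample (applied to every marker) or a vector per
        marker.  Default: no shift.
    noise_sd
        Within-type Gaussian SD on the asinh scale.
    intensity_scale
        ``(mu0, span)`` mapping reference values into asinh space.
    """

    reference: ReferenceMatrix
    proportions: Mapping[object, Sequence[float]]
    n_cells: Mapping[object, int]
    batch_shift: Mapping[object, object] | None = None
    noise_sd: float = DEFAULT_NOISE_SD
    intensity_scale: tuple[float, float] = (DEFAULT_MU0, DEFAULT_SPAN)
    seed: int = 0
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for s, p in self.proportions.items():
            p = np.asarray(p, dtype=float)
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"proportions for sample {s!r} sum to {p.sum()}, not 1")
            if len(p) != len(self.reference.cell_types):
                raise ValueError(f"proportions for sample {s!r} have wrong length")
        for s, n in self.n_cells.items():
            if n < 1:
                raise ValueError(f"n_cells for sample {s!r} must be >= 1")
        if set(self.proportions) != set(self.n_cells):
            raise ValueError("proportions and n_cells must cover the same samples")

    @classmethod
    def single_sample(
        cls,
        reference: ReferenceMatrix,
        proportions: Sequence[float],
        n_cells: int,
        **kw,
    ) -> "SimSpec":
        return cls(
            reference=reference,
            proportions={"sample1": proportions},
            n_cells={"sample1": n_cells},
            **kw,
        )


def simulate(spec: SimSpec) -> EventTable:
    """Draw one experiment; truth labels land in ``obs['true_label']``.

    Raw intensities are ``sinh`` of the generated asinh-space values and
    the result is tagged ``raw``; bit-reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mu0, span = spec.intensity_scale
    ref = spec.reference.values  # DataFrame types x markers
    types = list(spec.reference.cell_types)
    markers = list(spec.reference.markers)
    profile = mu0 + span * ref.to_numpy()  # (T, M) asinh-space means

    blocks, sids, labels = [], [], []
    for s in sorted(spec.proportions, key=str):
        n = spec.n_cells[s]
        p = np.asarray(spec.proportions[s], dtype=float)
        t_idx = rng.choice(len(types), size=n, p=p)
        y = profile[t_idx] + rng.normal(0.0, spec.noise_sd, size=(n, len(markers)))
        shift = 0.0
        if spec.batch_shift and s in spec.batch_shift:
            shift = np.asarray(spec.batch_shift[s], dtype=float)
        y = y + shift
        blocks.append(np.sinh(y))
        sids.append(np.repeat(s, n))
        labels.extend(types[i] for i in t_idx)

    table = EventTable(
        intensities=np.vstack(blocks),
        markers=markers,
        sample_id=np.concatenate(sids),
        sample_meta=spec.sample_meta if spec.sample_meta is not None else pd.DataFrame(),
        space_tag="raw",
        obs=pd.DataFrame({"true_label": labels}),
    )
    return table


def write_fcs_fixture(spec: SimSpec, folder: str | Path) -> list[Path]:
    """Write one minimal FCS 3.1 file per simulated sample plus truth CSV."""
    from .fcs_io import write_fcs

    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    table = simulate(spec)
    written = []
    for s in table.samples:
        mask = table.sample_mask(s)
        path = folder / f"{s}.fcs"
        write_fcs(
            path,
            table.intensities[mask],
            channel_names=[f"{m}-A" for m in table.markers],
            stain_names=[f"{m}-A" for m in table.markers],
        )
        written.append(path)
    truth = pd.DataFrame(
        {"sample_id": table.sample_id, "true_label": table.obs["true_label"]}
    )
    truth.to_csv(folder / "truth_labels.csv", index=False)
    return written


def dominant_marker_reference(
    n_types: int = 4,
    n_markers: int | None = None,
    high: float = 1.0,
    low: float = 0.0,
) -> ReferenceMatrix:
    """Reference where type ``i`` is high on marker ``i`` only.

    The standard planted design for gating and classification checks: each
    population carries exactly one positive marker, so an axis-aligned
    gate can in principle isolate it.
    """
    n_markers = n_markers or n_types
    if n_markers < n_types:
        raise ValueError("need at least one marker per type")
    vals = np.full((n_types, n_markers), low, dtype=float)
    for i in range(n_types):
        vals[i, i] = high
    types = [f"type{i + 1}" for i in range(n_types)]
    markers = [f"M{i + 1}" for i in range(n_markers)]
    return ReferenceMatrix(pd.DataFrame(vals, index=types, columns=markers))
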