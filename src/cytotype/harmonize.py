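"""Batch harmonization: biexponential transform, landmark alignment, retro.

Fluorescence area values from different acquisition days drift: the same
cell population peaks at different intensities in different samples.  The
harmonization step (1) maps raw intensities through the inverse of a
biexponential curve ``B(y) = a*exp(b*(y-w)) - c*exp(-d*(y-w)) + f`` (at the
default coefficients ``a=c=0.5, b=d=1, f=w=0`` this is exactly ``asinh``),
(2) detects density peaks ("landmarks") per sample and channel, shifts each
landmark onto the cross-sample consensus position ("benchmark", the median
of the matched landmark positions), and (3) applies the forward curve again
("retro" transform) so that visualizations live on the familiar intensity
scale.  Alignment is skippable when batch correction is not wanted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .events import EventTable

log = logging.getLogger(__name__)

__all__ = [
    "BiexpParams",
    "LandmarkSpec",
    "AlignmentReport",
    "biexp_transform",
    "retro_transform",
    "detect_landmarks",
    "align",
    "harmonize",
]


# ----------------------------------------------------------------------
# biexponential curve
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class BiexpParams:
    """Coefficients of the forward biexponential curve.

    ``B(y) = a*exp(b*(y-w)) - c*exp(-d*(y-w)) + f`` with ``a,c,b,d > 0``,
    which makes B strictly increasing and therefore invertible.  The
    defaults reduce B to ``sinh`` so the inverse is ``asinh``.
    """

    a: float = 0.5
    b: float = 1.0
    c: float = 0.5
    d: float = 1.0
    f: float = 0.0
    w: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.c <= 0 or self.b <= 0 or self.d <= 0:
            raise ValueError("biexponential requires a, b, c, d > 0 (invertibility)")

    def forward(self, y: np.ndarray) -> np.ndarray:
        """B(y), clipping the exponent arguments at |700| to avoid overflow."""
        y = np.asarray(y, dtype=float)
        up = self.b * (y - self.w)
        dn = -self.d * (y - self.w)
        if np.any(np.abs(up) > 700) or np.any(np.abs(dn) > 700):
            warnings.warn("biexponential overflow; exponent clipped at |700|")
            up = np.clip(up, -700, 700)
            dn = np.clip(dn, -700, 700)
        return self.a * np.exp(up) - self.c * np.exp(dn) + self.f

    def inverse(self, x: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Monotone root finding for y with B(y)=x.

        Vectorized bisection bracketed by [-50, 50] down to ``tol``,
        followed by Newton polish steps.
        """
        x = np.asarray(x, dtype=float)
        lo = np.full(x.shape, -50.0)
        hi = np.full(x.shape, 50.0)
        # ~60 halvings bring the 100-wide bracket below 1e-16
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            below = self.forward(mid) < x
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
            if np.max(hi - lo) < tol * 1e-3:
                break
        y = 0.5 * (lo + hi)
        for _ in range(2):  # Newton polish
            fy = self.forward(y) - x
            dfy = (
                self.a * self.b * np.exp(np.clip(self.b * (y - self.w), -700, 700))
                + self.c * self.d * np.exp(np.clip(-self.d * (y - self.w), -700, 700))
            )
            y = y - fy / dfy
        return y


def biexp_transform(events: EventTable, params: BiexpParams | None = None) -> EventTable:
    """Inverse-biexponential transform of every marker column (raw -> transformed)."""
    params = params or BiexpParams()
    events.require_space("raw")
    out = events.copy(intensities=params.inverse(events.intensities))
    out.space_tag = "transformed"
    return out


def retro_transform(events: EventTable, params: BiexpParams | None = None) -> EventTable:
    """Forward biexponential transform back to the intensity scale.

    Accepts aligned data (the normal pipeline) or transformed data (when
    alignment was skipped); tags the result ``retro``.
    """
    params = params or BiexpParams()
    events.require_space("aligned", "transformed")
    out = events.copy(intensities=params.forward(events.intensities))
    out.space_tag = "retro"
    return out


# ----------------------------------------------------------------------
# landmark detection
# ----------------------------------------------------------------------

@dataclass
class LandmarkSpec:
    """Which channels to align and how many density peaks to expect.

    ``peaks_per_channel`` maps a marker to its expected peak count (1 for
    unimodal channels, 2 for bimodal negative/positive staining); only the
    listed channels are aligned.  ``density_floor`` is the minimum
    normalized KDE height for a local maximum to count as a peak and
    ``merge_gap`` the minimum separation of two peaks as a fraction of the
    channel range (both default 0.05).
    """

    peaks_per_channel: Mapping[str, int]
    density_floor: float = 0.05
    merge_gap: float = 0.05
    grid_size: int = 512

    def __post_init__(self) -> None:
        if not 0 < self.density_floor < 1:
            raise ValueError("density_floor must be in (0, 1)")
        if not 0 < self.merge_gap < 1:
            raise ValueError("merge_gap must be in (0, 1)")
        for m, k in self.peaks_per_channel.items():
            if k not in (1, 2):
                raise ValueError(f"peaks_per_channel[{m!r}] must be 1 or 2")

    @classmethod
    def uniform(cls, markers, peaks: int = 1, **kw) -> "LandmarkSpec":
        return cls({m: peaks for m in markers}, **kw)


@dataclass
class AlignmentReport:
    """Detected landmarks, their benchmarks and the implied shifts.

    ``records`` has one row per sample x channel x landmark with columns
    ``sample, channel, peak, position, confidence, benchmark, shift``;
    ``benchmarks`` maps channel -> ascending benchmark positions;
    ``channel_range`` maps channel -> (lo, hi) in transformed space.
    """

    records: pd.DataFrame
    benchmarks: dict[str, np.ndarray]
    channel_range: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _find_channel_peaks(
    values: np.ndarray, spec: LandmarkSpec, lo: float, hi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Return (positions, raw confidence scores) of candidate KDE peaks."""
    if hi <= lo or len(values) < 5 or np.std(values) == 0:
        return np.array([]), np.array([])
    grid = np.linspace(lo, hi, spec.grid_size)
    dens = gaussian_kde(values)(grid)  # Silverman bandwidth
    dens = dens / dens.max()
    idx, _ = find_peaks(dens, height=spec.density_floor)
    if idx.size == 0:
        return np.array([]), np.array([])
    pos = grid[idx]
    height = dens[idx]
    # merge peaks closer than merge_gap * range, keeping the higher one
    min_sep = spec.merge_gap * (hi - lo)
    keep: list[int] = []
    for j in np.argsort(-height):
        if all(abs(pos[j] - pos[k]) >= min_sep for k in keep):
            keep.append(j)
    keep = sorted(keep, key=lambda j: pos[j])
    pos, height, idx = pos[keep], height[keep], idx[keep]
    # confidence = height * |curvature| at the maximum (sharpness)
    d2 = np.gradient(np.gradient(dens, grid), grid)
    conf = height * np.abs(d2[idx])
    return pos, conf


def detect_landmarks(events: EventTable, spec: LandmarkSpec) -> AlignmentReport:
    """Detect per-sample density peaks and cross-sample benchmarks.

    Per sample and channel, a Gaussian-kernel density estimate is scanned
    for local maxima above ``density_floor``; nearby maxima are merged; the
    ``peaks_per_channel`` highest-confidence peaks become the sample's
    landmarks (sorted ascending).  The benchmark for landmark ``k`` is the
    median of landmark ``k`` across samples.
    """
    events.require_space("transformed")
    rows = []
    benchmarks: dict[str, np.ndarray] = {}
    ranges: dict[str, tuple[float, float]] = {}
    for channel, n_peaks in spec.peaks_per_channel.items():
        col = events.column(channel)
        lo, hi = float(col.min()), float(col.max())
        ranges[channel] = (lo, hi)
        per_sample: dict[object, np.ndarray] = {}
        confs: dict[object, np.ndarray] = {}
        for s in events.samples:
            vals = col[events.sample_mask(s)]
            pos, conf = _find_channel_peaks(vals, spec, lo, hi)
            if pos.size == 0:
                warnings.warn(
                    f"no density peak found for sample {s!r} channel {channel!r}; "
                    "sample left unshifted on this channel"
                )
                per_sample[s] = np.array([])
                confs[s] = np.array([])
                continue
            if pos.size > n_peaks:
                top = np.sort(np.argsort(-conf)[:n_peaks])
                pos, conf = pos[top], conf[top]
            order = np.argsort(pos)
            per_sample[s] = pos[order]
            confs[s] = conf[order]
        # benchmarks: median of the k-th landmark across samples that have it
        bench = []
        for k in range(n_peaks):
            kth = [p[k] for p in per_sample.values() if len(p) > k]
            if kth:
                bench.append(float(np.median(kth)))
        bench_arr = np.array(bench)
        benchmarks[channel] = bench_arr
        # normalize confidence per channel for the report
        all_conf = np.concatenate([c for c in confs.values() if c.size]) if any(
            c.size for c in confs.values()
        ) else np.array([])
        cmin = all_conf.min() if all_conf.size else 0.0
        cspan = (all_conf.max() - cmin) if all_conf.size else 1.0
        for s in events.samples:
            pos, conf = per_sample[s], confs[s]
            matched = _match_landmarks(pos, bench_arr)
            for k, (p, c) in enumerate(zip(pos, conf)):
                m = matched[k]
                rows.append(
                    dict(
                        sample=s,
                        channel=channel,
                        peak=k,
                        position=p,
                        confidence=(c - cmin) / cspan if cspan > 0 else 1.0,
                        benchmark=bench_arr[m] if m is not None else np.nan,
                        shift=(bench_arr[m] - p) if m is not None else 0.0,
                    )
                )
    records = pd.DataFrame(
        rows,
        columns=["sample", "channel", "peak", "position", "confidence", "benchmark", "shift"],
    )
    return AlignmentReport(records=records, benchmarks=benchmarks, channel_range=ranges)


def _match_landmarks(pos: np.ndarray, bench: np.ndarray) -> list[int | None]:
    """Greedy 1:1 matching of sample landmarks to nearest benchmarks."""
    matched: list[int | None] = [None] * len(pos)
    if bench.size == 0:
        return matched
    taken: set[int] = set()
    pairs = sorted(
        ((abs(p - b), i, j) for i, p in enumerate(pos) for j, b in enumerate(bench)),
        key=lambda t: t[0],
    )
    done: set[int] = set()
    for _, i, j in pairs:
        if i in done or j in taken:
            continue
        matched[i] = j
        done.add(i)
        taken.add(j)
    return matched


# ----------------------------------------------------------------------
# warping
# ----------------------------------------------------------------------

def align(events: EventTable, report: AlignmentReport) -> EventTable:
    """Shift each sample's landmarks onto the benchmarks (transformed -> aligned).

    Values are warped with a sum of Gaussian kernels centred on the
    landmarks, ``x -> x + sum_k a_k * exp(-(x - l_k)^2 / (2 sigma_k^2))``,
    where sigma_k is half the distance to the nearest other landmark of the
    sample (or a quarter of the channel range for single-landmark channels)
    and the coefficients ``a_k`` solve a small linear system so that each
    landmark lands exactly on its benchmark even when kernels overlap.  As
    long as sigma_k stays below half the landmark gap the warp is order
    preserving.
    """
    events.require_space("transformed")
    missing = set(report.records["sample"].unique()) - set(events.samples)
    if missing:
        raise ValueError(f"alignment report refers to unknown samples: {sorted(missing)}")
    out = events.copy()
    X = out.intensities
    for channel, grp in report.records.groupby("channel", sort=False):
        j = events.marker_index(channel)
        lo, hi = report.channel_range.get(channel, (X[:, j].min(), X[:, j].max()))
        default_sigma = 0.25 * (hi - lo) if hi > lo else 1.0
        for s, sub in grp.groupby("sample", sort=False):
            sub = sub.dropna(subset=["benchmark"])
            if sub.empty:
                continue
            landmarks = sub["position"].to_numpy()
            shifts = sub["shift"].to_numpy()
            if len(landmarks) > 1:
                gaps = np.array(
                    [
                        np.min(np.abs(np.delete(landmarks, i) - l))
                        for i, l in enumerate(landmarks)
                    ]
                )
                sigmas = gaps / 2.0
            else:
                sigmas = np.array([default_sigma])
            # solve for kernel coefficients so each landmark lands exactly
            # on its benchmark despite overlapping kernels
            K = np.exp(
                -((landmarks[:, None] - landmarks[None, :]) ** 2)
                / (2.0 * sigmas[None, :] ** 2)
            )
            coef = np.linalg.solve(K, shifts)
            mask = events.sample_mask(s)
            x = X[mask, j]
            warp = np.zeros_like(x)
            for l, a, sg in zip(landmarks, coef, sigmas):
                warp += a * np.exp(-((x - l) ** 2) / (2.0 * sg**2))
            X[mask, j] = x + warp
    out.space_tag = "aligned"
    return out


def harmonize(
    events: EventTable,
    spec: LandmarkSpec,
    params: BiexpParams | None = None,
    do_align: bool = True,
    do_retro: bool = True,
) -> tuple[EventTable, AlignmentReport | None]:
    """Transform, optionally align, optionally retro-transform.

    Returns the processed table plus the alignment report (``None`` when
    alignment was skipped).
    """
    params = params or BiexpParams()
    out = biexp_transform(events, params)
    report = None
    if do_align:
        report = detect_landmarks(out, spec)
        out = align(out, report)
    if do_retro:
        out = retro_transform(out, params)
    return out, report
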