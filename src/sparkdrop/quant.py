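"""Image-analysis core: background subtraction, segmentation, gating, droplet
detection, and the three SPARK statistics with both normalization modes.

The three per-cell statistics compared here are

1. ``intensity_ratio`` — sum of droplet-pixel intensity over total cell
   intensity on the raw frame;
2. ``sd`` — standard deviation of the raw intensities within the cell mask;
3. ``area`` — total area of all fluorescent droplets detected on the
   rolling-ball background-subtracted frame.

Raw frames feed strategies 1-2; background-subtracted frames feed droplet
detection and strategy 3.  The area statistic starts from a true zero
baseline, which is what gives it the lowest resting signal and the highest
stimulation contrast of the three.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .population import StimulationProtocol
from .render import ImageStack

__all__ = [
    "QuantParams",
    "CellMask",
    "Droplet",
    "DropletSet",
    "SparkTrace",
    "disk_footprint",
    "rolling_ball_subtract",
    "segment_cells",
    "gate_expression",
    "detect_droplets",
    "bright_pixel_mask",
    "spark_stat_intensity_ratio",
    "spark_stat_sd",
    "spark_stat_area",
    "build_trace",
    "normalize_trace",
    "contrast_score",
]

STATISTICS = ("intensity_ratio", "sd", "area")


@dataclass(frozen=True)
class QuantParams:
    """Tunable image-analysis parameters.

    ``rolling_ball_radius`` must exceed the punctum footprint and fit inside
    the cell disks (smaller than the cell radius), so that the opening
    assigns the cell body to background and keeps only the puncta.
    ``expression_threshold`` gates cells on their background-corrected
    baseline brightness B_c (counts above the frame background, ``fixed``
    mode) or on a percentile of the B_c distribution; the default equals the
    default detection floor of the synthetic optics — the brightness below
    which droplet puncta sink into the read noise.
    The droplet intensity cutoff is ``droplet_k`` times the median absolute
    deviation of the cell's background-subtracted pixels (per-cell adaptive);
    8-connected components of at least ``min_droplet_area`` pixels count as
    droplets.
    """

    rolling_ball_radius: int = 10
    expression_threshold: float = 65.0
    threshold_mode: str = "fixed"  # or "percentile"
    droplet_k: float = 6.0
    min_droplet_area: int = 4
    k_seg: float = 6.0
    min_cell_area: int = 50
    ratio_k: float = 3.0  # bright-pixel cutoff (MADs) for the intensity-ratio statistic
    psf_sigma: float = 1.1

    def __post_init__(self):
        if self.rolling_ball_radius < 2 * self.psf_sigma:
            raise ValueError("rolling_ball_radius must be >= 2 x psf_sigma")
        if self.droplet_k <= 0:
            raise ValueError("droplet_k must be > 0")
        if self.threshold_mode not in ("fixed", "percentile"):
            raise ValueError("threshold_mode must be 'fixed' or 'percentile'")
        if self.threshold_mode == "percentile" and not 0 < self.expression_threshold < 100:
            raise ValueError("percentile threshold must be in (0, 100)")
        if self.min_droplet_area < 1 or self.min_cell_area < 1:
            raise ValueError("minimum areas must be >= 1")


# ---------------------------------------------------------------------------
# rolling-ball background subtraction
# ---------------------------------------------------------------------------


def disk_footprint(radius: int) -> np.ndarray:
    """Boolean disk structuring element of the given pixel radius."""
    ax = np.arange(-radius, radius + 1)
    xx, yy = np.meshgrid(ax, ax)
    return (xx**2 + yy**2) <= radius**2


def rolling_ball_subtract(frame: np.ndarray, radius: int) -> np.ndarray:
    """Classical rolling-ball background subtraction.

    The background is the grayscale morphological opening of the frame with
    a flat disk of the given radius; the result is ``frame - background``
    (a white top-hat).  Structures smaller than the ball — droplet puncta —
    survive; structures the ball fits into — the cell body, shading — are
    absorbed into the background.  The output is everywhere >= 0 because an
    opening never exceeds the image.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius > min(frame.shape) / 2:
        raise ValueError(
            f"rolling-ball radius {radius} exceeds half the frame size {frame.shape}"
        )
    background = ndimage.grey_opening(frame, footprint=disk_footprint(int(radius)))
    return frame - background


# ---------------------------------------------------------------------------
# segmentation and gating
# ---------------------------------------------------------------------------


@dataclass
class CellMask:
    """Baseline-frame segmentation: label image plus per-cell summaries.

    ``table`` columns: ``label``, ``area``, ``cy``, ``cx``, ``b_c`` (mean
    baseline intensity above the frame background — the expression proxy
    used for gating, proportional to the biosensor level) and ``gated``.
    """

    labels: np.ndarray
    table: pd.DataFrame

    def __post_init__(self):
        expected = np.arange(1, len(self.table) + 1)
        if not np.array_equal(np.sort(self.table["label"].to_numpy()), expected):
            raise ValueError("labels must be consecutive positive integers")
        if (self.table["b_c"] <= 0).any():
            raise ValueError("every cell must have positive baseline brightness")

    @property
    def n_cells(self) -> int:
        return len(self.table)

    @property
    def gated_labels(self) -> np.ndarray:
        return self.table.loc[self.table["gated"], "label"].to_numpy()

    def pixels_of(self, label: int) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.labels == label)


def segment_cells(baseline_frame: np.ndarray, params: QuantParams | None = None) -> CellMask:
    """Threshold-and-label segmentation of the pre-stimulus frame.

    The intensity threshold is ``median + k_seg * 1.4826 * MAD`` of the whole
    frame (a robust background estimate, valid while cells cover a minority
    of pixels); 8-connected components of at least ``min_cell_area`` pixels
    become cells.  B_c is the mean baseline intensity within each label
    minus the frame median, so it tracks the biosensor expression level
    rather than the camera offset.
    """
    params = params or QuantParams()
    frame = np.asarray(baseline_frame, dtype=np.float64)
    med = np.median(frame)
    mad = np.median(np.abs(frame - med))
    thr = med + params.k_seg * 1.4826 * mad
    fg = frame > thr
    labels, n_found = ndimage.label(fg, structure=np.ones((3, 3), dtype=bool))
    if n_found == 0:
        raise ValueError("no cells detected")
    # drop small components, relabel consecutively
    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero(areas >= params.min_cell_area)
    keep = keep[keep > 0]
    if len(keep) == 0:
        raise ValueError("no cells detected")
    remap = np.zeros(n_found + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    labels = remap[labels]

    rows = []
    centroids = ndimage.center_of_mass(fg, labels, np.arange(1, len(keep) + 1))
    means = ndimage.mean(frame, labels, np.arange(1, len(keep) + 1)) - med
    sizes = np.bincount(labels.ravel())[1:]
    for i in range(len(keep)):
        rows.append(
            {
                "label": i + 1,
                "area": int(sizes[i]),
                "cy": centroids[i][0],
                "cx": centroids[i][1],
                "b_c": float(means[i]),
                "gated": True,
            }
        )
    return CellMask(labels=labels, table=pd.DataFrame(rows))


def gate_expression(mask: CellMask, params: QuantParams | None = None) -> CellMask:
    """Set the gated flag: keep only cells whose B_c exceeds the threshold.

    Only gated cells enter any downstream response statistic — dim cells
    cannot display detectable droplet formation, so including them would
    deflate every responder share.  Gating is monotone: raising the
    threshold never gains a gated cell.
    """
    params = params or QuantParams()
    if params.threshold_mode == "percentile":
        thr = float(np.percentile(mask.table["b_c"], params.expression_threshold))
    else:
        thr = float(params.expression_threshold)
        if thr < 0:
            raise ValueError("fixed expression threshold must be >= 0")
    table = mask.table.copy()
    table["gated"] = table["b_c"] > thr
    return CellMask(labels=mask.labels, table=table)


# ---------------------------------------------------------------------------
# droplet detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Droplet:
    label: int  # owning cell label
    area: int
    integrated_intensity: float
    pixels: tuple[np.ndarray, np.ndarray] = field(repr=False, compare=False, default=None)


@dataclass
class DropletSet:
    """Droplets of one background-subtracted frame, grouped by cell label."""

    droplets: list[Droplet]
    subtracted: bool = True

    def for_cell(self, label: int) -> list[Droplet]:
        return [d for d in self.droplets if d.label == label]

    def total_area(self, label: int | None = None) -> int:
        return sum(d.area for d in self.droplets if label is None or d.label == label)


def detect_droplets(
    subtracted_frame: np.ndarray,
    mask: CellMask,
    params: QuantParams | None = None,
    *,
    subtracted: bool = True,
) -> DropletSet:
    """Per-cell adaptive droplet detection on a background-subtracted frame.

    Within each gated cell, droplet pixels are those exceeding
    ``median + droplet_k x MAD`` of the cell's subtracted pixels (the
    median offset matters because the opening under-estimates a noisy
    background by a few counts, shifting the whole residual up);
    8-connected components of at least ``min_droplet_area`` pixels become
    droplets.  Droplets never cross cell boundaries (components are
    intersected with the owning mask).
    """
    if not subtracted:
        raise ValueError("detect_droplets requires a background-subtracted frame")
    params = params or QuantParams()
    frame = np.asarray(subtracted_frame, dtype=np.float64)
    if frame.shape != mask.labels.shape:
        raise ValueError("frame and mask shapes differ")
    droplets: list[Droplet] = []
    slices = ndimage.find_objects(mask.labels)
    eight = np.ones((3, 3), dtype=bool)
    for row in mask.table.itertuples():
        if not row.gated:
            continue
        sl = slices[row.label - 1]
        if sl is None:
            continue
        sub = frame[sl]
        inside = mask.labels[sl] == row.label
        vals = sub[inside]
        med = np.median(vals)
        cutoff = med + params.droplet_k * np.median(np.abs(vals - med))
        cand = inside & (sub > cutoff)
        comp, n_comp = ndimage.label(cand, structure=eight)
        if n_comp == 0:
            continue
        for c in range(1, n_comp + 1):
            sel = comp == c
            area = int(sel.sum())
            if area < params.min_droplet_area:
                continue
            rr, cc = np.nonzero(sel)
            droplets.append(
                Droplet(
                    label=row.label,
                    area=area,
                    integrated_intensity=float(sub[sel].sum()),
                    pixels=(rr + sl[0].start, cc + sl[1].start),
                )
            )
    return DropletSet(droplets=droplets, subtracted=True)


def bright_pixel_mask(
    raw_frame: np.ndarray, mask: CellMask, label: int, k: float = 3.0
) -> np.ndarray:
    """Droplet-pixel proxy on the *raw* frame for the intensity-ratio statistic.

    Mimics a manual intensity threshold set above the diffuse cytoplasmic
    level: pixels brighter than ``median + k x MAD`` of the cell's raw
    pixels.  Returns a boolean frame-shaped mask.
    """
    frame = np.asarray(raw_frame, dtype=np.float64)
    inside = mask.labels == label
    vals = frame[inside]
    med = np.median(vals)
    cutoff = med + k * np.median(np.abs(vals - med))
    return inside & (frame > cutoff)


# ---------------------------------------------------------------------------
# the three SPARK statistics
# ---------------------------------------------------------------------------


def spark_stat_intensity_ratio(
    raw_frame: np.ndarray, mask: CellMask, label: int, droplet_pixels: np.ndarray
) -> float:
    """Strategy 1: droplet intensity sum over total cell intensity (raw frame).

    ``droplet_pixels`` is a boolean frame-shaped mask of the droplet pixels
    (must lie inside the cell); returns a value in [0, 1], 0 when empty.
    """
    frame = np.asarray(raw_frame, dtype=np.float64)
    inside = mask.labels == label
    total = frame[inside].sum()
    if total <= 0:
        raise ValueError(f"cell {label} has zero total intensity")
    if droplet_pixels is None:
        return 0.0
    drop = droplet_pixels & inside
    return float(frame[drop].sum() / total)


def spark_stat_sd(raw_frame: np.ndarray, mask: CellMask, label: int) -> float:
    """Strategy 2: population SD of raw intensities within the cell mask."""
    vals = np.asarray(raw_frame, dtype=np.float64)[mask.labels == label]
    if len(vals) == 0:
        raise ValueError(f"cell {label} has an empty mask")
    return float(vals.std(ddof=0))


def spark_stat_area(droplets: DropletSet, label: int) -> float:
    """Strategy 3: total droplet area (px^2) after background subtraction."""
    if not droplets.subtracted:
        raise ValueError("area statistic requires droplets from a subtracted frame")
    return float(droplets.total_area(label))


# ---------------------------------------------------------------------------
# per-cell time traces
# ---------------------------------------------------------------------------


@dataclass
class SparkTrace:
    """Per-cell time series of one droplet statistic.

    ``values`` is (n_gated_cells, T); rows follow ``labels``.
    """

    labels: np.ndarray
    times: np.ndarray
    values: np.ndarray
    statistic: str
    protocol: StimulationProtocol
    normalization: str = "none"

    def row(self, label: int) -> np.ndarray:
        idx = np.flatnonzero(self.labels == label)
        if not len(idx):
            raise KeyError(f"label {label} is not in the trace (ungated?)")
        return self.values[idx[0]]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, lab in enumerate(self.labels):
            for j, t in enumerate(self.times):
                recs.append(
                    {
                        "cell_label": int(lab),
                        "frame": j,
                        "time_min": float(t),
                        "statistic": self.statistic,
                        "value": float(self.values[i, j]),
                    }
                )
        return pd.DataFrame(recs)

    def to_csv(self, path: str | Path, header_comments: dict | None = None) -> None:
        with open(Path(path), "w") as fh:
            fh.write(f"# sparkdrop trace, statistic={self.statistic}, "
                     f"normalization={self.normalization}\n")
            for k, v in (header_comments or {}).items():
                fh.write(f"# {k}={v}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, protocol: StimulationProtocol) -> "SparkTrace":
        df = pd.read_csv(path, comment="#")
        stat = df["statistic"].iloc[0]
        piv = df.pivot(index="cell_label", columns="frame", values="value")
        times = df.drop_duplicates("frame").sort_values("frame")["time_min"].to_numpy()
        return cls(
            labels=piv.index.to_numpy(),
            times=times,
            values=piv.to_numpy(),
            statistic=stat,
            protocol=protocol,
        )


def build_trace(
    stack: ImageStack,
    mask: CellMask,
    params: QuantParams | None = None,
    statistic: str = "area",
) -> SparkTrace:
    """Evaluate one SPARK statistic per gated cell per frame.

    Masks come from the baseline frame and are reused for every frame (cells
    are assumed stationary over the movie).
    """
    params = params or QuantParams()
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    gated = mask.gated_labels
    values = np.zeros((len(gated), stack.n_frames))
    for j in range(stack.n_frames):
        raw = stack.frames[j].astype(np.float64)
        if statistic == "area":
            sub = rolling_ball_subtract(raw, params.rolling_ball_radius)
            drops = detect_droplets(sub, mask, params)
            for i, lab in enumerate(gated):
                values[i, j] = spark_stat_area(drops, lab)
        elif statistic == "sd":
            for i, lab in enumerate(gated):
                values[i, j] = spark_stat_sd(raw, mask, lab)
        else:
            for i, lab in enumerate(gated):
                bright = bright_pixel_mask(raw, mask, lab, params.ratio_k)
                values[i, j] = spark_stat_intensity_ratio(raw, mask, lab, bright)
    return SparkTrace(
        labels=np.asarray(gated),
        times=stack.timestamps.copy(),
        values=values,
        statistic=statistic,
        protocol=stack.protocol,
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_trace(trace: SparkTrace, mode: str) -> SparkTrace:
    """Normalize each cell's trace to its maximum or to its t0 value.

    ``to_max`` yields values in [0, 1]; ``to_t0`` yields fold change over
    the first time point ("contrast").  ``to_t0`` fails on a zero baseline —
    which is exactly why the zero-baseline area statistic needs the epsilon
    floor of :func:`contrast_score` for contrast comparisons.
    """
    if mode not in ("to_max", "to_t0"):
        raise ValueError("mode must be 'to_max' or 'to_t0'")
    vals = trace.values.astype(np.float64)
    if mode == "to_max":
        denom = vals.max(axis=1, keepdims=True)
        if (denom <= 0).any():
            raise ValueError("to_max requires every cell trace to have a positive maximum")
    else:
        denom = vals[:, :1]
        if (denom <= 0).any():
            raise ValueError("to_t0 requires a positive value at the zero time point")
    return SparkTrace(
        labels=trace.labels.copy(),
        times=trace.times.copy(),
        values=vals / denom,
        statistic=trace.statistic,
        protocol=trace.protocol,
        normalization=mode,
    )


def contrast_score(trace_row: np.ndarray, baseline_frames: int, eps: float = 0.0) -> float:
    """Fold change of the trace maximum over its pre-stimulus baseline.

    ``eps`` is the floor added to the baseline; the area statistic uses
    eps = 1 px^2 so that its (typically exactly zero) baseline still yields
    a finite contrast.
    """
    base = float(np.mean(trace_row[:baseline_frames]))
    if base + eps <= 0:
        raise ValueError("zero baseline: use a positive eps floor")
    return float(trace_row.max() / (base + eps))
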