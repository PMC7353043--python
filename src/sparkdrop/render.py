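"""Render latent population state into synthetic fluorescence time-lapse stacks.

Each cell is drawn as a uniform disk whose brightness is proportional to its
biosensor expression; droplet mass is converted into a set of Gaussian puncta
whose peak brightness is also proportional to expression, so dim cells form
puncta that vanish into the read noise — the mechanism behind the detection
floor.  Punctum positions are drawn once per cell and persist across frames;
puncta appear and disappear in seniority order, so droplet patterns are
temporally coherent.

The per-frame punctum count is Poisson(D_i(t)/mass_per_punctum) in
distribution.  To keep it monotone in droplet mass over time (real droplets
do not blink), the count is produced by inverting the Poisson CDF at one
fixed uniform variate per cell (a common-random-number coupling): each
frame's count is marginally Poisson, and the whole count trace is comonotone
with the latent mass trace.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import stats

from .population import ActivityTraces, CellRoster, StimulationProtocol

__all__ = ["OpticsConfig", "ImageStack", "render_stack", "write_stack", "read_stack"]


@dataclass(frozen=True)
class OpticsConfig:
    """Acquisition model for the synthetic microscope.

    Units: intensities in camera counts, lengths in pixels, time in minutes.
    ``photon_scale`` converts one expression unit into disk counts;
    ``droplet_intensity_gain`` converts expression into punctum peak counts;
    ``droplet_unit_area`` bounds the rendered footprint of one punctum
    (kernel support radius ``sqrt(area/pi)``); ``mass_per_punctum`` is the
    droplet mass represented by one punctum.
    """

    frame_shape: tuple[int, int] = (512, 512)
    psf_sigma: float = 1.1
    background_level: float = 100.0
    read_noise_sd: float = 3.0
    photon_scale: float = 1.0
    droplet_unit_area: float = 12.0
    droplet_intensity_gain: float = 0.35
    mass_per_punctum: float = 1.0
    frame_interval: float = 1.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self):
        positive = (
            "psf_sigma",
            "background_level",
            "read_noise_sd",
            "photon_scale",
            "droplet_unit_area",
            "droplet_intensity_gain",
            "mass_per_punctum",
            "frame_interval",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth == 8 else np.uint16

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["frame_shape"] = list(self.frame_shape)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "OpticsConfig":
        d = json.loads(text)
        d["frame_shape"] = tuple(d["frame_shape"])
        return cls(**d)


@dataclass
class ImageStack:
    """A rendered (or loaded) movie: T x H x W frames plus metadata."""

    frames: np.ndarray
    timestamps: np.ndarray
    protocol: StimulationProtocol
    optics: OpticsConfig

    def __post_init__(self):
        if self.frames.ndim != 3:
            raise ValueError("frames must be T x H x W")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if self.frames.dtype != self.optics.dtype:
            raise ValueError(
                f"frame dtype {self.frames.dtype} does not match bit depth "
                f"{self.optics.bit_depth}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def baseline_frame(self) -> np.ndarray:
        """Mean of the pre-stimulus frames, as float counts."""
        first = (
            self.protocol.events[0].time_min
            if self.protocol.events
            else self.timestamps[-1] + 1
        )
        pre = self.frames[self.timestamps < first]
        if len(pre) == 0:
            pre = self.frames[:1]
        return pre.mean(axis=0)


def _disk_pixels(x: float, y: float, radius: float, shape: tuple[int, int]):
    """Integer pixel coordinates (rows, cols) inside a disk."""
    h, w = shape
    r0 = max(int(np.floor(y - radius)) - 1, 0)
    r1 = min(int(np.ceil(y + radius)) + 2, h)
    c0 = max(int(np.floor(x - radius)) - 1, 0)
    c1 = min(int(np.ceil(x + radius)) + 2, w)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - y) ** 2 + (cc - x) ** 2 <= radius**2
    return rr[inside], cc[inside]


def roster_disk_labels(roster: CellRoster, shape: tuple[int, int]) -> np.ndarray:
    """Ground-truth label image of the roster's disks (cell_id + 1)."""
    labels = np.zeros(shape, dtype=np.int32)
    for row in roster.cells.itertuples():
        rr, cc = _disk_pixels(row.x, row.y, row.radius, shape)
        labels[rr, cc] = row.cell_id + 1
    return labels


def _punctum_kernel(peak: float, sigma: float, support_area: float) -> np.ndarray:
    """Gaussian punctum with hard support of the configured unit area."""
    r_max = np.sqrt(support_area / np.pi)
    half = int(np.ceil(r_max))
    ax = np.arange(-half, half + 1)
    xx, yy = np.meshgrid(ax, ax)
    d2 = xx**2 + yy**2
    kern = peak * np.exp(-d2 / (2.0 * sigma**2))
    kern[d2 > r_max**2] = 0.0
    return kern


def render_stack(
    roster: CellRoster,
    traces: ActivityTraces,
    optics: OpticsConfig | None = None,
    protocol: StimulationProtocol | None = None,
) -> ImageStack:
    """Render the latent traces into a noisy unsigned-integer image stack.

    Frames are taken every ``optics.frame_interval`` minutes from 0 to the
    protocol duration (inclusive).  Identical inputs and seed give a
    bit-identical stack.
    """
    optics = optics or OpticsConfig()
    if protocol is None:
        raise ValueError("protocol is required (it defines the movie duration)")
    duration = protocol.duration_min
    if traces.times[-1] < duration - 1e-9:
        raise ValueError("latent traces do not cover the full protocol duration")
    timestamps = np.arange(0.0, duration + 1e-9, optics.frame_interval)

    shape = optics.frame_shape
    rng = np.random.default_rng(optics.seed)
    df = roster.cells

    # static component: background + expression disks
    base = np.full(shape, optics.background_level, dtype=np.float64)
    disk_idx = []
    for row in df.itertuples():
        rr, cc = _disk_pixels(row.x, row.y, row.radius, shape)
        base[rr, cc] += row.expression * optics.photon_scale
        disk_idx.append((rr, cc))

    mass = traces.mass_at(timestamps)  # (n_cells, T)
    lam = mass / optics.mass_per_punctum
    lam_max = float(lam.max()) if lam.size else 1.0

    # persistent punctum positions (seniority order) + one CRN uniform per cell
    n_positions = int(stats.poisson.ppf(0.9999, max(lam_max, 1.0))) + 3
    positions = []
    for row in df.itertuples():
        u = rng.uniform(0.0, 1.0, n_positions)
        theta = rng.uniform(0.0, 2.0 * np.pi, n_positions)
        rad = 0.75 * row.radius * np.sqrt(u)
        positions.append(
            np.column_stack([row.x + rad * np.cos(theta), row.y + rad * np.sin(theta)])
        )
    count_u = rng.uniform(0.0, 1.0, len(df))
    if lam.size:
        counts = stats.poisson.ppf(count_u[:, None], np.clip(lam, 1e-12, None)).astype(int)
        counts = np.minimum(counts, n_positions)
    else:
        counts = np.zeros((0, len(timestamps)), dtype=int)

    kernels = {
        row.cell_id: _punctum_kernel(
            row.expression * optics.droplet_intensity_gain,
            optics.psf_sigma,
            optics.droplet_unit_area,
        )
        for row in df.itertuples()
    }

    frames = np.empty((len(timestamps), *shape), dtype=optics.dtype)
    h, w = shape
    for t_idx in range(len(timestamps)):
        frame = base.copy()
        for i, row in enumerate(df.itertuples()):
            n_p = counts[i, t_idx]
            if n_p == 0:
                continue
            kern = kernels[row.cell_id]
            half = kern.shape[0] // 2
            for px, py in positions[i][:n_p]:
                r, c = int(round(py)), int(round(px))
                r0, r1 = r - half, r + half + 1
                c0, c1 = c - half, c + half + 1
                kr0, kc0 = max(0, -r0), max(0, -c0)
                kr1 = kern.shape[0] - max(0, r1 - h)
                kc1 = kern.shape[1] - max(0, c1 - w)
                frame[max(r0, 0):min(r1, h), max(c0, 0):min(c1, w)] += kern[kr0:kr1, kc0:kc1]
        frame += rng.normal(0.0, optics.read_noise_sd, shape)
        np.clip(frame, 0, optics.max_count, out=frame)
        frames[t_idx] = np.round(frame).astype(optics.dtype)

    return ImageStack(frames=frames, timestamps=timestamps, protocol=protocol, optics=optics)


# ---------------------------------------------------------------------------
# disk I/O: multi-page TIFF + sidecar JSON
# ---------------------------------------------------------------------------


def write_stack(stack: ImageStack, tiff_path: str | Path, sidecar_path: str | Path | None = None) -> Path:
    """Write a multi-page TIFF (one page per frame) and a sidecar JSON."""
    tiff_path = Path(tiff_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    tifffile.imwrite(tiff_path, stack.frames)
    sha = hashlib.sha256(stack.frames.tobytes()).hexdigest()[:16]
    sidecar_path.write_text(
        json.dumps(
            {
                "schema": "sparkdrop/1",
                "timestamps_min": stack.timestamps.tolist(),
                "protocol": json.loads(stack.protocol.to_json()),
                "optics": json.loads(stack.optics.to_json()),
                "frames_sha256_16": sha,
            },
            indent=2,
        )
    )
    return sidecar_path


def read_stack(tiff_path: str | Path, sidecar_path: str | Path | None = None) -> ImageStack:
    """Read back a TIFF + sidecar pair written by :func:`write_stack`."""
    tiff_path = Path(tiff_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text())
    if meta.get("schema") != "sparkdrop/1":
        raise ValueError(f"unrecognized sidecar schema {meta.get('schema')!r}")
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    protocol = StimulationProtocol.from_json(json.dumps(meta["protocol"]))
    optics = OpticsConfig.from_json(json.dumps(meta["optics"]))
    return ImageStack(
        frames=frames,
        timestamps=np.asarray(meta["timestamps_min"], dtype=float),
        protocol=protocol,
        optics=optics,
    )
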