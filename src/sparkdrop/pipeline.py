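"""End-to-end composition: simulate -> render -> quantify -> call.

These helpers wire the modules together for parameter-recovery studies: a
ground-truth roster is simulated, rendered into a noisy movie, and the image
pipeline alone (segmentation, gating, rolling-ball subtraction, droplet
detection, responder calling) must recover the population structure.

``replicate_field_design`` holds the replicate-field geometry used for the
recovery studies: 250 cells per field need more room than the 512x512 demo
frame, so fields are 704x704 with radius-10 cells, imaged every 2 min.  The
rolling-ball radius scales with the cell radius (it must fit inside the
cell for the plateau to be background).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .calling import CallingParams, PopulationSummary, call_all, population_share
from .population import (
    CellRoster,
    KineticParams,
    StimulationProtocol,
    SyntheticConfig,
    simulate_activity,
    simulate_roster,
    single_stimulus_protocol,
)
from .quant import CellMask, QuantParams, SparkTrace, build_trace, gate_expression, segment_cells
from .render import ImageStack, OpticsConfig, render_stack

__all__ = [
    "FieldResult",
    "run_field",
    "recover_share",
    "replicate_field_design",
    "match_labels_to_roster",
]


@dataclass
class FieldResult:
    """Everything produced for one simulated field of view."""

    roster: CellRoster
    stack: ImageStack
    mask: CellMask
    trace: SparkTrace
    calls: pd.DataFrame


def replicate_field_design(n_cells: int = 250, seed: int = 0) -> tuple[SyntheticConfig, OpticsConfig, QuantParams]:
    """Replicate-field geometry for population-share recovery studies."""
    frame = (704, 704) if n_cells > 60 else (352, 352)
    config = SyntheticConfig(
        n_cells=n_cells, frame_shape=frame, cell_radius=10.0, seed=seed
    )
    optics = OpticsConfig(frame_shape=frame, frame_interval=2.0, seed=seed + 1)
    quant = QuantParams(rolling_ball_radius=5, min_cell_area=40)
    return config, optics, quant


def run_field(
    config: SyntheticConfig,
    protocol: StimulationProtocol,
    optics: OpticsConfig | None = None,
    quant: QuantParams | None = None,
    calling: CallingParams | None = None,
    kinetics: KineticParams | None = None,
    statistic: str = "area",
) -> FieldResult:
    """Simulate one field and run the full quantification pipeline on it."""
    optics = optics or OpticsConfig(frame_shape=config.frame_shape, seed=config.seed + 1)
    if optics.frame_shape != config.frame_shape:
        raise ValueError("optics.frame_shape must match the roster frame_shape")
    quant = quant or QuantParams()
    calling = calling or CallingParams()

    roster = simulate_roster(config)
    traces = simulate_activity(roster, protocol, kinetics)
    stack = render_stack(roster, traces, optics, protocol)
    mask = segment_cells(stack.baseline_frame(), quant)
    mask = gate_expression(mask, quant)
    trace = build_trace(stack, mask, quant, statistic=statistic)
    calls = call_all(trace, calling)
    return FieldResult(roster=roster, stack=stack, mask=mask, trace=trace, calls=calls)


def recover_share(
    base_config: SyntheticConfig,
    protocol: StimulationProtocol,
    agent: str,
    n_replicates: int = 4,
    seeds: list[int] | None = None,
    optics: OpticsConfig | None = None,
    quant: QuantParams | None = None,
    calling: CallingParams | None = None,
    kinetics: KineticParams | None = None,
) -> PopulationSummary:
    """Recovered responder share for one agent across replicate fields."""
    seeds = seeds if seeds is not None else list(range(1, n_replicates + 1))
    frames = []
    for rep, seed in enumerate(seeds):
        config = replace(base_config, seed=int(seed))
        rep_optics = (
            replace(optics, seed=int(seed) + 1)
            if optics is not None
            else OpticsConfig(frame_shape=config.frame_shape, seed=int(seed) + 1)
        )
        result = run_field(config, protocol, rep_optics, quant, calling, kinetics)
        calls = result.calls
        calls = calls[calls["agent"] == agent].copy()
        calls["_replicate"] = rep
        frames.append(calls)
    merged = pd.concat(frames, ignore_index=True)
    return population_share(merged, merged["_replicate"].to_numpy())


def match_labels_to_roster(mask: CellMask, roster: CellRoster, max_dist: float = 5.0) -> pd.DataFrame:
    """Match segmented labels to ground-truth cells by centroid distance.

    Returns a frame with columns ``label`` and ``cell_id`` (-1 when no roster
    cell lies within ``max_dist`` pixels of the label centroid).
    """
    gx = roster.cells["x"].to_numpy()
    gy = roster.cells["y"].to_numpy()
    ids = roster.cells["cell_id"].to_numpy()
    rows = []
    for row in mask.table.itertuples():
        d2 = (gx - row.cx) ** 2 + (gy - row.cy) ** 2
        j = int(np.argmin(d2))
        rows.append(
            {
                "label": row.label,
                "cell_id": int(ids[j]) if d2[j] <= max_dist**2 else -1,
                "dist": float(np.sqrt(d2[j])),
            }
        )
    return pd.DataFrame(rows)
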