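"""Responder calling, population shares, sequential overlap and clone summaries.

A cell is a responder to a stimulus when its droplet statistic rises above a
re-anchored pre-stimulus baseline by more than a margin, and stays there for
a minimum number of consecutive frames.  Because droplet disassembly is slow
(droplets partially persist >= 30 min after wash-off), sequential protocols
cannot wait for a return to the basal state: the baseline window is
re-anchored immediately before *each* stimulus, so persisting droplets from
an earlier hormone do not count as a new response.

The population share is the ratio of responding cells to all
expression-gated cells, reported per replicate field and summarized as
mean +/- SE across replicates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .population import StimulationProtocol, StimulusEvent
from .quant import SparkTrace

__all__ = [
    "CallingParams",
    "ResponseCall",
    "PopulationSummary",
    "call_response",
    "call_all",
    "classify_archetype",
    "population_share",
    "sequential_overlap",
    "clone_summary",
]


@dataclass(frozen=True)
class CallingParams:
    """Responder criterion and archetype thresholds.

    The rise margin is ``max(abs_min_rise, k_resp * baseline_noise_sd)``;
    ``abs_min_rise`` (default 8, in the units of the chosen statistic —
    px^2 for the area statistic, i.e. two minimum-size droplets) guards the
    zero-baseline area statistic, whose baseline SD is typically exactly 0.
    A responder must exceed baseline + margin for ``min_frames`` consecutive
    frames.  Archetype: transient responses fall below baseline +
    ``sustain_frac`` x amplitude within ``t_trans_min`` minutes of the peak;
    sustained ones do not.  ``smooth_frames`` is the moving-average window
    applied before archetype classification only.
    """

    b_win_min: float = 6.0
    k_resp: float = 5.0
    abs_min_rise: float = 8.0
    min_frames: int = 3
    t_trans_min: float = 15.0
    sustain_frac: float = 0.88
    smooth_frames: int = 3

    def __post_init__(self):
        if self.b_win_min <= 0 or self.k_resp < 0 or self.abs_min_rise < 0:
            raise ValueError("invalid calling parameters")
        if self.min_frames < 1 or self.smooth_frames < 1:
            raise ValueError("frame counts must be >= 1")
        if not 0 < self.sustain_frac < 1:
            raise ValueError("sustain_frac must be in (0, 1)")


@dataclass
class ResponseCall:
    """Per-cell, per-stimulus decision.

    ``responder`` is True iff the cell *formed* droplets in response to the
    stimulus (archetype transient or sustained); a dissolution response
    (net loss of pre-existing droplets) is archetype ``dissolving`` with
    ``responder=False`` so it never inflates the droplet-formation share.
    """

    cell_label: int
    agent: str
    stim_time_min: float
    responder: bool
    amplitude: float
    baseline: float
    onset_frame: int | None
    duration_min: float
    archetype: str

    def __post_init__(self):
        if self.responder != (self.archetype in ("transient", "sustained")):
            raise ValueError("responder flag inconsistent with archetype")


@dataclass
class PopulationSummary:
    n_gated: int
    n_responding: int
    share_pct: float
    se_pct: float
    per_replicate: pd.DataFrame

    def __post_init__(self):
        if not 0 <= self.share_pct <= 100 or self.n_responding > self.n_gated:
            raise ValueError("inconsistent population summary")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_gated": self.n_gated,
                "n_responding": self.n_responding,
                "share_pct": self.share_pct,
                "se_pct": self.se_pct,
                "per_replicate": self.per_replicate.to_dict(orient="records"),
            },
            indent=2,
        )


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    pad = np.pad(x, (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def _windows(trace: SparkTrace, stimulus: StimulusEvent, params: CallingParams):
    """Baseline and post-stimulus frame index windows for one stimulus."""
    t = trace.times
    base = np.flatnonzero((t >= stimulus.time_min - params.b_win_min) & (t < stimulus.time_min))
    if len(base) < 2:
        raise ValueError(
            f"baseline window before t={stimulus.time_min} min has {len(base)} frames (< 2)"
        )
    later = [e.time_min for e in trace.protocol.stimuli if e.time_min > stimulus.time_min]
    t_end = min(later) if later else t[-1] + 1
    post = np.flatnonzero((t >= stimulus.time_min) & (t < t_end))
    if len(post) == 0:
        raise ValueError("stimulus has no post-stimulus frames within the movie")
    return base, post


def call_response(
    trace: SparkTrace,
    cell_label: int,
    stimulus: StimulusEvent,
    params: CallingParams | None = None,
) -> ResponseCall:
    """Call one cell's response to one stimulus.

    The baseline is the mean statistic over the ``b_win_min`` window ending
    at the stimulus; droplet formation requires the trace to exceed
    baseline + margin for ``min_frames`` consecutive post-stimulus frames.
    Dissolution (only callable when the cell already carries droplets,
    baseline > abs_min_rise) requires the trace to fall below
    baseline - margin for the same run length.
    """
    params = params or CallingParams()
    y = trace.row(cell_label)
    base_idx, post_idx = _windows(trace, stimulus, params)
    baseline = float(y[base_idx].mean())
    # robust noise scale: a droplet-laden baseline steps by whole puncta when
    # mass crosses a count boundary; the MAD ignores such single jumps where
    # a plain SD would inflate the margin and mask genuine re-stimulation
    med = np.median(y[base_idx])
    noise_sd = float(1.4826 * np.median(np.abs(y[base_idx] - med)))
    margin = max(params.abs_min_rise, params.k_resp * noise_sd)

    post = y[post_idx]
    above = post > baseline + margin
    onset_rel = _first_run(above, params.min_frames)

    archetype = "nonresponder"
    responder = False
    amplitude = float(post.max() - baseline)
    onset_frame = None
    duration = 0.0

    if onset_rel is not None:
        responder = True
        onset_frame = int(post_idx[onset_rel])
        archetype = classify_archetype(y, trace.times, post_idx, baseline, params)
        half = baseline + 0.5 * amplitude
        dt_frame = float(np.median(np.diff(trace.times)))
        duration = float((post > half).sum() * dt_frame)
    elif baseline > params.abs_min_rise:
        below = post < baseline - margin
        if _first_run(below, params.min_frames) is not None:
            archetype = "dissolving"
            amplitude = float(post.min() - baseline)

    return ResponseCall(
        cell_label=int(cell_label),
        agent=stimulus.agent,
        stim_time_min=stimulus.time_min,
        responder=responder,
        amplitude=amplitude,
        baseline=baseline,
        onset_frame=onset_frame,
        duration_min=duration,
        archetype=archetype,
    )


def _first_run(flags: np.ndarray, run: int) -> int | None:
    """Index of the first position opening a run of ``run`` consecutive True."""
    if run == 1:
        hits = np.flatnonzero(flags)
        return int(hits[0]) if len(hits) else None
    conv = np.convolve(flags.astype(int), np.ones(run, dtype=int), mode="valid")
    hits = np.flatnonzero(conv == run)
    return int(hits[0]) if len(hits) else None


def classify_archetype(
    y: np.ndarray,
    times: np.ndarray,
    post_idx: np.ndarray,
    baseline: float,
    params: CallingParams,
) -> str:
    """Transient vs sustained from the smoothed post-stimulus trace.

    Droplet disassembly is slow (half-life >= 30 min), so a transient
    response does not return to half its amplitude within a movie; instead
    the discriminator asks whether the smoothed trace decays below
    ``baseline + sustain_frac x amplitude`` within ``t_trans_min`` minutes
    of the peak.  A sustained response keeps integrating droplet mass and
    stays at or above its plateau.
    """
    smooth = _moving_average(y, params.smooth_frames)
    post = smooth[post_idx]
    peak_rel = int(np.argmax(post))
    amplitude = post[peak_rel] - baseline
    t_post = times[post_idx]
    window = (t_post > t_post[peak_rel]) & (t_post <= t_post[peak_rel] + params.t_trans_min)
    if not window.any():
        return "sustained"
    cut = baseline + params.sustain_frac * amplitude
    return "transient" if post[window].min() < cut else "sustained"


def call_all(
    trace: SparkTrace,
    params: CallingParams | None = None,
    stimuli: list[StimulusEvent] | None = None,
) -> pd.DataFrame:
    """Call every gated cell against every (non-wash) stimulus of the protocol."""
    params = params or CallingParams()
    stimuli = list(stimuli) if stimuli is not None else list(trace.protocol.stimuli)
    if not stimuli:
        raise ValueError("protocol has no stimuli to call against")
    records = []
    for stim in stimuli:
        for lab in trace.labels:
            call = call_response(trace, lab, stim, params)
            records.append(
                {
                    "cell_label": call.cell_label,
                    "agent": call.agent,
                    "stim_time_min": call.stim_time_min,
                    "responder": call.responder,
                    "amplitude": call.amplitude,
                    "baseline": call.baseline,
                    "onset_frame": call.onset_frame,
                    "duration_min": call.duration_min,
                    "archetype": call.archetype,
                }
            )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# population summaries
# ---------------------------------------------------------------------------


def population_share(
    calls: pd.DataFrame, replicate: np.ndarray | pd.Series | None = None
) -> PopulationSummary:
    """Responder share, mean +/- SE across replicate units.

    ``calls`` must contain one row per gated cell (for one stimulus) with a
    boolean ``responder`` column; ``replicate`` labels rows by field /
    experiment (a single replicate if omitted).  Share per replicate is
    ``100 * n_responding / n_gated``; the summary SE is the sample SD of the
    replicate shares divided by sqrt(R).  Replicates with no gated cells are
    excluded with a warning.
    """
    if len(calls) == 0:
        raise ValueError("no calls supplied")
    rep = (
        np.asarray(replicate)
        if replicate is not None
        else np.zeros(len(calls), dtype=int)
    )
    df = calls.assign(_rep=rep)
    rows = []
    for r, grp in df.groupby("_rep"):
        n_gated = len(grp)
        if n_gated == 0:
            warnings.warn(f"replicate {r!r} has no gated cells; excluded")
            continue
        n_resp = int(grp["responder"].sum())
        rows.append({"replicate": r, "n_gated": n_gated, "n_responding": n_resp,
                     "share_pct": 100.0 * n_resp / n_gated})
    if not rows:
        raise ValueError("every replicate was empty")
    per_rep = pd.DataFrame(rows)
    shares = per_rep["share_pct"].to_numpy()
    se = float(shares.std(ddof=1) / np.sqrt(len(shares))) if len(shares) > 1 else 0.0
    return PopulationSummary(
        n_gated=int(per_rep["n_gated"].sum()),
        n_responding=int(per_rep["n_responding"].sum()),
        share_pct=float(shares.mean()),
        se_pct=se,
        per_replicate=per_rep,
    )


def sequential_overlap(calls: pd.DataFrame) -> pd.DataFrame:
    """Overlap accounting for a sequential-stimulation experiment.

    ``calls`` holds one row per (cell, stimulus).  For each stimulus in
    protocol order the table reports the responder count, the count of *new*
    responders (cells that responded to no earlier stimulus), and the
    cumulative union share of all responders so far among gated cells.
    """
    stims = calls.drop_duplicates(["agent", "stim_time_min"]).sort_values("stim_time_min")
    if len(stims) < 2:
        raise ValueError("sequential overlap needs at least two stimuli")
    cell_sets = {}
    gated_sets = {}
    for stim in stims.itertuples():
        grp = calls[(calls["agent"] == stim.agent) & (calls["stim_time_min"] == stim.stim_time_min)]
        gated_sets[(stim.agent, stim.stim_time_min)] = set(grp["cell_label"])
        cell_sets[(stim.agent, stim.stim_time_min)] = set(
            grp.loc[grp["responder"], "cell_label"]
        )
    common = set.intersection(*gated_sets.values())
    if not common:
        raise ValueError("stimuli were called on disjoint cell sets")
    n_gated = len(common)
    rows = []
    seen: set = set()
    for stim in stims.itertuples():
        key = (stim.agent, stim.stim_time_min)
        resp = cell_sets[key] & common
        new = resp - seen
        seen |= resp
        rows.append(
            {
                "agent": stim.agent,
                "stim_time_min": stim.stim_time_min,
                "n_gated": n_gated,
                "n_responding": len(resp),
                "n_new": len(new),
                "share_pct": 100.0 * len(resp) / n_gated,
                "new_share_pct": 100.0 * len(new) / n_gated,
                "union_share_pct": 100.0 * len(seen) / n_gated,
            }
        )
    return pd.DataFrame(rows)


def clone_summary(calls_by_clone: dict[object, pd.DataFrame]) -> dict:
    """Clone-level shares with the clone as the replicate unit.

    Each value of ``calls_by_clone`` is a calls table for one clone (one
    stimulus).  Returns per-clone shares and the grand mean +/- SE across
    clones; clones with no gated cells are excluded with a warning.
    """
    if len(calls_by_clone) < 2:
        raise ValueError("clone summary needs at least two clones")
    rows = []
    for clone, calls in calls_by_clone.items():
        if len(calls) == 0:
            warnings.warn(f"clone {clone!r} has no gated cells; excluded")
            continue
        n_resp = int(calls["responder"].sum())
        rows.append(
            {
                "clone": clone,
                "n_gated": len(calls),
                "n_responding": n_resp,
                "share_pct": 100.0 * n_resp / len(calls),
            }
        )
    if len(rows) < 2:
        raise ValueError("fewer than two non-empty clones")
    per_clone = pd.DataFrame(rows)
    shares = per_clone["share_pct"].to_numpy()
    return {
        "per_clone": per_clone,
        "grand_mean_pct": float(shares.mean()),
        "se_pct": float(shares.std(ddof=1) / np.sqrt(len(shares))),
        "sd_pct": float(shares.std(ddof=1)),
    }


def plot_traces(trace: SparkTrace, path: str | Path, max_cells: int = 30) -> Path:
    """Quick-look per-cell trace plot (thin colored lines + mean)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for i in range(min(len(trace.labels), max_cells)):
        ax.plot(trace.times, trace.values[i], lw=0.7, alpha=0.6)
    ax.plot(trace.times, trace.values.mean(axis=0), lw=2.5, color="0.3", label="mean")
    for ev in trace.protocol.events:
        ax.axvline(ev.time_min, ls="--", color="k", lw=0.8)
        ax.annotate(ev.agent, (ev.time_min, ax.get_ylim()[1]), fontsize=7, rotation=90)
    ax.set_xlabel("time (min)")
    ax.set_ylabel(trace.statistic)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
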