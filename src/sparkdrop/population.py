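"""Synthetic heterogeneous cell populations and their latent droplet kinetics.

This module builds the ground truth that the imaging pipeline is later asked
to recover: a roster of disk-shaped cells with heterogeneous biosensor
expression, a sub-population capable of cAMP/PKA activation (i.e. possessing
adenylyl cyclase), hormone-specific responder subsets that largely coincide
("nested" overlap), and per-cell latent PKA-activity / droplet-mass kinetics
under an arbitrary stimulation protocol.

Responder-set construction is deliberately deterministic: exactly
``round_half_up(n_cells * fraction)`` cells belong to each set, so population
shares are exact at roster level and all sampling noise enters downstream,
through rendering and image analysis.  This separates statistical error from
imaging error when validating the pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ARCHETYPES",
    "HormoneSpec",
    "SyntheticConfig",
    "CellRoster",
    "StimulusEvent",
    "StimulationProtocol",
    "KineticParams",
    "ActivityTraces",
    "simulate_roster",
    "simulate_activity",
    "round_half_up",
]

ARCHETYPES = ("transient", "sustained", "dissolving")

EVENT_KINDS = (
    "receptor_agonist",
    "adenylyl_cyclase_activator",
    "direct_pka_activator",
    "wash",
)


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going away from zero-half (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HormoneSpec:
    """Population-level description of the response to one hormone.

    Parameters
    ----------
    responder_frac:
        Fraction of all cells that respond to this hormone (the quantity the
        pipeline tries to recover).
    archetype_weights:
        Probabilities of the ``transient`` / ``sustained`` / ``dissolving``
        response archetypes among responders; must sum to 1.
    amplitude_mean, amplitude_cv:
        Log-normal amplitude of the latent PKA-activity pulse (arbitrary
        activity units; the transient hormones default to mean 1.0, the weak
        sustained ones to 0.25).
    """

    responder_frac: float
    archetype_weights: Mapping[str, float] = field(
        default_factory=lambda: {"transient": 1.0}
    )
    amplitude_mean: float = 1.0
    amplitude_cv: float = 0.3

    def __post_init__(self):
        if not 0.0 <= self.responder_frac <= 1.0:
            raise ValueError(f"responder_frac must be in [0,1], got {self.responder_frac}")
        unknown = set(self.archetype_weights) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes {unknown}")
        total = sum(self.archetype_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype_weights must sum to 1, got {total}")
        if self.amplitude_mean <= 0 or self.amplitude_cv < 0:
            raise ValueError("amplitude_mean must be > 0 and amplitude_cv >= 0")


def default_hormone_panel() -> dict[str, HormoneSpec]:
    """The five-hormone panel of the study conditions.

    Responder fractions are the reported population shares (adenosine 37.0%,
    noradrenaline 34.7%, dopamine 25.2%, serotonin 16.6%, histamine 4.2%);
    adenosine/noradrenaline/dopamine respond with strong transient kinetics,
    serotonin/histamine with weak sustained ones (amplitude 0.25x).
    """
    strong = dict(archetype_weights={"transient": 1.0}, amplitude_mean=1.0)
    weak = dict(archetype_weights={"sustained": 1.0}, amplitude_mean=0.25)
    return {
        "adenosine": HormoneSpec(0.370, **strong),
        "noradrenaline": HormoneSpec(0.347, **strong),
        "dopamine": HormoneSpec(0.252, **strong),
        "serotonin": HormoneSpec(0.166, **weak),
        "histamine": HormoneSpec(0.042, **weak),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth population structure for one simulated field of view.

    ``frac_capable`` is the fraction of cells possessing adenylyl cyclase,
    i.e. able to respond to receptor agonists and to forskolin; the default
    0.482 is the observed forskolin responder share.  ``frac_pka_responsive``
    is the fraction responding to a direct PKA activator (6-Bnz-cAMP style),
    default 0.912.  ``detection_floor`` is the biosensor expression level
    below which rendered droplets are indistinguishable from noise at default
    optics (see `sparkdrop.render`).
    """

    n_cells: int = 50
    frac_capable: float = 0.482
    frac_pka_responsive: float = 0.912
    hormone_panel: Mapping[str, HormoneSpec] = field(default_factory=default_hormone_panel)
    overlap_mode: str = "nested"  # or "independent"
    nested_epsilon: float = 0.0
    expression_mu: float = math.log(300.0)
    expression_sigma: float = 0.4
    detection_floor: float = 65.0
    activator_amplitude_mean: float = 1.0
    activator_amplitude_cv: float = 0.3
    frame_shape: tuple[int, int] = (512, 512)
    cell_radius: float = 15.0
    min_gap: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        for name, value in [
            ("frac_capable", self.frac_capable),
            ("frac_pka_responsive", self.frac_pka_responsive),
            ("nested_epsilon", self.nested_epsilon),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")
        if self.overlap_mode not in ("nested", "independent"):
            raise ValueError(f"overlap_mode must be 'nested' or 'independent'")
        if self.cell_radius <= 0 or self.min_gap < 0:
            raise ValueError("cell_radius must be > 0 and min_gap >= 0")
        if self.detection_floor < 0:
            raise ValueError("detection_floor must be >= 0")

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["hormone_panel"] = {
            h: {
                "responder_frac": s.responder_frac,
                "archetype_weights": dict(s.archetype_weights),
                "amplitude_mean": s.amplitude_mean,
                "amplitude_cv": s.amplitude_cv,
            }
            for h, s in self.hormone_panel.items()
        }
        d["frame_shape"] = list(self.frame_shape)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        d = json.loads(text)
        d["hormone_panel"] = {
            h: HormoneSpec(**s) for h, s in d.get("hormone_panel", {}).items()
        }
        d["frame_shape"] = tuple(d["frame_shape"])
        return cls(**d)


# ---------------------------------------------------------------------------
# stimulation protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusEvent:
    time_min: float
    agent: str
    kind: str

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}")
        if self.time_min < 0:
            raise ValueError("event time must be >= 0")


@dataclass(frozen=True)
class StimulationProtocol:
    """Ordered stimulation events plus the total movie duration.

    Event times are minutes from movie start; the first event must not
    precede ``baseline_min`` so every call has a pre-stimulus baseline
    window.
    """

    events: tuple[StimulusEvent, ...]
    duration_min: float = 30.0
    baseline_min: float = 6.0

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))
        times = [e.time_min for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if self.events and self.events[0].time_min < self.baseline_min:
            raise ValueError(
                f"first event at {self.events[0].time_min} min precedes the "
                f"{self.baseline_min} min baseline window"
            )
        if self.events and self.events[-1].time_min >= self.duration_min:
            raise ValueError("all events must occur before duration_min")

    @property
    def stimuli(self) -> tuple[StimulusEvent, ...]:
        return tuple(e for e in self.events if e.kind != "wash")

    def to_json(self) -> str:
        return json.dumps(
            {
                "duration_min": self.duration_min,
                "baseline_min": self.baseline_min,
                "events": [
                    {"time_min": e.time_min, "agent": e.agent, "kind": e.kind}
                    for e in self.events
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "StimulationProtocol":
        d = json.loads(text)
        return cls(
            events=tuple(StimulusEvent(**e) for e in d["events"]),
            duration_min=d["duration_min"],
            baseline_min=d.get("baseline_min", 6.0),
        )


def single_stimulus_protocol(
    agent: str,
    kind: str = "receptor_agonist",
    stim_min: float = 6.0,
    duration_min: float = 30.0,
) -> StimulationProtocol:
    """Baseline, one stimulus, observation until ``duration_min``."""
    return StimulationProtocol(
        events=(StimulusEvent(stim_min, agent, kind),),
        duration_min=duration_min,
        baseline_min=stim_min,
    )


def sequential_protocol(
    agents: Iterable[str],
    kind: str = "receptor_agonist",
    first_stim_min: float = 6.0,
    dwell_min: float = 18.0,
    wash_min: float = 2.0,
    tail_min: float = 18.0,
) -> StimulationProtocol:
    """Hormones added one after another with an intensive wash in between.

    Droplets persist through the wash (slow disassembly), so downstream
    response calling re-anchors its baseline immediately before each
    stimulus rather than waiting for a return to the basal state.
    """
    events = []
    t = first_stim_min
    agents = list(agents)
    for i, agent in enumerate(agents):
        events.append(StimulusEvent(t, agent, kind))
        if i < len(agents) - 1:
            events.append(StimulusEvent(t + dwell_min, "wash", "wash"))
            t = t + dwell_min + wash_min
    return StimulationProtocol(
        events=tuple(events), duration_min=t + tail_min, baseline_min=first_stim_min
    )


# ---------------------------------------------------------------------------
# roster
# ---------------------------------------------------------------------------


@dataclass
class CellRoster:
    """Ground-truth table of simulated cells.

    ``cells`` has one row per cell: ``cell_id, x, y, radius, expression,
    capable, pka_responsive, activator_amplitude`` plus, per hormone ``h``,
    ``resp_<h>`` (bool), ``arch_<h>`` (archetype or ''), ``amp_<h>`` (float).
    """

    cells: pd.DataFrame
    hormones: tuple[str, ...]
    config: SyntheticConfig

    def __post_init__(self):
        df = self.cells
        r = df["radius"].to_numpy()
        h, w = self.config.frame_shape
        if ((df["x"] - r < 0) | (df["x"] + r >= w) | (df["y"] - r < 0) | (df["y"] + r >= h)).any():
            raise ValueError("cell disk extends outside the frame")

    def __len__(self) -> int:
        return len(self.cells)

    def responder_ids(self, hormone: str) -> np.ndarray:
        return self.cells.loc[self.cells[f"resp_{hormone}"], "cell_id"].to_numpy()

    def affected_mask(self, event: StimulusEvent) -> np.ndarray:
        """Boolean mask of cells whose PKA activity the event can drive."""
        df = self.cells
        if event.kind == "receptor_agonist":
            col = f"resp_{event.agent}"
            if col not in df.columns:
                raise KeyError(f"hormone {event.agent!r} not in roster panel {self.hormones}")
            return df[col].to_numpy()
        if event.kind == "adenylyl_cyclase_activator":
            return df["capable"].to_numpy()
        if event.kind == "direct_pka_activator":
            return df["pka_responsive"].to_numpy()
        return np.zeros(len(df), dtype=bool)  # wash

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# sparkdrop roster, seed={self.config.seed}\n")
            fh.write(f"# hormones={','.join(self.hormones)}\n")
            self.cells.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, config: SyntheticConfig) -> "CellRoster":
        df = pd.read_csv(path, comment="#")
        hormones = tuple(c[len("resp_"):] for c in df.columns if c.startswith("resp_"))
        return cls(cells=df, hormones=hormones, config=config)


def _place_disks(rng: np.random.Generator, config: SyntheticConfig) -> np.ndarray:
    """Rejection-sample non-overlapping disk centres; (n, 2) array of (x, y)."""
    h, w = config.frame_shape
    r = config.cell_radius
    margin = r + 1.0
    min_d2 = (2 * r + config.min_gap) ** 2
    centers: list[tuple[float, float]] = []
    placed = np.empty((0, 2))
    max_tries = 20000 * config.n_cells
    tries = 0
    while len(centers) < config.n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {config.n_cells} non-overlapping disks of radius "
                f"{r} in a {h}x{w} frame; enlarge the frame or shrink the cells"
            )
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if len(centers):
            d2 = (placed[:, 0] - x) ** 2 + (placed[:, 1] - y) ** 2
            if (d2 < min_d2).any():
                continue
        centers.append((x, y))
        placed = np.asarray(centers)
    return placed


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Log-normal draws parameterized by arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean)
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def simulate_roster(config: SyntheticConfig) -> CellRoster:
    """Draw the deterministic-count population roster.

    Exactly ``round_half_up(n_cells * frac_capable)`` cells are capable; each
    hormone's responder set has exactly ``round_half_up(n_cells *
    responder_frac)`` members.  In nested mode the sets are prefixes of one
    seeded shuffle of the capable cells (largest-first), so they coincide up
    to ``nested_epsilon``; in independent mode each set is drawn independently
    within the capable set.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    centers = _place_disks(rng, config)
    expression = rng.lognormal(config.expression_mu, config.expression_sigma, n)

    n_cap = round_half_up(n * config.frac_capable)
    capable_order = rng.permutation(n)
    capable_ids = capable_order[:n_cap]
    capable = np.zeros(n, dtype=bool)
    capable[capable_ids] = True

    n_pka = round_half_up(n * config.frac_pka_responsive)
    pka_order = rng.permutation(n)
    pka = np.zeros(n, dtype=bool)
    pka[pka_order[:n_pka]] = True

    df = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "x": centers[:, 0],
            "y": centers[:, 1],
            "radius": np.full(n, config.cell_radius),
            "expression": expression,
            "capable": capable,
            "pka_responsive": pka,
            "activator_amplitude": _lognormal(
                rng, config.activator_amplitude_mean, config.activator_amplitude_cv, n
            ),
        }
    )

    # Hormone responder sets: largest-first so smaller sets nest inside larger.
    hormones = tuple(
        sorted(config.hormone_panel, key=lambda h: -config.hormone_panel[h].responder_frac)
    )
    nest_shuffle = rng.permutation(capable_ids)
    for hormone in hormones:
        spec = config.hormone_panel[hormone]
        n_resp = round_half_up(n * spec.responder_frac)
        if n_resp > n_cap:
            raise ValueError(
                f"{hormone}: responder_frac {spec.responder_frac} exceeds "
                f"frac_capable {config.frac_capable} (impossible subset)"
            )
        if config.overlap_mode == "nested":
            n_extra = min(round_half_up(n * config.nested_epsilon), n_cap - n_resp)
            core = nest_shuffle[: n_resp - n_extra] if n_extra else nest_shuffle[:n_resp]
            members = np.concatenate(
                [core, rng.choice(nest_shuffle[len(core):], n_extra, replace=False)]
            ) if n_extra else core
        else:
            members = rng.choice(capable_ids, n_resp, replace=False)
        resp = np.zeros(n, dtype=bool)
        resp[members] = True
        arch = np.array([""] * n, dtype=object)
        names = list(spec.archetype_weights)
        probs = np.array([spec.archetype_weights[a] for a in names])
        arch[members] = rng.choice(names, size=len(members), p=probs / probs.sum())
        amp = np.zeros(n)
        amp[members] = _lognormal(rng, spec.amplitude_mean, spec.amplitude_cv, len(members))
        df[f"resp_{hormone}"] = resp
        df[f"arch_{hormone}"] = arch
        df[f"amp_{hormone}"] = amp

    return CellRoster(cells=df, hormones=hormones, config=config)


# ---------------------------------------------------------------------------
# latent kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticParams:
    """Latent activity / droplet-mass kinetics.

    Transient activity follows a double exponential
    ``A (exp(-t/tau_decay) - exp(-t/tau_rise))``; sustained activity is a
    saturating rise ``A (1 - exp(-t/tau_rise_sustained))``.  Droplet mass
    integrates (forward Euler)

        dD/dt = k_on * max(a - theta_nuc, 0) * max(1 - D/C(a), 0) - k_off * D
        C(a)  = d_max * clip((a - theta_nuc) / cap_ref_activity, 0, 1)

    where ``C(a)`` is the activity-dependent droplet capacity: only the
    phosphorylated reporter fraction can condense, and that fraction tracks
    the current kinase activity.  A strong transient pulse therefore reaches
    a high droplet mass quickly and then decays slowly at ``k_off``, while a
    weak sustained activity plateau holds a *low* droplet mass indefinitely
    ("long but weak") instead of accumulating mass without bound.  The
    dissolving archetype adds ``-k_diss*D`` from its stimulus onward.
    ``k_off`` must keep the droplet half-life >= 30 min, matching the
    observed slow disassembly after hormone wash-off.
    """

    tau_rise: float = 0.5
    tau_decay: float = 5.0
    tau_rise_sustained: float = 3.0
    k_on: float = 5.0
    k_off: float = math.log(2.0) / 45.0
    k_diss: float = 0.5
    theta_nuc: float = 0.05
    d_max: float = 9.0
    cap_ref_activity: float = 0.4
    dt: float = 0.05

    def __post_init__(self):
        for name in ("tau_rise", "tau_decay", "tau_rise_sustained"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("k_on", "k_off", "k_diss", "theta_nuc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.d_max <= 0 or self.cap_ref_activity <= 0:
            raise ValueError("d_max and cap_ref_activity must be > 0")
        if self.k_off > 0 and math.log(2.0) / self.k_off < 30.0:
            raise ValueError("k_off implies droplet half-life < 30 min")
        if self.dt <= 0 or self.dt > self.tau_rise / 2.0:
            raise ValueError(
                f"dt={self.dt} must be in (0, tau_rise/2={self.tau_rise / 2}] "
                "(integration too coarse)"
            )


@dataclass
class ActivityTraces:
    """Latent per-cell traces on the simulation grid (minutes)."""

    times: np.ndarray          # (n_steps,)
    activity: np.ndarray       # (n_cells, n_steps)
    droplet_mass: np.ndarray   # (n_cells, n_steps)
    cell_ids: np.ndarray

    def mass_at(self, t_min: np.ndarray | float) -> np.ndarray:
        """Droplet mass sampled at arbitrary times (nearest simulation step)."""
        idx = np.clip(
            np.round(np.atleast_1d(t_min) / (self.times[1] - self.times[0])).astype(int),
            0,
            len(self.times) - 1,
        )
        return self.droplet_mass[:, idx]


def simulate_activity(
    roster: CellRoster,
    protocol: StimulationProtocol,
    kinetics: KineticParams | None = None,
) -> ActivityTraces:
    """Integrate latent PKA activity and droplet mass for every cell.

    Each stimulus event adds the archetype activity law for the cells it
    affects; a wash zeroes all ongoing activity but leaves droplet mass to
    decay at ``k_off``.  Cells lacking adenylyl cyclase (``capable=False``)
    never respond to receptor agonists or forskolin but do respond to a
    direct PKA activator if ``pka_responsive``.
    """
    kin = kinetics or KineticParams()
    df = roster.cells
    n = len(df)
    n_steps = int(round(protocol.duration_min / kin.dt)) + 1
    times = np.arange(n_steps) * kin.dt
    activity = np.zeros((n, n_steps))
    diss = np.zeros((n, n_steps), dtype=bool)

    wash_times = [e.time_min for e in protocol.events if e.kind == "wash"]

    for event in protocol.events:
        if event.kind == "wash":
            continue
        affected = roster.affected_mask(event)
        if not affected.any():
            continue
        next_wash = min(
            (t for t in wash_times if t > event.time_min), default=protocol.duration_min
        )
        start = int(round(event.time_min / kin.dt))
        stop = min(int(round(next_wash / kin.dt)), n_steps)
        tt = times[start:stop] - event.time_min

        if event.kind == "receptor_agonist":
            arch = df[f"arch_{event.agent}"].to_numpy()
            amp = df[f"amp_{event.agent}"].to_numpy()
        else:
            # adenylyl-cyclase or direct PKA activators: saturating strong drive
            arch = np.where(affected, "sustained", "")
            amp = df["activator_amplitude"].to_numpy()

        for law, idx in (
            ("transient", np.flatnonzero(affected & (arch == "transient"))),
            ("sustained", np.flatnonzero(affected & (arch == "sustained"))),
        ):
            if not len(idx):
                continue
            if law == "transient":
                shape = np.exp(-tt / kin.tau_decay) - np.exp(-tt / kin.tau_rise)
            else:
                shape = 1.0 - np.exp(-tt / kin.tau_rise_sustained)
            activity[idx, start:stop] += amp[idx, None] * shape[None, :]

        dis_idx = np.flatnonzero(affected & (arch == "dissolving"))
        if len(dis_idx):
            diss[dis_idx, start:] = True

    # forward Euler for droplet mass
    excess = np.clip(activity - kin.theta_nuc, 0.0, None)
    drive = kin.k_on * excess
    capacity = kin.d_max * np.clip(excess / kin.cap_ref_activity, 0.0, 1.0)
    mass = np.zeros((n, n_steps))
    decay = kin.k_off + kin.k_diss * diss
    with np.errstate(divide="ignore", invalid="ignore"):
        for k in range(n_steps - 1):
            pool = np.where(
                capacity[:, k] > 0,
                np.clip(1.0 - mass[:, k] / np.where(capacity[:, k] > 0, capacity[:, k], 1.0), 0.0, 1.0),
                0.0,
            )
            mass[:, k + 1] = np.clip(
                mass[:, k] + kin.dt * (drive[:, k] * pool - decay[:, k] * mass[:, k]),
                0.0,
                None,
            )

    return ActivityTraces(
        times=times,
        activity=activity,
        droplet_mass=mass,
        cell_ids=df["cell_id"].to_numpy(),
    )
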