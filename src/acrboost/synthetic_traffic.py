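"""Synthetic congested platoons with a known aggressive minority.

Follower dynamics use the Intelligent Driver Model (IDM):

    a = a_max * [1 - (v / v0)^4 - (s* / s)^2]
    s* = s0 + v*T + v*dv / (2 sqrt(a_max * b))

where v0 is the desired speed, T the desired time gap, s0 the standstill
minimum gap, a_max the maximum acceleration, b the comfortable
deceleration and dv = v_follower - v_leader. Aggressive drivers differ
from normal drivers chiefly by stochastically shorter desired time gaps
and smaller minimum gaps, which produces elevated crash-risk statistics
while keeping the two populations overlapping.

The lead vehicle of each platoon chain follows a stop-and-go speed
profile (sinusoidal oscillation around a low base speed plus noise),
emulating congested freeway flow. Aggressiveness is assigned to drivers
independently of their position, so leader and follower ground truth are
statistically independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory_io import CarFollowingEpisode

__all__ = [
    "DriverProfile",
    "LeadProfile",
    "SimulationConfig",
    "sample_population",
    "simulate_platoon",
    "episodes_to_trajectory_frame",
    "SimulationError",
]


class SimulationError(RuntimeError):
    """Numerical blow-up during integration."""


@dataclass(frozen=True)
class DriverProfile:
    driver_id: int
    is_aggressive: bool
    desired_time_gap: float  # T, s
    min_gap: float  # s0, m
    max_accel: float  # a_max, m/s^2
    comfy_decel: float  # b, m/s^2
    desired_speed: float  # v0, m/s

    def __post_init__(self) -> None:
        for name in (
            "desired_time_gap",
            "min_gap",
            "max_accel",
            "comfy_decel",
            "desired_speed",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class LeadProfile:
    """Stop-and-go speed trace parameters for the head of each chain."""

    base_speed: float = 6.0  # m/s, congested mean
    oscillation_amplitude: float = 4.0  # m/s
    period: float = 60.0  # s
    noise_sd: float = 0.3  # m/s per step


@dataclass(frozen=True)
class SimulationConfig:
    n_drivers: int = 299
    aggressive_fraction: float = 0.144
    duration: float = 60.0  # s per episode
    dt: float = 0.1
    lead_profile: LeadProfile = field(default_factory=LeadProfile)
    chain_length: int = 12  # vehicles per platoon chain (incl. head)
    accel_noise_sd: float = 0.35  # m/s^2, stochastic-IDM acceleration noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.aggressive_fraction < 0.5):
            raise ValueError("aggressive_fraction must be in (0, 0.5)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_drivers < 1:
            raise ValueError("n_drivers must be >= 1")
        if self.chain_length < 2:
            raise ValueError("chain_length must be >= 2")


# Population parameters: normal drivers keep ~1.5 s gaps, aggressive
# drivers tailgate at ~0.6 s. Accel/decel capabilities overlap.
_NORMAL = dict(time_gap_mean=1.5, time_gap_sd=0.2, min_gap=2.0)
_AGGRESSIVE = dict(time_gap_mean=0.6, time_gap_sd=0.15, min_gap=0.8)
_TIME_GAP_FLOOR_AGGR = 0.3
_TIME_GAP_FLOOR_NORM = 0.8


def sample_population(config: SimulationConfig) -> list[DriverProfile]:
    """Draw a driver population with exactly round(n * fraction) aggressive.

    Aggressive status is shuffled over positions so that chain placement
    (hence who leads whom) is independent of aggressiveness.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_drivers
    n_aggr = int(round(n * config.aggressive_fraction))
    flags = np.zeros(n, dtype=bool)
    flags[:n_aggr] = True
    rng.shuffle(flags)

    profiles = []
    for i, aggressive in enumerate(flags):
        pop = _AGGRESSIVE if aggressive else _NORMAL
        floor = _TIME_GAP_FLOOR_AGGR if aggressive else _TIME_GAP_FLOOR_NORM
        tg = rng.normal(pop["time_gap_mean"], pop["time_gap_sd"])
        while tg <= floor:
            tg = rng.normal(pop["time_gap_mean"], pop["time_gap_sd"])
        profiles.append(
            DriverProfile(
                driver_id=i,
                is_aggressive=bool(aggressive),
                desired_time_gap=float(tg),
                min_gap=pop["min_gap"],
                max_accel=float(np.clip(rng.normal(1.5, 0.2), 0.8, 2.5)),
                comfy_decel=float(np.clip(rng.normal(2.0, 0.3), 1.0, 3.5)),
                desired_speed=float(np.clip(rng.normal(16.0, 2.0), 10.0, 25.0)),
            )
        )
    return profiles


def _lead_speed_trace(
    n_steps: int, dt: float, lead: LeadProfile, rng: np.random.Generator
) -> np.ndarray:
    t = np.arange(n_steps) * dt
    phase = rng.uniform(0, 2 * np.pi)
    v = (
        lead.base_speed
        + lead.oscillation_amplitude * np.sin(2 * np.pi * t / lead.period + phase)
        + rng.normal(0.0, lead.noise_sd, n_steps)
    )
    # smooth the per-step noise so acceleration stays physical;
    # edge-pad to avoid boundary droop from the moving average
    kernel = np.ones(5) / 5.0
    v = np.convolve(np.pad(v, 2, mode="edge"), kernel, mode="valid")
    return np.maximum(v, 0.0)


def _idm_accel(v, v_lead, gap, p: DriverProfile) -> float:
    dv = v - v_lead
    s_star = p.min_gap + v * p.desired_time_gap + v * dv / (
        2.0 * np.sqrt(p.max_accel * p.comfy_decel)
    )
    s_star = max(s_star, p.min_gap)
    return p.max_accel * (1.0 - (v / p.desired_speed) ** 4 - (s_star / gap) ** 2)


_MIN_GAP_CLAMP = 0.1  # m
_MAX_DECEL = 8.0  # m/s^2, friction-limited emergency braking cap


def simulate_platoon(
    profiles: list[DriverProfile], config: SimulationConfig
) -> tuple[list[CarFollowingEpisode], pd.DataFrame]:
    """Integrate platoon chains; return episodes and a ground-truth table.

    Drivers are split into chains of ``config.chain_length``; within a
    chain, vehicle k follows vehicle k-1 and vehicle 0 follows the
    stop-and-go lead trace (the head vehicle itself yields no episode
    within its chain, but heads after the first chain are still drivers
    with ground truth; every vehicle with a leader yields one episode of
    ``config.duration`` seconds).
    """
    if not profiles:
        raise ValueError("need at least one profile")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    dt = config.dt
    n_steps = int(round(config.duration / dt)) + 1

    episodes: list[CarFollowingEpisode] = []
    truth_rows = []

    chains = [
        profiles[i : i + config.chain_length]
        for i in range(0, len(profiles), config.chain_length)
    ]
    for chain in chains:
        v_lead = _lead_speed_trace(n_steps, dt, config.lead_profile, rng)
        # state per vehicle in chain: speed, gap to leader
        prev_v = v_lead  # series of the vehicle ahead
        for idx, prof in enumerate(chain):
            v = np.empty(n_steps)
            a = np.empty(n_steps)
            d = np.empty(n_steps)
            # start near equilibrium spacing at the leader's initial speed
            v[0] = prev_v[0]
            d[0] = max(prof.min_gap + v[0] * prof.desired_time_gap, _MIN_GAP_CLAMP)
            noise = rng.normal(0.0, config.accel_noise_sd, n_steps - 1)
            for k in range(n_steps - 1):
                acc = _idm_accel(v[k], prev_v[k], d[k], prof) + noise[k]
                acc = float(np.clip(acc, -_MAX_DECEL, prof.max_accel))
                a[k] = acc
                v_next = max(v[k] + acc * dt, 0.0)
                d_next = d[k] + (prev_v[k] - v[k]) * dt
                v[k + 1] = v_next
                d[k + 1] = max(d_next, _MIN_GAP_CLAMP)
            a[-1] = a[-2]
            if not (np.all(np.isfinite(v)) and np.all(np.isfinite(d))):
                bad = int(np.flatnonzero(~np.isfinite(v))[0]) if np.any(
                    ~np.isfinite(v)
                ) else int(np.flatnonzero(~np.isfinite(d))[0])
                raise SimulationError(
                    f"non-finite state for driver {prof.driver_id} at step {bad}"
                )
            leader_id = chain[idx - 1].driver_id if idx > 0 else -1
            episodes.append(
                CarFollowingEpisode(
                    follower_id=prof.driver_id,
                    leader_id=leader_id,
                    dt=dt,
                    t=np.arange(n_steps) * dt,
                    v_l=prev_v.copy(),
                    v_f=v,
                    a_f=a,
                    d=d,
                )
            )
            truth_rows.append(
                {
                    "driver_id": prof.driver_id,
                    "is_aggressive": prof.is_aggressive,
                    "desired_time_gap": prof.desired_time_gap,
                }
            )
            prev_v = v
    truth = pd.DataFrame(truth_rows).sort_values("driver_id").reset_index(drop=True)
    return episodes, truth


def episodes_to_trajectory_frame(episodes: list[CarFollowingEpisode]) -> pd.DataFrame:
    """Re-emit episodes in the NGSIM CSV schema (metric units).

    Synthetic vehicle lengths are fixed at 4.5 m; positions are cumulative
    follower displacement. Lets the reader module ingest its own output.
    Vehicle ids are offset by +1 because NGSIM reserves 0 for "no leader".
    """
    veh_len = 4.5
    rows = []
    for ep in episodes:
        pos = np.concatenate([[0.0], np.cumsum(ep.v_f[:-1] * ep.dt)])
        frames = np.arange(len(ep))
        df = pd.DataFrame(
            {
                "Vehicle_ID": ep.follower_id + 1,
                "Frame_ID": frames,
                "Lane_ID": 1,
                "Preceding": ep.leader_id + 1 if ep.leader_id >= 0 else 0,
                "Local_Y": pos,
                "v_Vel": ep.v_f,
                "v_Acc": ep.a_f,
                "Space_Headway": ep.d + veh_len,
                "v_length": veh_len,
            }
        )
        rows.append(df)
    return pd.concat(rows, ignore_index=True)
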