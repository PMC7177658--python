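"""Collision surrogate measures for car-following episodes.

The central statistic is the Average Crash Risk (ACR): the time average of
a per-step Crash Risk (CR), which is itself derived from the Difference of
Space distance and Stopping distance (DSS).

DSS(t) = (v_l(t)^2 - v_f(t)^2) / (2 mu g) + d(t) - tau v_f(t)      [m]

measures the signed margin between the spacing available to the follower
and the spacing it needs to come to a stop, assuming both vehicles brake
at the friction-limited rate mu*g, plus a reaction-time allowance tau*v_f.
The reaction time tau switches with the follower's instantaneous
acceleration: 1.5 s while accelerating, 0.7 s while decelerating or idling.

A positive DSS means the follower can stop in time; Crash Risk is then 0.
A non-positive DSS signals rear-end risk and CR = |DSS| / v_f, a time
deficit in seconds. ACR is the mean of the CR samples over the episode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_io import CarFollowingEpisode

__all__ = [
    "RiskParameters",
    "RiskSeries",
    "compute_dss",
    "select_tau",
    "compute_cr",
    "compute_acr",
    "risk_table",
]


@dataclass(frozen=True)
class RiskParameters:
    """Physical constants of the stopping-distance model.

    mu : road-tyre friction coefficient (dimensionless), default 0.7.
    g : gravitational acceleration, m/s^2.
    tau_accel : driver reaction time while accelerating, s.
    tau_decel : reaction time while decelerating or idling, s.
    dt : sampling interval of the trajectory, s.
    """

    mu: float = 0.7
    g: float = 9.8
    tau_accel: float = 1.5
    tau_decel: float = 0.7
    dt: float = 0.1

    def __post_init__(self) -> None:
        for name in ("mu", "g", "tau_accel", "tau_decel", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_accel < self.tau_decel:
            raise ValueError("tau_accel must be >= tau_decel")


@dataclass
class RiskSeries:
    """Per-step DSS and CR plus the scalar ACR for one episode."""

    follower_id: int
    leader_id: int
    dss: np.ndarray  # m, signed
    cr: np.ndarray  # s, >= 0
    acr: float  # s
    duration: float  # s, T = N * dt

    @property
    def frac_steps_dss_negative(self) -> float:
        return float(np.mean(self.dss <= 0.0))


def _validate(v_l, v_f, d) -> None:
    if np.any(np.asarray(v_l) < 0) or np.any(np.asarray(v_f) < 0):
        raise ValueError("speeds must be non-negative")
    if np.any(np.asarray(d) < 0):
        raise ValueError("gap must be non-negative")


def compute_dss(v_l, v_f, d, tau, params: RiskParameters = RiskParameters()):
    """Difference of Space distance and Stopping distance, in metres.

    Accepts scalars or arrays (broadcast); ``tau`` may be per-step.
    """
    v_l = np.asarray(v_l, dtype=float)
    v_f = np.asarray(v_f, dtype=float)
    d = np.asarray(d, dtype=float)
    _validate(v_l, v_f, d)
    out = (v_l**2 - v_f**2) / (2.0 * params.mu * params.g) + d - np.asarray(tau) * v_f
    return out if out.ndim else float(out)


def select_tau(a_f, params: RiskParameters = RiskParameters()):
    """Reaction time by the follower's instantaneous acceleration sign.

    Strictly positive acceleration selects ``tau_accel``; deceleration and
    idling (a_f <= 0) select ``tau_decel``.
    """
    a_f = np.asarray(a_f, dtype=float)
    if not np.all(np.isfinite(a_f)):
        raise ValueError("acceleration must be finite")
    out = np.where(a_f > 0.0, params.tau_accel, params.tau_decel)
    return out if out.ndim else float(out)


def compute_cr(dss, v_f):
    """Crash Risk in seconds: |DSS|/v_f where DSS <= 0, else 0.

    A stationary follower (v_f = 0) with non-positive DSS is assigned
    CR = 0: it cannot close the gap itself.
    """
    dss = np.asarray(dss, dtype=float)
    v_f = np.asarray(v_f, dtype=float)
    if np.any(v_f < 0):
        raise ValueError("speeds must be non-negative")
    dss_b, v_b = np.broadcast_arrays(dss, v_f)
    with np.errstate(divide="ignore", invalid="ignore"):
        risky = (dss_b <= 0.0) & (v_b > 0.0)
        out = np.where(risky, np.abs(dss_b) / np.where(v_b > 0, v_b, 1.0), 0.0)
    return out if out.ndim else float(out)


def compute_acr(
    episode: CarFollowingEpisode, params: RiskParameters = RiskParameters()
) -> RiskSeries:
    """Full risk series and Average Crash Risk for one episode.

    ACR = (sum_i CR_i * dt) / T with T = N * dt, i.e. the arithmetic mean
    of the CR samples; this keeps ACR invariant to episode length for a
    stationary risk level.
    """
    if len(episode.v_f) == 0:
        raise ValueError("episode series must be non-empty")
    tau = select_tau(episode.a_f, params)
    dss = compute_dss(episode.v_l, episode.v_f, episode.d, tau, params)
    cr = compute_cr(dss, episode.v_f)
    n = len(cr)
    acr = float(np.sum(cr) * episode.dt / (n * episode.dt))
    return RiskSeries(
        follower_id=episode.follower_id,
        leader_id=episode.leader_id,
        dss=np.asarray(dss),
        cr=np.asarray(cr),
        acr=acr,
        duration=n * episode.dt,
    )


def risk_table(episodes, params: RiskParameters = RiskParameters()):
    """Per-driver risk summary as a DataFrame.

    Columns: follower_id, leader_id, duration_s, acr, frac_steps_dss_negative.
    """
    import pandas as pd

    rows = []
    for ep in episodes:
        rs = compute_acr(ep, params)
        rows.append(
            {
                "follower_id": rs.follower_id,
                "leader_id": rs.leader_id,
                "duration_s": rs.duration,
                "acr": rs.acr,
                "frac_steps_dss_negative": rs.frac_steps_dss_negative,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "follower_id",
            "leader_id",
            "duration_s",
            "acr",
            "frac_steps_dss_negative",
        ],
    )
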