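"""Admittance-based z-axis scan-force modulation.

The probe's vertical compliance is a virtual mass–spring–damper
admittance, H(s) = X(s)/F(s) = 1/(M s^2 + B s + K), that converts the
commanded contact force into a desired probe displacement. The damping
is chosen for a critically damped response (B = 2*sqrt(M*K)): the
fastest approach to the new indentation depth with no overshoot into
the patient.

The commanded force follows the image-quality verdict: while the
classifier reports low quality (V_svm = 0) the force is stepped up by
``delta_f`` each image tick; once frames are high quality the force
holds. The loop runs at the image rate (30 Hz by default); the inner
robot force-tracking loop is abstracted as ideal, so commanded and
applied force coincide within a tick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import QualityModel, classify


def critical_damping(mass: float, stiffness: float) -> float:
    """Damping coefficient giving a critically damped second-order
    response: B = 2*sqrt(M*K)."""
    if mass <= 0 or stiffness <= 0:
        raise ValueError(
            f"mass and stiffness must be positive, got M={mass}, K={stiffness}"
        )
    return 2.0 * math.sqrt(mass * stiffness)


@dataclass(frozen=True)
class AdmittanceParams:
    """Virtual mass (kg), damping (N·s/m) and stiffness (N/m) of the
    z-axis admittance model. Defaults: M = 5.625 kg, K = 50 N/m, with
    B set to the critical value 2*sqrt(M*K) ≈ 33.54 N·s/m."""

    mass: float = 5.625
    damping: float = critical_damping(5.625, 50.0)
    stiffness: float = 50.0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if self.damping < 0:
            raise ValueError(f"damping must be non-negative, got {self.damping}")
        if self.stiffness <= 0:
            raise ValueError(f"stiffness must be positive, got {self.stiffness}")

    @classmethod
    def critically_damped(cls, mass: float = 5.625, stiffness: float = 50.0) -> "AdmittanceParams":
        return cls(mass=mass, damping=critical_damping(mass, stiffness), stiffness=stiffness)


@dataclass(frozen=True)
class ForcePolicy:
    """Force-update policy: increment per low-quality tick and the
    scanning range limits (defaults mirror the 1–20 N sweep with
    0.25 N increments)."""

    delta_f: float = 0.25
    f_min: float = 1.0
    f_max: float = 20.0

    def __post_init__(self) -> None:
        if self.delta_f <= 0:
            raise ValueError(f"delta_f must be positive, got {self.delta_f}")
        if self.f_min > self.f_max:
            raise ValueError(f"f_min must not exceed f_max, got {self.f_min} > {self.f_max}")


def update_force(force: float, v_svm: int, policy: ForcePolicy) -> float:
    """Next commanded force: F + delta_f * (1 - V_svm), capped at f_max.

    A high-quality verdict (V_svm = 1) holds the force constant; a
    low-quality one steps it up by the increment.
    """
    if v_svm not in (0, 1):
        raise ValueError(f"v_svm must be 0 or 1, got {v_svm}")
    return min(force + policy.delta_f * (1 - v_svm), policy.f_max)


@dataclass(frozen=True)
class ScanState:
    """Continuous state of the admittance model at one instant."""

    t: float = 0.0
    force: float = 0.0
    depth: float = 0.0
    velocity: float = 0.0


def admittance_step(
    state: ScanState,
    f_applied: float,
    params: AdmittanceParams,
    dt: float,
) -> ScanState:
    """Advance M*x'' + B*x' + K*x = F by one Heun (explicit
    trapezoidal) step.

    Second-order accurate: at the 30 Hz image-loop rate the discretized
    step response tracks the closed-form critically damped solution to
    well under 1% of the steady-state displacement.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")

    def _accel(x: float, v: float) -> float:
        return (f_applied - params.damping * v - params.stiffness * x) / params.mass

    x0, v0 = state.depth, state.velocity
    a0 = _accel(x0, v0)
    x1, v1 = x0 + dt * v0, v0 + dt * a0
    a1 = _accel(x1, v1)
    x = x0 + dt * (v0 + v1) / 2.0
    v = v0 + dt * (a0 + a1) / 2.0
    return ScanState(t=state.t + dt, force=f_applied, depth=x, velocity=v)


def critically_damped_response(
    force: float, params: AdmittanceParams, t: np.ndarray | float
) -> np.ndarray | float:
    """Closed-form unit-step displacement of the critically damped
    admittance: x(t) = (F/K) * (1 - (1 + w*t) * exp(-w*t)), w = sqrt(K/M)."""
    w = math.sqrt(params.stiffness / params.mass)
    t = np.asarray(t, dtype=np.float64)
    return (force / params.stiffness) * (1.0 - (1.0 + w * t) * np.exp(-w * t))


@dataclass
class ScanTrace:
    """Per-tick record of a simulated scan.

    Columns: tick, t_s, force_N, depth_m, correlation, f_c, f_n, v_svm.
    ``converged`` means the verdict was high quality for
    ``convergence_window`` consecutive ticks.
    """

    records: list[dict] = field(default_factory=list)
    rate_hz: float = 30.0
    converged: bool = False
    converged_tick: int | None = None

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["tick", "t_s", "force_N", "depth_m", "correlation", "f_c", "f_n", "v_svm"],
        )

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(path, index=False)


def simulate_scan(
    model: QualityModel,
    phantom,
    params: AdmittanceParams | None = None,
    policy: ForcePolicy | None = None,
    rate_hz: float = 30.0,
    max_ticks: int = 600,
    seed: int = 0,
    convergence_window: int = 10,
    stop_on_convergence: bool = True,
) -> ScanTrace:
    """Closed-loop scan simulation at the image rate.

    Each tick: the phantom renders a frame for the current commanded
    force, the gated SVM produces V_svm, the admittance model advances
    one step with the commanded force applied (ideal inner force
    tracking), and the force-update rule sets the next command starting
    from ``policy.f_min``. The scan converges when V_svm has been 1 for
    ``convergence_window`` consecutive ticks; if ``max_ticks`` elapse
    first the trace is returned with ``converged=False``.
    """
    params = params or AdmittanceParams()
    policy = policy or ForcePolicy()
    if max_ticks < 1:
        raise ValueError("max_ticks must be >= 1")
    dt = 1.0 / rate_hz
    tick_seeds = np.random.SeedSequence(seed).generate_state(max_ticks)
    trace = ScanTrace(rate_hz=rate_hz)
    state = ScanState(force=policy.f_min)
    force = policy.f_min
    consecutive = 0
    for tick in range(max_ticks):
        frame = phantom.render_contact(force, seed=int(tick_seeds[tick]))
        v, fv = classify(model, frame, phantom.reference)
        state = admittance_step(state, force, params, dt)
        trace.records.append(
            {
                "tick": tick,
                "t_s": tick * dt,
                "force_N": force,
                "depth_m": state.depth,
                "correlation": fv.correlation_raw,
                "f_c": fv.compression,
                "f_n": fv.noise,
                "v_svm": v,
            }
        )
        consecutive = consecutive + 1 if v == 1 else 0
        if consecutive >= convergence_window and not trace.converged:
            trace.converged = True
            trace.converged_tick = tick
            if stop_on_convergence:
                break
        force = update_force(force, v, policy)
    return trace
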