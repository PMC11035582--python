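"""Core model definitions for the Allee-based distributed detection algorithm.

A microbial whole-cell sensor population is abstracted as two logical cell
states: L ("low", voting that the analyte is absent) and H ("high", voting
that it is present), with densities ``L(t)`` and ``H(t)`` and a conserved
total ``P = H + L`` (replication and death are neglected). Three reactions
drive the state:

* **Set** — an L cell switches to H at the rare-event detection rate
  ``sigma = sigma_A * A + sigma_err`` (true detections plus spurious ones);
* **Hold** — quorum-sensing-driven positive feedback: L cells switch to H at
  rate ``kappa * H^n / (H^n + K^n)``, a Hill function of the H density;
* **Reset** — H cells relax back to L at rate ``rho``.

Eliminating ``L = P - H`` gives a single autonomous ODE,

    dH/dt = sigma*(P - H) + kappa * H^n/(H^n + K^n) * (P - H) - rho*H,

whose cooperative (n > 1) Hill feedback produces an Allee effect: below a
critical H density the reset reaction wins and the population relaxes to a
low state; above it the feedback takes over and the population commits to a
high, self-maintaining state.

This module holds the shared parameter set, the Hill activation function in
an overflow-safe form, piecewise-constant analyte profiles, and the ODE
right-hand sides of the Allee algorithm and of three comparison algorithms
(set-reset, broadcasting, and quorum-sensing distributed amplification).

Units are fixed package-wide: densities in mL^-1, rates in h^-1, time in h.
Analyte concentrations are in arbitrary analyte units; ``sigma_A`` converts
them to a rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import NamedTuple, Optional, Union

import numpy as np
import yaml

__all__ = [
    "AlgorithmParameters",
    "PopulationState",
    "DistAmpState",
    "AnalyteProfile",
    "hill_activation",
    "effective_sigma",
    "allee_rhs",
    "set_reset_rhs",
    "broadcast_rhs",
    "dist_amp_rhs",
]

#: Keys accepted in a flat parameter config file.
PARAM_KEYS = ("kappa", "K", "n", "rho", "P", "sigma_A", "sigma_err", "kappa_bcast")
#: Keys that must be present when loading a config file.
REQUIRED_PARAM_KEYS = ("kappa", "K", "n", "rho", "P", "sigma_A", "sigma_err")


@dataclass(frozen=True)
class AlgorithmParameters:
    """Rate and population constants shared by all four algorithm models.

    Parameters
    ----------
    kappa : float
        Maximum rate of the quorum-sensing Hold reaction, h^-1.
    K : float
        Half-activation H density of the Hill feedback, mL^-1.
    n : float
        Hill coefficient (cooperativity); must exceed 1 for bistability.
    rho : float
        Reset rate constant (H -> L), h^-1.
    P : float
        Total (conserved) population density, mL^-1.
    sigma_A : float
        Per-analyte-unit detection rate coefficient, h^-1 per analyte unit.
    sigma_err : float
        Spurious (erroneous) detection rate, h^-1.
    kappa_bcast : float, optional
        Bimolecular relay rate of the broadcasting comparison algorithm,
        mL h^-1.  Defaults to ``kappa / P`` so that the relay saturates at
        the same per-capita rate ``kappa`` as the Hold reaction.
    """

    kappa: float = 35.0
    K: float = 8e7
    n: float = 4.0
    rho: float = 14.0
    P: float = 1.5e8
    sigma_A: float = 1.0
    sigma_err: float = 0.0
    kappa_bcast: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("K", "rho", "P"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        # kappa = 0 is admitted as the degenerate set-reset limit (no Hold
        # feedback); bistability then requires kappa > 0 and is reported
        # infeasible downstream.
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa!r}")
        if not self.n > 1:
            raise ValueError(f"Hill coefficient n must be > 1, got {self.n!r}")
        if self.sigma_A < 0 or self.sigma_err < 0:
            raise ValueError("sigma_A and sigma_err must be non-negative")
        if self.kappa_bcast is not None and self.kappa_bcast < 0:
            raise ValueError("kappa_bcast must be non-negative")

    @property
    def broadcast_rate(self) -> float:
        """Effective bimolecular relay rate (mL h^-1) for broadcasting."""
        return self.kappa / self.P if self.kappa_bcast is None else self.kappa_bcast

    def replace(self, **changes) -> "AlgorithmParameters":
        return replace(self, **changes)

    # -- flat-file config round trip ------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        if d["kappa_bcast"] is None:
            del d["kappa_bcast"]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AlgorithmParameters":
        unknown = set(d) - set(PARAM_KEYS)
        if unknown:
            raise KeyError(f"unknown parameter key(s): {sorted(unknown)}")
        missing = set(REQUIRED_PARAM_KEYS) - set(d)
        if missing:
            raise KeyError(f"missing parameter key(s): {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_file(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith(".json"):
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_file(cls, path) -> "AlgorithmParameters":
        path = str(path)
        with open(path) as fh:
            d = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"parameter file {path} did not contain a mapping")
        return cls.from_dict(d)


class PopulationState(NamedTuple):
    """Two-state population snapshot; ``L`` is always ``P - H``."""

    H: float
    L: float

    @classmethod
    def from_H(cls, H: float, p: AlgorithmParameters) -> "PopulationState":
        if not 0 <= H <= p.P:
            raise ValueError(f"H={H!r} outside [0, P={p.P!r}]")
        return cls(H=H, L=p.P - H)


class DistAmpState(NamedTuple):
    """State of the distributed-amplification model: H cells and reporter S."""

    H: float
    S: float


# ----------------------------------------------------------------------
# Analyte profiles
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class AnalyteProfile:
    """Piecewise-constant analyte concentration A(t).

    Three shapes are supported: ``constant`` (A = amplitude for all t),
    ``step_down`` (A = amplitude until ``t_step``, then baseline), and
    ``pulse`` (baseline except A = amplitude on ``[t_start, t_start+width[``).
    Evaluation is vectorised over time.
    """

    kind: str
    amplitude: float
    baseline: float = 0.0
    t_step: Optional[float] = None
    t_start: Optional[float] = None
    width: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "step_down", "pulse"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.amplitude < 0 or self.baseline < 0:
            raise ValueError("analyte amplitudes must be non-negative")
        if self.kind == "step_down":
            if self.t_step is None or self.t_step < 0:
                raise ValueError("step_down profile needs t_step >= 0")
        if self.kind == "pulse":
            if self.t_start is None or self.width is None:
                raise ValueError("pulse profile needs t_start and width")
            if self.t_start < 0 or self.width <= 0:
                raise ValueError("pulse needs t_start >= 0 and width > 0")

    @classmethod
    def constant(cls, amplitude: float) -> "AnalyteProfile":
        return cls(kind="constant", amplitude=amplitude)

    @classmethod
    def step_down(cls, amplitude: float, t_step: float,
                  baseline: float = 0.0) -> "AnalyteProfile":
        return cls(kind="step_down", amplitude=amplitude, t_step=t_step,
                   baseline=baseline)

    @classmethod
    def pulse(cls, amplitude: float, t_start: float, width: float,
              baseline: float = 0.0) -> "AnalyteProfile":
        return cls(kind="pulse", amplitude=amplitude, t_start=t_start,
                   width=width, baseline=baseline)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("analyte profiles are defined for t >= 0")
        if self.kind == "constant":
            out = np.full_like(t, self.amplitude)
        elif self.kind == "step_down":
            out = np.where(t < self.t_step, self.amplitude, self.baseline)
        else:  # pulse
            inside = (t >= self.t_start) & (t < self.t_start + self.width)
            out = np.where(inside, self.amplitude, self.baseline)
        return float(out) if out.ndim == 0 else out

    def breakpoints(self, t_end: float) -> list:
        """Discontinuity times in ]0, t_end[ (solver restart points)."""
        if self.kind == "constant":
            pts = []
        elif self.kind == "step_down":
            pts = [self.t_step]
        else:
            pts = [self.t_start, self.t_start + self.width]
        return sorted(t for t in pts if 0.0 < t < t_end)

    @property
    def end_time(self) -> float:
        """Time after which A(t) is constant at its tail value."""
        if self.kind == "constant":
            return 0.0
        if self.kind == "step_down":
            return float(self.t_step)
        return float(self.t_start + self.width)

    @property
    def tail_value(self) -> float:
        return self.amplitude if self.kind == "constant" else self.baseline


# ----------------------------------------------------------------------
# Kinetics
# ----------------------------------------------------------------------

def hill_activation(H, K: float, n: float):
    """Cooperative Hill activation H^n / (H^n + K^n), in [0, 1].

    Evaluated as ``1 / (1 + (K/H)^n)`` so that densities of order 1e8 never
    enter a large power; ``(K/H)^n`` overflowing for H << K cleanly floors
    the result at 0. Accepts scalars or arrays.
    """
    if K <= 0:
        raise ValueError(f"K must be > 0, got {K!r}")
    if n <= 1:
        raise ValueError(f"Hill coefficient n must be > 1, got {n!r}")
    H = np.asarray(H, dtype=float)
    if np.any(H < 0):
        raise ValueError("H density must be non-negative")
    out = np.zeros_like(H)
    pos = H > 0
    with np.errstate(over="ignore"):
        ratio = np.power(K / H[pos], n)
    out[pos] = 1.0 / (1.0 + ratio)
    return float(out) if out.ndim == 0 else out


def effective_sigma(A, p: AlgorithmParameters):
    """Rare-event detection rate sigma = sigma_A * A + sigma_err (h^-1)."""
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("analyte concentration must be non-negative")
    out = p.sigma_A * A + p.sigma_err
    return float(out) if out.ndim == 0 else out


def _check_H(H, P: float) -> None:
    if np.any(np.asarray(H) < -1e-9 * P) or np.any(np.asarray(H) > P * (1 + 1e-9)):
        raise ValueError(f"H={H!r} outside the physical range [0, P={P!r}]")


def _allee_rate(H, sigma, p: AlgorithmParameters):
    # unchecked kernel shared with the integrator; hill argument clipped so
    # solver micro-overshoots below 0 do not raise
    Hh = np.clip(H, 0.0, None)
    return (sigma * (p.P - H)
            + p.kappa * hill_activation(Hh, p.K, p.n) * (p.P - H)
            - p.rho * H)


def allee_rhs(H, sigma: float, p: AlgorithmParameters):
    """dH/dt of the Allee-based algorithm (mL^-1 h^-1).

    ``sigma*(P-H) + kappa*hill(H)*(P-H) - rho*H``: analyte/error-driven Set,
    quorum-feedback Hold, and Reset. Strictly increasing in ``sigma`` for
    H < P.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    _check_H(H, p.P)
    out = _allee_rate(np.asarray(H, dtype=float), sigma, p)
    return float(out) if np.ndim(out) == 0 else out


def set_reset_rhs(H, sigma: float, p: AlgorithmParameters):
    """dH/dt of the memoryless set-reset algorithm: sigma*(P-H) - rho*H.

    The unique steady state is ``P * sigma / (rho + sigma)``: the response is
    linear in the analyte at small sigma and has no threshold or memory.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    _check_H(H, p.P)
    H = np.asarray(H, dtype=float)
    out = sigma * (p.P - H) - p.rho * H
    return float(out) if out.ndim == 0 else out


def broadcast_rhs(H, sigma: float, p: AlgorithmParameters,
                  kappa_bcast: Optional[float] = None):
    """dH/dt of the broadcasting algorithm: sigma*(P-H) + kappa_b*H*(P-H).

    Mass-action relay with no reset: any positive sigma eventually converts
    the whole population, so the threshold sits at zero analyte.
    ``kappa_bcast`` (mL h^-1) defaults to ``p.broadcast_rate`` = kappa/P.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    _check_H(H, p.P)
    kb = p.broadcast_rate if kappa_bcast is None else kappa_bcast
    H = np.asarray(H, dtype=float)
    out = sigma * (p.P - H) + kb * H * (p.P - H)
    return float(out) if out.ndim == 0 else out


def dist_amp_rhs(state, sigma: float, p: AlgorithmParameters):
    """(dH/dt, dS/dt) of the quorum-sensing distributed-amplification model.

    H cells follow set-reset kinetics; every cell (L and H alike, totalling
    P) secretes the reporter S at the Hill-activated rate, and S decays at
    rho:

        dH/dt = sigma*(P - H) - rho*H
        dS/dt = kappa * hill(H) * P - rho*S
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    H, S = state
    _check_H(H, p.P)
    if S < 0:
        raise ValueError("reporter density S must be non-negative")
    dH = sigma * (p.P - H) - p.rho * H
    dS = p.kappa * hill_activation(max(H, 0.0), p.K, p.n) * p.P - p.rho * S
    return (float(dH), float(dS))


def dist_amp_steady_state(sigma: float, p: AlgorithmParameters) -> DistAmpState:
    """Closed-form fixed point of the distributed-amplification model."""
    H = p.P * sigma / (p.rho + sigma)
    S = (p.kappa / p.rho) * p.P * hill_activation(H, p.K, p.n)
    return DistAmpState(H=H, S=S)
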