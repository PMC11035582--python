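"""Hybrid stochastic-deterministic robustness experiments.

A real genetic circuit produces spurious L -> H transitions at a rate that
fluctuates in time (e.g. leaky repressor expression). This module models
that fluctuation as a stochastic birth-death process of an auxiliary noise
species — births at constant rate beta, per-copy deaths at rate gamma, so
the stationary copy number is Poisson with mean beta/gamma — simulated
exactly with the Gillespie algorithm. The resulting integer-valued path
drives the spurious detection rate sigma(t) = sigma_unit * count(t) of an
otherwise deterministic Allee-model simulation, integrated piecewise
between noise events.

The question the experiment answers: do stochastic excursions of the
spurious rate ever push the population over the commitment threshold
(a false positive), or does the Allee threshold absorb them?
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import AlgorithmParameters
from .equilibria import alpha_bounds
from .simulate import TrajectoryResult, integrate_segments

__all__ = [
    "NoiseTrajectory",
    "RobustnessReport",
    "simulate_birth_death",
    "hybrid_simulation",
    "robustness_ensemble",
    "false_positive_rate",
]


@dataclass(frozen=True)
class NoiseTrajectory:
    """Seeded birth-death sample path of the noise species copy number.

    ``event_times[0] = 0`` with ``counts[0]`` the initial copy number (0);
    each later entry records the time of a birth or death and the copy
    number immediately after it. The path is right-continuous and constant
    between events, and fully reproducible from (beta, gamma, t_end, seed).
    """

    event_times: np.ndarray
    counts: np.ndarray
    beta: float
    gamma: float
    seed: int
    t_end: float

    def count_at(self, t) -> np.ndarray:
        """Copy number at time(s) t (right-continuous step function)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        out = self.counts[np.clip(idx, 0, len(self.counts) - 1)]
        return int(out) if out.ndim == 0 else out

    def segments(self, t_end: Optional[float] = None) -> List[Tuple[float, float, int]]:
        """Constant-count intervals (t0, t1, count) covering [0, t_end]."""
        t_end = self.t_end if t_end is None else float(t_end)
        if t_end > self.t_end:
            raise ValueError(
                f"noise trajectory covers [0, {self.t_end}] < requested {t_end}")
        cuts = np.concatenate([self.event_times[self.event_times < t_end], [t_end]])
        return [(float(a), float(b), int(c))
                for a, b, c in zip(cuts[:-1], cuts[1:], self.counts) if b > a]

    def time_average(self) -> float:
        """Time-averaged copy number over [0, t_end]."""
        segs = self.segments()
        return sum((b - a) * c for a, b, c in segs) / self.t_end

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.event_times, "count": self.counts})

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# birth-death noise: beta={self.beta}, gamma={self.gamma}, "
                     f"seed={self.seed}, t_end={self.t_end}\n")
            self.to_dataframe().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, beta: float = np.nan, gamma: float = np.nan,
                 seed: int = -1, t_end: Optional[float] = None) -> "NoiseTrajectory":
        header = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for part in first.lstrip("# ").split(":")[-1].split(","):
                    k, v = part.split("=")
                    header[k.strip()] = float(v)
            df = pd.read_csv(fh if first.startswith("#") else path)
        return cls(event_times=df["t"].to_numpy(float),
                   counts=df["count"].to_numpy(int),
                   beta=header.get("beta", beta), gamma=header.get("gamma", gamma),
                   seed=int(header.get("seed", seed)),
                   t_end=float(header.get("t_end", t_end if t_end is not None
                                          else df["t"].iloc[-1])))


@dataclass(frozen=True)
class RobustnessReport:
    """Outcome of one hybrid run: did noise ever trip the detector?"""

    max_H: float
    fraction_time_low: float
    false_positive: bool
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {"max_H": self.max_H, "fraction_time_low": self.fraction_time_low,
                "false_positive": self.false_positive, "seed": self.seed}


def simulate_birth_death(beta: float, gamma: float, t_end: float,
                         seed: int) -> NoiseTrajectory:
    """Exact (Gillespie) simulation of births at beta, deaths at gamma*count.

    Starts from copy number 0; event times are drawn from the exponential
    next-reaction clock, so the sample path is statistically exact and
    bit-reproducible given the seed.
    """
    if beta < 0 or gamma <= 0 or t_end <= 0:
        raise ValueError("need beta >= 0, gamma > 0, t_end > 0")
    rng = np.random.default_rng(seed)
    t, count = 0.0, 0
    times, counts = [0.0], [0]
    while True:
        rate = beta + gamma * count
        if rate == 0.0:
            break
        t += rng.exponential(1.0 / rate)
        if t > t_end:
            break
        count += 1 if rng.random() < beta / rate else -1
        times.append(t)
        counts.append(count)
    return NoiseTrajectory(event_times=np.asarray(times),
                           counts=np.asarray(counts, dtype=int),
                           beta=beta, gamma=gamma, seed=int(seed),
                           t_end=float(t_end))


def hybrid_simulation(noise: NoiseTrajectory, p: AlgorithmParameters,
                      sigma_unit: float = 1.0,
                      t_end: Optional[float] = None,
                      H0: float = 0.0) -> Tuple[TrajectoryResult, RobustnessReport]:
    """Drive the deterministic Allee model with a stochastic rate path.

    sigma(t) = sigma_unit * count(t) is constant between noise events, so
    the ODE is integrated exactly piecewise with the solver restarted at
    every event. The report flags a false positive when H(t) ever reaches
    the committed fraction alpha_f * P.
    """
    if sigma_unit < 0:
        raise ValueError("sigma_unit must be non-negative")
    t_end = noise.t_end if t_end is None else float(t_end)
    segs = [(a, b, sigma_unit * c) for a, b, c in noise.segments(t_end)]
    traj = integrate_segments("allee", p, segs, [H0],
                              n_points=max(2001, 4 * len(segs)))
    _, alpha_f = alpha_bounds(p)
    threshold = alpha_f * p.P
    max_H = float(np.max(traj.H))
    dt = np.diff(traj.times)
    low = traj.H[:-1] < threshold
    frac_low = float(np.sum(dt[low]) / (traj.times[-1] - traj.times[0]))
    report = RobustnessReport(max_H=max_H, fraction_time_low=frac_low,
                              false_positive=bool(max_H >= threshold),
                              seed=noise.seed)
    return traj, report


def robustness_ensemble(p: AlgorithmParameters, beta: float = 0.5,
                        gamma: float = 2.0, n_runs: int = 20,
                        t_end: float = 100.0, base_seed: int = 0,
                        sigma_unit: float = 1.0) -> List[RobustnessReport]:
    """Independent seeded replicates of the hybrid robustness experiment.

    Run i uses seed ``base_seed + i``; with ``n_runs = 1`` this reproduces a
    single :func:`hybrid_simulation` at ``base_seed`` exactly.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    reports = []
    for i in range(n_runs):
        noise = simulate_birth_death(beta, gamma, t_end, seed=base_seed + i)
        _, rep = hybrid_simulation(noise, p, sigma_unit=sigma_unit, t_end=t_end)
        reports.append(rep)
    return reports


def false_positive_rate(reports: List[RobustnessReport]) -> float:
    """Fraction of ensemble runs that tripped the detector."""
    return sum(r.false_positive for r in reports) / len(reports)
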