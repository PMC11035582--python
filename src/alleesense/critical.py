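"""Critical rare-event rate sigma_c: bisection search and parameter sweeps.

sigma_c is the saddle-node value of the detection rate at which the low and
middle fixed points of the Allee ODE merge: below it the low "no detection"
state exists and spurious detections are absorbed; above it every
trajectory commits to the high "detected" state. There is no closed form;
sigma_c is located by bisection on the root count of the fixed-point
equation (three roots below, one above), exactly the transition a
saddle-node produces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .core import AlgorithmParameters
from .equilibria import (InfeasibleParametersError, feasibility_condition,
                         find_equilibria)

__all__ = [
    "CriticalRateResult",
    "SweepGrid",
    "sigma_utr",
    "find_sigma_c",
    "sweep_sigma_c",
]

#: Default bisection precision on sigma_c, h^-1 (bracket width at exit).
DEFAULT_PRECISION = 1e-3
MAX_BISECTIONS = 64


@dataclass(frozen=True)
class CriticalRateResult:
    """Result of the sigma_c bisection.

    ``bracket`` is the final (low, high) interval with three fixed points at
    the low end and one at the high end; ``terminated_by`` is ``precision``
    when the bracket narrowed below the request and ``tangency`` when a
    midpoint landed on the merged double root itself.
    """

    sigma_c: float
    bracket: tuple
    iterations: int
    terminated_by: str
    feasible: bool = True

    def to_dict(self) -> dict:
        return {
            "sigma_c": self.sigma_c,
            "bracket": list(self.bracket),
            "iterations": self.iterations,
            "terminated_by": self.terminated_by,
            "feasible": self.feasible,
        }


def _n_roots(sigma: float, p: AlgorithmParameters) -> int:
    return find_equilibria(sigma, p).n_roots


def sigma_utr(p: AlgorithmParameters, max_doublings: int = 60) -> float:
    """Upper end of the initial bisection interval.

    Doubles upward from rho until the fixed-point equation has a single
    root, returning the smallest power-of-two multiple of rho found. Raises
    :class:`InfeasibleParametersError` when bistability is impossible (then
    sigma = 0 already has a single root and no transition exists).
    """
    if not feasibility_condition(p).satisfied:
        raise InfeasibleParametersError(
            "bistability condition fails; no three-root regime exists")
    s = p.rho
    for _ in range(max_doublings):
        if _n_roots(s, p) == 1:
            return s
        s *= 2.0
    raise RuntimeError("no single-root sigma found while doubling from rho")


def find_sigma_c(p: AlgorithmParameters,
                 precision: float = DEFAULT_PRECISION,
                 max_iter: int = MAX_BISECTIONS) -> CriticalRateResult:
    """Bisect the root-count transition to locate sigma_c.

    Starting from [0, sigma_utr], each midpoint's fixed points are counted:
    three roots move the lower bound up, one root moves the upper bound
    down, and a midpoint whose root set contains a merged (tangent) double
    root is the saddle-node itself and is returned immediately. Terminates
    when the bracket is narrower than ``precision``.
    """
    if precision <= 0:
        raise ValueError("precision must be positive")
    hi = sigma_utr(p)
    lo = 0.0
    if _n_roots(lo, p) < 3:
        raise InfeasibleParametersError("no bistable regime at sigma = 0")
    it = 0
    while hi - lo > precision and it < max_iter:
        mid = 0.5 * (lo + hi)
        eq = find_equilibria(mid, p)
        if eq.has_tangency:
            return CriticalRateResult(sigma_c=mid, bracket=(lo, hi),
                                      iterations=it + 1,
                                      terminated_by="tangency")
        if eq.n_roots >= 3:
            lo = mid
        else:
            hi = mid
        it += 1
    return CriticalRateResult(sigma_c=0.5 * (lo + hi), bracket=(lo, hi),
                              iterations=it, terminated_by="precision")


# ----------------------------------------------------------------------
# Parameter sweeps (heat-map grids)
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SweepGrid:
    """sigma_c over a (kappa, rho) grid at fixed P; 0 marks infeasible cells.

    ``matrix[i, j]`` holds sigma_c for ``kappa_values[i]``,
    ``rho_values[j]``. Cells where the bistability condition fails carry 0,
    the convention used for heat-map rendering.
    """

    kappa_values: np.ndarray
    rho_values: np.ndarray
    P: float
    precision: float
    matrix: np.ndarray

    def to_csv(self, path, sidecar: Optional[str] = None) -> None:
        """Write the grid as CSV (kappa rows, rho columns) + JSON sidecar."""
        with open(path, "w") as fh:
            fh.write(f"# sigma_c grid, P={self.P:g} mL^-1, "
                     f"precision={self.precision:g} h^-1\n")
            fh.write("kappa\\rho," +
                     ",".join(f"{r:.10g}" for r in self.rho_values) + "\n")
            for k, row in zip(self.kappa_values, self.matrix):
                fh.write(f"{k:.10g}," + ",".join(f"{v:.10g}" for v in row) + "\n")
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump({"P": self.P, "precision": self.precision,
                           "kappa_values": list(map(float, self.kappa_values)),
                           "rho_values": list(map(float, self.rho_values))},
                          fh, indent=2)

    def plot(self, path) -> None:
        """Render the grid as a log-log heat map (file output only)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 4))
        mesh = ax.pcolormesh(self.rho_values, self.kappa_values, self.matrix,
                             shading="nearest")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel(r"reset rate $\rho$ (h$^{-1}$)")
        ax.set_ylabel(r"hold rate $\kappa$ (h$^{-1}$)")
        fig.colorbar(mesh, ax=ax, label=r"$\sigma_c$ (h$^{-1}$)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def default_sweep_axes(n: int = 64, lo: float = 1.0,
                       hi: float = 100.0) -> np.ndarray:
    """Log-spaced rate axis used by default for heat-map grids, h^-1."""
    return np.geomspace(lo, hi, n)


def sweep_sigma_c(kappa_values: Sequence[float],
                  rho_values: Sequence[float],
                  p_base: AlgorithmParameters,
                  precision: float = DEFAULT_PRECISION) -> SweepGrid:
    """sigma_c for every (kappa, rho) pair at the base parameters' P.

    Cells are computed independently in a fixed row-major order, so grids
    are bit-reproducible. Infeasible cells (bistability condition violated)
    are encoded as sigma_c = 0.
    """
    kv = np.asarray(list(kappa_values), dtype=float)
    rv = np.asarray(list(rho_values), dtype=float)
    if kv.size == 0 or rv.size == 0 or np.any(kv <= 0) or np.any(rv <= 0):
        raise ValueError("kappa and rho grids must be non-empty and positive")
    mat = np.zeros((kv.size, rv.size))
    for i, k in enumerate(kv):
        for j, r in enumerate(rv):
            p = p_base.replace(kappa=float(k), rho=float(r))
            try:
                mat[i, j] = find_sigma_c(p, precision=precision).sigma_c
            except InfeasibleParametersError:
                mat[i, j] = 0.0
    return SweepGrid(kappa_values=kv, rho_values=rv, P=p_base.P,
                     precision=precision, matrix=mat)
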