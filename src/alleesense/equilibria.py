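"""Equilibria and stability of the Allee detection ODE.

The fixed points of ``dH/dt = sigma*(P-H) + kappa*hill(H)*(P-H) - rho*H``
on [0, P] organise the algorithm's behaviour: below the critical rate the
system is bistable (low stable root = "no detection", middle unstable root =
the tipping density, high stable root = "detected"); above it only the high
root survives. For integer Hill coefficients the fixed-point equation is
cleared to a degree-(n+1) polynomial and solved exactly via companion-matrix
roots; non-integer coefficients fall back to a sign-change scan with
bisection refinement.

The feasibility check asks whether the analyte-free net birth rate
``g(H) = kappa*hill(H)*(P-H) - rho*H`` becomes positive anywhere on [0, P]
— the condition under which bistability (and hence detection with memory)
exists at all. When it holds, the sigma = 0 root structure defines two
fractions of the population: ``alpha_i`` (the unstable tipping fraction —
start above it and the population commits) and ``alpha_f`` (the committed
level — every "detected" steady state lies at or above it).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.optimize import brentq, minimize_scalar

from .core import AlgorithmParameters, _allee_rate, hill_activation

__all__ = [
    "EquilibriumSet",
    "FeasibilityReport",
    "InfeasibleParametersError",
    "find_equilibria",
    "feasibility_condition",
    "alpha_bounds",
    "critical_point",
]

#: Relative root-deduplication tolerance; a pair of roots closer than this
#: (in units of P) is reported once and labelled "tangent".
DEDUP_RTOL = 1e-6
#: Relative imaginary-part cutoff for accepting a polynomial root as real.
IMAG_RTOL = 1e-6
#: Offset (in units of P) used for derivative-free stability probing.
STAB_EPS = 1e-5


class InfeasibleParametersError(ValueError):
    """Raised when bistability is impossible (analyte-free net birth never positive)."""


@dataclass(frozen=True)
class EquilibriumSet:
    """All fixed points of the Allee ODE in [0, P] at one value of sigma.

    ``stability`` labels each sorted root ``stable`` / ``unstable`` /
    ``tangent`` (a merged double root at the saddle-node). ``H_c_sigma`` is
    the middle unstable root when the system is bistable — the tipping
    density separating the two basins — and is absent otherwise. ``H_c_0``
    is populated at sigma = 0 only: the second-lowest non-negative root,
    i.e. the analyte-free tipping density alpha_i * P.
    """

    sigma: float
    roots: List[float]
    stability: List[str]
    H_c_sigma: Optional[float] = None
    H_c_0: Optional[float] = None

    @property
    def n_roots(self) -> int:
        return len(self.roots)

    @property
    def has_tangency(self) -> bool:
        return "tangent" in self.stability

    def stable_roots(self) -> List[float]:
        return [r for r, s in zip(self.roots, self.stability) if s == "stable"]

    def to_dict(self) -> dict:
        return {
            "sigma": self.sigma,
            "roots": list(self.roots),
            "stability": list(self.stability),
            "H_c_sigma": self.H_c_sigma,
            "H_c_0": self.H_c_0,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass(frozen=True)
class FeasibilityReport:
    """Outcome of the bistability feasibility check.

    ``g_max`` is the certified maximum of the analyte-free net birth rate
    g(H) over [0, P]; the parameters support bistable detection iff it is
    positive. ``alpha_i``/``alpha_f`` (tipping and committed population
    fractions) are derived from the sigma = 0 roots and present only when
    the condition holds.
    """

    g_max: float
    H_at_max: float
    satisfied: bool
    alpha_i: Optional[float] = None
    alpha_f: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "g_max": self.g_max,
            "H_at_max": self.H_at_max,
            "satisfied": self.satisfied,
            "alpha_i": self.alpha_i,
            "alpha_f": self.alpha_f,
        }


# ----------------------------------------------------------------------
# Root finding
# ----------------------------------------------------------------------

def _polynomial_roots_scaled(sigma: float, p: AlgorithmParameters) -> np.ndarray:
    """Real roots in [0, 1] of the fixed-point equation in x = H/P.

    Clearing the Hill denominator turns dH/dt = 0 into
    ``(sigma*(1-x) - rho*x) * (x^n + k^n) + kappa * x^n * (1-x) = 0`` with
    k = K/P — a degree-(n+1) polynomial whose coefficients are O(rates),
    well-conditioned regardless of the 1e8 density scale.
    """
    n = int(round(p.n))
    k = p.K / p.P
    lin = np.array([sigma, -(sigma + p.rho)])          # sigma - (sigma+rho) x
    xn = np.zeros(n + 1)
    xn[n] = 1.0
    poly = npoly.polyadd(npoly.polymul(lin, npoly.polyadd(xn, [k ** n])),
                         p.kappa * npoly.polymul(xn, [1.0, -1.0]))
    roots = npoly.polyroots(poly)
    scale = max(1.0, float(np.max(np.abs(roots)))) if len(roots) else 1.0
    real = roots[np.abs(roots.imag) < IMAG_RTOL * scale].real
    real = real[(real > -1e-9) & (real < 1.0 + 1e-9)]
    # polish with Newton on the cleared polynomial for certified residuals
    dpoly = npoly.polyder(poly)
    for _ in range(3):
        fv = npoly.polyval(real, poly)
        dv = npoly.polyval(real, dpoly)
        step = np.where(np.abs(dv) > 0, fv / np.where(dv == 0, 1.0, dv), 0.0)
        real = np.clip(real - step, 0.0, 1.0)
    return np.sort(np.clip(real, 0.0, 1.0))


def _scan_roots_scaled(sigma: float, p: AlgorithmParameters,
                       n_grid: int = 8192) -> np.ndarray:
    """Sign-change bracketing fallback for non-integer Hill coefficients."""
    x = np.linspace(0.0, 1.0, n_grid + 1)
    f = _allee_rate(x * p.P, sigma, p)
    roots = []
    if f[0] == 0.0:
        roots.append(0.0)
    sign = np.sign(f)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        r = brentq(lambda xx: _allee_rate(xx * p.P, sigma, p),
                   x[i], x[i + 1], xtol=1e-14)
        roots.append(r)
    for i in np.nonzero(sign[1:] == 0)[0]:
        roots.append(x[i + 1])
    return np.sort(np.asarray(roots))


def _dedup(roots: np.ndarray) -> List[tuple]:
    """Merge near-coincident roots; return (root, multiplicity) pairs."""
    out: List[tuple] = []
    for r in roots:
        if out and abs(r - out[-1][0]) < DEDUP_RTOL:
            merged = ((out[-1][0] * out[-1][1] + r) / (out[-1][1] + 1),
                      out[-1][1] + 1)
            out[-1] = merged
        else:
            out.append((r, 1))
    return out


def find_equilibria(sigma: float, p: AlgorithmParameters) -> EquilibriumSet:
    """Find and classify every fixed point of the Allee ODE in [0, P].

    Roots are certified by their residual |dH/dt| and classified by the sign
    of dH/dt just below and just above (offset ``STAB_EPS * P``): flow
    toward the root on both sides is ``stable``, away is ``unstable``, the
    same sign on both sides marks a merged double root (``tangent``).

    Raises
    ------
    ValueError
        If sigma is negative, or if a computed root fails the residual
        certification check.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if float(p.n).is_integer():
        xs = _polynomial_roots_scaled(sigma, p)
    else:
        xs = _scan_roots_scaled(sigma, p)

    rate_scale = (sigma + p.kappa + p.rho) * p.P
    pairs = _dedup(xs)
    roots, labels = [], []
    for x, mult in pairs:
        H = x * p.P
        resid = abs(_allee_rate(H, sigma, p))
        if resid > 1e-6 * rate_scale:
            raise ValueError(
                f"root certification failed at H={H:.6g} (residual {resid:.3g})")
        lo = x - STAB_EPS
        hi = x + STAB_EPS
        s_below = np.sign(_allee_rate(lo * p.P, sigma, p)) if lo >= 0.0 else 1.0
        s_above = np.sign(_allee_rate(hi * p.P, sigma, p)) if hi <= 1.0 else -1.0
        if mult > 1 or s_below == s_above:
            label = "tangent"
        elif s_below > 0 and s_above < 0:
            label = "stable"
        else:
            label = "unstable"
        roots.append(H)
        labels.append(label)

    H_c_sigma = roots[1] if len(roots) == 3 else None
    H_c_0 = None
    if sigma == 0:
        nonneg = [r for r in roots if r >= 0]
        if len(nonneg) >= 2:
            H_c_0 = sorted(nonneg)[1]
    return EquilibriumSet(sigma=float(sigma), roots=roots, stability=labels,
                          H_c_sigma=H_c_sigma, H_c_0=H_c_0)


# ----------------------------------------------------------------------
# Feasibility and the alpha fractions
# ----------------------------------------------------------------------

def _g(H, p: AlgorithmParameters):
    """Analyte-free net birth rate g(H) = kappa*hill(H)*(P-H) - rho*H."""
    H = np.asarray(H, dtype=float)
    return p.kappa * hill_activation(H, p.K, p.n) * (p.P - H) - p.rho * H


def feasibility_condition(p: AlgorithmParameters,
                          n_grid: int = 4096) -> FeasibilityReport:
    """Check whether the parameters admit bistable detection.

    Locates the maximum of g(H) on [0, P] by a coarse grid followed by
    bounded local refinement. The condition ``g_max > 0`` is exactly the
    hypothesis under which the Allee algorithm has a positive critical rate
    and a memory threshold.
    """
    H = np.linspace(0.0, p.P, n_grid + 1)
    g = _g(H, p)
    i = int(np.argmax(g))
    lo = H[max(i - 1, 0)]
    hi = H[min(i + 1, n_grid)]
    if hi > lo:
        res = minimize_scalar(lambda h: -_g(h, p), bounds=(lo, hi),
                              method="bounded",
                              options={"xatol": 1e-9 * p.P})
        H_at_max, g_max = float(res.x), float(-res.fun)
        if g[i] > g_max:       # refinement may not beat the grid at corners
            H_at_max, g_max = float(H[i]), float(g[i])
    else:
        H_at_max, g_max = float(H[i]), float(g[i])
    satisfied = g_max > 0
    alpha_i = alpha_f = None
    if satisfied:
        eq0 = find_equilibria(0.0, p)
        if len(eq0.roots) >= 3:
            alpha_i = eq0.roots[1] / p.P
            alpha_f = eq0.roots[2] / p.P
        else:
            # positive g_max with fewer than 3 roots only happens within
            # numerical tolerance of tangency; treat as infeasible
            satisfied = False
    return FeasibilityReport(g_max=g_max, H_at_max=H_at_max,
                             satisfied=satisfied, alpha_i=alpha_i,
                             alpha_f=alpha_f)


def alpha_bounds(p: AlgorithmParameters) -> tuple:
    """(alpha_i, alpha_f): tipping and committed population fractions.

    ``alpha_i * P`` is the unstable analyte-free root (start above it and
    the population self-amplifies even with no analyte), ``alpha_f * P``
    the high stable analyte-free root (the floor of every committed state).
    """
    rep = feasibility_condition(p)
    if not rep.satisfied:
        raise InfeasibleParametersError(
            f"bistability condition fails (g_max={rep.g_max:.4g} <= 0)")
    return rep.alpha_i, rep.alpha_f


def critical_point(sigma: float, p: AlgorithmParameters) -> Optional[float]:
    """Tipping density H_c at this sigma (middle unstable root), or None.

    Present exactly when the system is bistable at ``sigma``; trajectories
    started below it relax to the low root, above it to the high root.
    """
    eq = find_equilibria(sigma, p)
    return eq.H_c_sigma
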