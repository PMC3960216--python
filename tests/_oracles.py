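"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: resistances come from
numerical quadrature, fractional release from the classical eigenfunction
series for a homogeneous sphere, and the sampling arithmetic from an explicit
step-by-step mass-balance simulation of the withdraw/replenish cycle.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad


def quadrature_resistance(r_in: float, r_out: float, D: float) -> float:
    """Spherical-shell resistance by numerical quadrature of dr/(4 pi D r^2)."""
    if r_in == r_out:
        return 0.0
    val, _ = quad(lambda r: 1.0 / (4.0 * math.pi * D * r * r), r_in, r_out,
                  epsabs=0.0, epsrel=1e-12)
    return val


def crank_release(tau, n_terms: int = 400) -> np.ndarray:
    """Fractional release from a uniformly loaded homogeneous sphere with a
    surface sink, in dimensionless time tau = D t / a^2.

    Uses the eigenfunction series 1 - (6/pi^2) sum n^-2 exp(-n^2 pi^2 tau) for
    tau >= 1e-3 and the short-time expansion 6 sqrt(tau/pi) - 3 tau below it
    (where the complementary-error-function corrections are < 1e-16), so the
    oracle is accurate at all times despite the series' slow convergence near
    zero.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    out = np.zeros_like(tau)
    small = (tau > 0) & (tau < 1e-3)
    big = tau >= 1e-3
    if np.any(big):
        n = np.arange(1, n_terms + 1)[:, None]
        s = np.sum(np.exp(-(n**2) * math.pi**2 * tau[big][None, :]) / n**2, axis=0)
        out[big] = 1.0 - 6.0 / math.pi**2 * s
    if np.any(small):
        ts = tau[small]
        out[small] = 6.0 * np.sqrt(ts / math.pi) - 3.0 * ts
    return out


def brute_force_cumulative(concentrations, V_total: float, V_aliquot: float) -> np.ndarray:
    """Cumulative released mass by explicit withdraw/replenish simulation.

    Walks the assay forward: at each time point the vessel holds C_n * V_total
    of drug; the newly released increment since the previous point is whatever
    mass is needed to reach that state after the previous aliquot removed
    C_{n-1} * V_aliquot.  Cumulative release is the running sum of increments.
    """
    conc = np.asarray(concentrations, dtype=float)
    cum = np.zeros_like(conc)
    in_vessel_prev = 0.0  # drug mass in the vessel just after last replenish
    total = 0.0
    for i, c in enumerate(conc):
        released_now = c * V_total - in_vessel_prev
        total += released_now
        cum[i] = total
        in_vessel_prev = c * V_total - c * V_aliquot  # aliquot removed, buffer added
    return cum


def explicit_loss_ledger(release_mass: float, content: float, loss_mass: float) -> float:
    """Percent release after coating loss, by explicit mass ledger."""
    remaining_content = content - loss_mass
    return 100.0 * release_mass / remaining_content
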