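"""Steady-state series-resistance model of a coated sphere.

A drug-loaded polymer particle (core, radius ``r2``) carrying a
polyelectrolyte-multilayer (PEM) shell of thickness ``t`` is treated as two
concentric spherical conduction regions.  At steady state the radial mass flow
through a shell bounded by radii ``r_in < r_out`` with diffusivity ``D`` sees
a resistance

    R = (r_out - r_in) / (4 pi D r_in r_out)

(the mass-transfer analogue of conduction through a spherical wall).  The
resistance from an interior reference radius ``r1`` to the particle surface is
``R_a``; the PEM shell adds ``R_b`` in series, with the partition coefficient
``K`` folded into an effective shell diffusivity ``K*D2``.  The mass-transfer
rate under a concentration difference ``C_i - C_0`` is ``(C_i - C_0)/R_T``
with ``R_T = R_a + R_b``.

The retardation ratio -- the coated-to-uncoated mass-transfer-rate ratio under
equal driving force -- is then

    M_T / M_0 = R_a / (R_a + R_b)

It equals 1 exactly when the shell is absent (``t = 0``) or when the core
offers no resistance (``D1 = 0``, the capsule limit), and tends to 1 as the
particle grows at fixed shell thickness: the physical statement that a PEM
barrier retards release on small particles but not large ones.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "LENGTH_UNITS",
    "as_length",
    "CompositeSphere",
    "ResistanceBreakdown",
    "DrivingForce",
    "shell_resistance",
    "total_resistance",
    "mass_transfer_rate",
    "retardation_ratio",
    "size_sweep",
    "save_sweep",
]

#: Length units accepted by :func:`as_length`, as multiples of a micrometre.
LENGTH_UNITS: dict[str, float] = {
    "nm": 1e-3,
    "um": 1.0,
    "µm": 1.0,
    "micron": 1.0,
    "mm": 1e3,
}


def as_length(value: "float | tuple[float, str]", unit: str = "um") -> float:
    """Normalize a length to ``unit`` (default micrometres).

    ``value`` is either a bare float (already in ``unit``) or a
    ``(magnitude, unit)`` tuple, e.g. ``(100, "nm")``.
    """
    target = LENGTH_UNITS.get(unit)
    if target is None:
        raise ValueError(f"unknown length unit {unit!r}")
    if isinstance(value, tuple):
        mag, u = value
        factor = LENGTH_UNITS.get(u)
        if factor is None:
            raise ValueError(f"unknown length unit {u!r}")
        return float(mag) * factor / target
    return float(value)


@dataclass(frozen=True)
class CompositeSphere:
    """Geometry and transport parameters of a PEM-coated particle.

    All lengths must be in one consistent unit (use :meth:`from_units` to
    normalize mixed-unit input); diffusivities in (length unit)^2 per time
    unit.

    Parameters
    ----------
    r1:
        Interior reference (sampling) radius, ``0 < r1 < r2``.  The
        retardation ratio depends on this choice, so it is always explicit.
    r2:
        Particle (core) outer radius.
    t:
        PEM shell thickness, ``>= 0``.
    D1:
        Core diffusivity, ``>= 0`` (0 means a resistance-free core: a capsule).
    D2:
        Shell diffusivity, ``> 0``.
    K:
        Shell/core partition coefficient (dimensionless, ``> 0``); enters only
        as the effective shell diffusivity ``K*D2``.
    """

    r1: float
    r2: float
    t: float
    D1: float
    D2: float
    K: float = 1.0

    def __post_init__(self) -> None:
        if not self.r1 > 0:
            raise ValueError(f"r1 must be positive, got {self.r1}")
        if not self.r2 > self.r1:
            raise ValueError(f"require 0 < r1 < r2, got r1={self.r1}, r2={self.r2}")
        if self.t < 0:
            raise ValueError(f"shell thickness t must be >= 0, got {self.t}")
        if self.D1 < 0:
            raise ValueError(f"D1 must be >= 0, got {self.D1}")
        if not self.D2 > 0:
            raise ValueError(f"D2 must be positive, got {self.D2}")
        if not self.K > 0:
            raise ValueError(f"K must be positive, got {self.K}")

    @property
    def r3(self) -> float:
        """Shell outer radius, exactly ``r2 + t``."""
        return self.r2 + self.t

    @classmethod
    def from_units(
        cls,
        r1: "float | tuple[float, str]",
        r2: "float | tuple[float, str]",
        t: "float | tuple[float, str]",
        D1: float,
        D2: float,
        K: float = 1.0,
        unit: str = "um",
    ) -> "CompositeSphere":
        """Build a sphere from possibly mixed-unit lengths, normalized to ``unit``."""
        return cls(
            r1=as_length(r1, unit),
            r2=as_length(r2, unit),
            t=as_length(t, unit),
            D1=D1,
            D2=D2,
            K=K,
        )

    def replace(self, **changes) -> "CompositeSphere":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ResistanceBreakdown:
    """Series resistances of the composite sphere.

    ``R_a`` spans r1 -> r2 (core region), ``R_b`` spans r2 -> r3 (shell);
    ``R_T = R_a + R_b``.  ``core_blocked`` flags the D1 = 0 capsule limit,
    where ``R_a`` is reported as infinite.
    """

    R_a: float
    R_b: float
    R_T: float
    core_blocked: bool = False

    def __post_init__(self) -> None:
        if self.R_a < 0 or self.R_b < 0:
            raise ValueError("resistances must be non-negative")


@dataclass(frozen=True)
class DrivingForce:
    """Inner/outer concentration pair; only the difference is consumed."""

    C_i: float
    C_0: float

    @property
    def delta(self) -> float:
        return self.C_i - self.C_0


def shell_resistance(r_in: float, r_out: float, D: float) -> float:
    """Steady-state diffusional resistance of the spherical shell r_in -> r_out.

    Returns ``(r_out - r_in) / (4 pi D r_in r_out)``, equivalently the
    integral of ``dr / (4 pi D r^2)`` across the shell; zero for a
    zero-thickness shell.
    """
    if not r_in > 0:
        raise ValueError(f"r_in must be positive, got {r_in}")
    if r_out < r_in:
        raise ValueError(f"r_out must be >= r_in, got r_out={r_out} < r_in={r_in}")
    if not D > 0:
        raise ValueError(f"D must be positive, got {D}")
    return (r_out - r_in) / (4.0 * math.pi * D * r_in * r_out)


def total_resistance(sphere: CompositeSphere) -> ResistanceBreakdown:
    """Series resistance breakdown ``R_a + R_b`` for a coated particle.

    ``R_a`` uses the core diffusivity ``D1``; ``R_b`` the effective shell
    diffusivity ``K*D2``.  ``D1 = 0`` yields an infinite ``R_a`` with the
    ``core_blocked`` flag set (capsule limit) rather than an error.
    """
    if sphere.D1 == 0:
        R_a = math.inf
        blocked = True
    else:
        R_a = shell_resistance(sphere.r1, sphere.r2, sphere.D1)
        blocked = False
    if sphere.t == 0:
        R_b = 0.0
    else:
        R_b = shell_resistance(sphere.r2, sphere.r3, sphere.K * sphere.D2)
    return ResistanceBreakdown(R_a=R_a, R_b=R_b, R_T=R_a + R_b, core_blocked=blocked)


def mass_transfer_rate(df: DrivingForce, rb: ResistanceBreakdown) -> float:
    """Quasi-steady mass-transfer rate ``(C_i - C_0) / R_T``.

    Infinite total resistance transports nothing (returns 0); zero total
    resistance is a degenerate geometry and raises.
    """
    if rb.R_T == 0:
        raise ValueError("R_T = 0: degenerate geometry (r1 = r2 = r3)")
    if math.isinf(rb.R_T):
        return 0.0
    return df.delta / rb.R_T


def retardation_ratio(sphere: CompositeSphere) -> float:
    """Coated/uncoated mass-transfer-rate ratio ``M_T/M_0 = R_a/(R_a + R_b)``.

    Valid at early times, while the driving concentration difference is the
    same for bare and coated particles.  Always in ``(0, 1]``; exactly 1 when
    ``t = 0`` (no coating) or ``D1 = 0`` (no core resistance -- a capsule),
    handled as exact special cases.
    """
    if sphere.t == 0 or sphere.D1 == 0:
        return 1.0
    rb = total_resistance(sphere)
    return rb.R_a / (rb.R_a + rb.R_b)


def size_sweep(
    base: CompositeSphere,
    r2_values: Sequence[float] | Iterable[float],
    r1_fraction: float = 0.5,
) -> pd.DataFrame:
    """Retardation ratio as a function of particle radius at fixed coating.

    For each candidate core radius the interior reference radius is set to
    ``r1_fraction * r2`` while ``t``, ``D1``, ``D2`` and ``K`` are held at the
    base sphere's values.  Returns a DataFrame with columns ``r2`` and
    ``ratio`` sorted by ``r2``; the ratio is non-decreasing in ``r2`` and
    approaches 1 for large particles.
    """
    if not 0 < r1_fraction < 1:
        raise ValueError(f"r1_fraction must be in (0, 1), got {r1_fraction}")
    rows = []
    for r2 in r2_values:
        sphere = base.replace(r1=r1_fraction * r2, r2=r2)
        rows.append((r2, retardation_ratio(sphere)))
    table = pd.DataFrame(rows, columns=["r2", "ratio"])
    return table.sort_values("r2", ignore_index=True)


def save_sweep(
    table: pd.DataFrame,
    path: "str | Path",
    base: CompositeSphere,
    r1_fraction: float,
) -> Path:
    """Write a sweep table as CSV plus a JSON sidecar of the held parameters.

    The sidecar (``<path>.json``) records ``r1_fraction``, ``t``, ``D1``,
    ``D2`` and ``K`` so every ratio is reproducible.
    """
    path = Path(path)
    table.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "r1_fraction": r1_fraction,
                "t": base.t,
                "D1": base.D1,
                "D2": base.D2,
                "K": base.K,
            },
            indent=2,
        )
    )
    return sidecar
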