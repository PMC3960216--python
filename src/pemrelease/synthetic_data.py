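"""Seeded generators for study-shaped synthetic data.

Produces the three kinds of measurement the analysis consumes, with the
statistical structure the real study exhibits, so every downstream stage can
be exercised without experimental data:

* triplicate cumulative-release curves -- a burst fraction at t = 0
  (default 0.40, the immediate release of surface-segregated protein from
  uncoated nanoparticles) composed with a diffusion-limited tail from the
  two-layer transient solver, plus multiplicative measurement noise truncated
  to keep each replicate monotone non-decreasing;
* layer-by-layer coating-loss runs -- per-step (adsorption/wash) drug-loss
  masses whose expected per-layer sequence decays geometrically with layer
  number, whose expected grand total matches the condition's published total
  (pair x build-up pH), and whose layer-1 wash/adsorption ordering carries the
  pH signature (wash > adsorption at pH 4, the reverse at pH 9/unadjusted);
* zeta-potential sequences -- sign-alternating per-layer values with
  pair-specific magnitude (about 40 mV for PAH/PSS, 15 mV for PLL/DES,
  bare particle at -25 mV).

Determinism contract: the same config (including seed) yields byte-identical
arrays.  Independent substreams are derived per product so generating one kind
of data never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .bookkeeping import CoatingRun, CoatingStep
from .core_model import CompositeSphere
from .transient_solver import InitialCondition, ReleaseCurve, SolverGrid, solve_release

__all__ = [
    "TABLE_TOTAL_LOSS",
    "ZETA_LEVELS",
    "BARE_ZETA_MV",
    "SyntheticConfig",
    "default_geometry",
    "generate_release_curves",
    "generate_coating_run",
    "generate_zeta_sequence",
    "write_release_dataset",
]

#: Published total drug-loss percentages by (pair, build-up pH); pH None = unadjusted.
TABLE_TOTAL_LOSS: dict[tuple[str, Optional[int]], float] = {
    ("PAH/PSS", None): 8.0,
    ("PLL/DES", None): 5.4,
    ("PAH/PSS", 4): 6.8,
    ("PLL/DES", 4): 3.7,
    ("PAH/PSS", 9): 5.0,
    ("PLL/DES", 9): 3.7,
}

#: Typical |zeta| (mV) reached during build-up, by polyelectrolyte pair.
ZETA_LEVELS: dict[str, float] = {"PAH/PSS": 40.0, "PLL/DES": 15.0}

#: zeta-potential of the bare (uncoated) particle, mV.
BARE_ZETA_MV: float = -25.0

# layer-1 adsorption/wash split of the expected loss, by build-up pH regime.
# pH 9 / unadjusted: protein stays bound to the polycation, so washing removes
# little (2.4% -> 0.2% pattern).  pH 4: protein is positively charged and
# desorbs during washing (1.4% -> 1.9% pattern).
_ADS_SHARE = {"high": 2.4 / (2.4 + 0.2), "low": 1.4 / (1.4 + 1.9)}


def default_geometry() -> CompositeSphere:
    """Nanoparticle study geometry: 330 nm particle with a 4-layer PEM.

    Radii in micrometres, diffusivities in um^2/h.  The core diffusivity puts
    the diffusion time r2^2/D1 near 27 h (days-scale release); the shell is a
    20 nm PEM whose permeability is 1% of the core's, the regime where the
    coating dominates the resistance on a nanoparticle.  r1 is the
    mass-centroid radius of a uniformly loaded core, 0.75 * r2.
    """
    r2 = 0.165
    return CompositeSphere(r1=0.75 * r2, r2=r2, t=0.020, D1=1e-3, D2=1e-5, K=1.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything a generator run depends on, seed included.

    ``times`` is the measurement schedule in hours (default: a typical
    release-study schedule out to one week).  ``loss_scale`` multiplies every
    coating-loss mass (0 gives an all-zero run); ``loss_decay`` is the
    geometric per-layer decay of the expected loss; ``loss_shape`` the Gamma
    shape of each step's draw (larger = tighter).  ``content_basis_ug`` is the
    drug content the coating-loss percentages refer to.
    """

    seed: int = 0
    burst_fraction: float = 0.40
    noise_sd: float = 0.03
    n_replicates: int = 3
    pair: str = "PAH/PSS"
    buildup_ph: Optional[int] = None
    n_layers: int = 4
    loss_scale: float = 1.0
    loss_decay: float = 0.55
    loss_shape: float = 80.0
    zeta_spread_mv: float = 3.0
    content_basis_ug: float = 100.0
    geometry: CompositeSphere = field(default_factory=default_geometry)
    times: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0, 96.0, 168.0)
    grid: SolverGrid = field(default_factory=lambda: SolverGrid(
        n_core=48, n_shell=12, dt=0.25, t_end=168.0))

    def __post_init__(self) -> None:
        if not 0.0 <= self.burst_fraction < 1.0:
            raise ValueError("burst_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.loss_scale < 0:
            raise ValueError("loss_scale must be >= 0")
        if not 0 < self.loss_decay <= 1:
            raise ValueError("loss_decay must be in (0, 1]")
        if self.pair not in ZETA_LEVELS:
            raise ValueError(f"unknown polyelectrolyte pair {self.pair!r}")

    def replace(self, **changes) -> "SyntheticConfig":
        return dataclasses.replace(self, **changes)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible substream for one generator product."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))

    def to_dict(self) -> dict:
        g = self.geometry
        return {
            "seed": self.seed,
            "burst_fraction": self.burst_fraction,
            "noise_sd": self.noise_sd,
            "n_replicates": self.n_replicates,
            "pair": self.pair,
            "buildup_ph": self.buildup_ph,
            "n_layers": self.n_layers,
            "loss_scale": self.loss_scale,
            "loss_decay": self.loss_decay,
            "loss_shape": self.loss_shape,
            "zeta_spread_mv": self.zeta_spread_mv,
            "content_basis_ug": self.content_basis_ug,
            "geometry": {"r1": g.r1, "r2": g.r2, "t": g.t,
                         "D1": g.D1, "D2": g.D2, "K": g.K},
            "times": list(self.times),
            "grid": {"n_core": self.grid.n_core, "n_shell": self.grid.n_shell,
                     "dt": self.grid.dt, "t_end": self.grid.t_end,
                     "scheme": self.grid.scheme},
        }


_STREAM_RELEASE = 1
_STREAM_COATING = 2
_STREAM_ZETA = 3


def generate_release_curves(cfg: SyntheticConfig, coated: bool) -> ReleaseCurve:
    """Replicated cumulative-release curves for a coated or bare particle.

    The noise-free mean curve is ``burst + (1 - burst) * F(t)`` where F is the
    solver's diffusion-limited fraction; the bare particle uses the same core
    with the shell removed.  Each replicate multiplies the mean by independent
    lognormal factors exp(sigma * z - sigma^2/2) (unit mean) and is then
    clipped to be monotone non-decreasing, emulating an assay whose
    coefficient of variation scales with signal.
    """
    sphere = cfg.geometry if coated else cfg.geometry.replace(t=0.0)
    base = solve_release(sphere, cfg.grid, "uniform_core",
                         output_times=np.asarray(cfg.times))
    mean = cfg.burst_fraction + (1.0 - cfg.burst_fraction) * base.fraction_released
    rng = cfg.rng(_STREAM_RELEASE + (0 if coated else 10))
    sigma = cfg.noise_sd
    if sigma == 0:
        reps = np.tile(mean, (cfg.n_replicates, 1))
    else:
        z = rng.standard_normal((cfg.n_replicates, mean.size))
        reps = mean * np.exp(sigma * z - 0.5 * sigma * sigma)
        reps = np.maximum.accumulate(reps, axis=1)
    return ReleaseCurve(times=np.asarray(cfg.times, dtype=float),
                        fraction_released=reps.mean(axis=0),
                        replicates=reps)


def _condition_label(cfg: SyntheticConfig) -> str:
    ph = "NA" if cfg.buildup_ph is None else str(cfg.buildup_ph)
    return f"{cfg.pair} @ {ph}"


def generate_coating_run(cfg: SyntheticConfig) -> CoatingRun:
    """One layer-by-layer coating run with per-step drug-loss masses.

    Expected per-layer loss decays geometrically (rate ``loss_decay``); the
    expected grand total equals the published total for the configured
    (pair, pH) condition scaled by ``loss_scale``.  Step losses are Gamma
    distributed (non-negative, right-skewed).  The layer-1 adsorption/wash
    ordering is enforced to carry the pH signature: wash > adsorption below
    the protein's isoelectric point (pH 4), the reverse at pH 9/unadjusted.
    """
    target_pct = TABLE_TOTAL_LOSS.get((cfg.pair, cfg.buildup_ph))
    if target_pct is None:
        raise ValueError(f"no published total for condition {(cfg.pair, cfg.buildup_ph)}")
    total_mass = cfg.loss_scale * target_pct / 100.0 * cfg.content_basis_ug
    regime = "low" if cfg.buildup_ph == 4 else "high"
    ads_share = _ADS_SHARE[regime]

    weights = cfg.loss_decay ** np.arange(cfg.n_layers)
    layer_means = total_mass * weights / weights.sum()
    rng = cfg.rng(_STREAM_COATING)
    steps: list[CoatingStep] = []
    for i, lm in enumerate(layer_means):
        means = (lm * ads_share, lm * (1.0 - ads_share))
        draws = []
        for m in means:
            if m == 0:
                draws.append(0.0)
            else:
                draws.append(float(rng.gamma(cfg.loss_shape, m / cfg.loss_shape)))
        ads, wash = draws
        if i == 0 and total_mass > 0:
            # enforce the pH-dependent first-layer signature without changing
            # the layer total
            if regime == "low" and wash <= ads:
                ads, wash = wash, ads
            elif regime == "high" and ads <= wash:
                ads, wash = wash, ads
        steps.append(CoatingStep("adsorption", i + 1, ads))
        steps.append(CoatingStep("wash", i + 1, wash))
    return CoatingRun(condition=_condition_label(cfg), steps=tuple(steps),
                      content_basis=cfg.content_basis_ug)


def generate_zeta_sequence(cfg: SyntheticConfig, include_bare: bool = False) -> np.ndarray:
    """Per-layer zeta-potential values (mV) with strict sign alternation.

    The bare particle is negative; each polycation layer flips the sign
    positive and each polyanion layer back to negative, so layer l carries
    sign (-1)^(l+1).  Magnitudes are pair-specific (|zeta| around 40 mV for
    PAH/PSS, 15 mV for PLL/DES) with Gaussian spread; spread 0 gives the
    exact alternating +/- level sequence.
    """
    level = ZETA_LEVELS[cfg.pair]
    rng = cfg.rng(_STREAM_ZETA)
    mags = np.abs(level + cfg.zeta_spread_mv * rng.standard_normal(cfg.n_layers))
    signs = np.where(np.arange(1, cfg.n_layers + 1) % 2 == 1, 1.0, -1.0)
    seq = signs * mags
    if include_bare:
        seq = np.concatenate([[BARE_ZETA_MV], seq])
    return seq


def write_release_dataset(cfg: SyntheticConfig, coated: bool, out_csv: "str | Path") -> Path:
    """Emit a release-curve CSV plus a JSON manifest with the full config."""
    curve = generate_release_curves(cfg, coated)
    out_csv = Path(out_csv)
    curve.to_csv(out_csv)
    manifest = out_csv.with_suffix(out_csv.suffix + ".manifest.json")
    manifest.write_text(json.dumps({"config": cfg.to_dict(), "coated": coated}, indent=2))
    return manifest
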