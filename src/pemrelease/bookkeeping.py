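"""Measurement arithmetic for release assays and coating-loss accounting.

Covers the bookkeeping around an in-vitro release study on coated particles:

* cumulative mass released under aliquot-and-replenish sampling (each
  withdrawn aliquot removes drug mass that later time points must credit
  back);
* percent release relative to drug content, drug loading (w/w) and
  encapsulation efficiency;
* per-step drug-loss accounting during layer-by-layer coating, including the
  correction that re-expresses a release percentage on the post-loss content
  basis -- the arithmetic that shows how unreported drug loss can masquerade
  as release retardation (a 20 ug release from 100 ug content reads 20%;
  lose 15 ug during coating and a 5 ug release from the remaining 85 ug reads
  5.9%, with no barrier involved).

Percentages are kept at full precision internally; ``render_percent`` applies
one-decimal, round-half-away-from-zero formatting only at the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SamplingProtocol",
    "DrugContent",
    "CoatingStep",
    "CoatingRun",
    "LossSummary",
    "cumulative_mass_released",
    "percent_release",
    "drug_loading",
    "encapsulation_efficiency",
    "loss_adjusted_release",
    "loss_summary",
    "mean_total_loss",
    "render_percent",
    "read_coating_runs",
    "summarize_coating_runs",
]


@dataclass(frozen=True)
class SamplingProtocol:
    """Aliquot-and-replenish sampling schedule of a release assay.

    At each scheduled time an aliquot ``V_aliquot`` of supernatant is
    withdrawn for quantitation and replaced with the same volume of fresh
    (drug-free) buffer, restoring ``V_total``.
    """

    V_total: float
    V_aliquot: float
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0 < self.V_aliquot <= self.V_total:
            raise ValueError(
                f"require 0 < V_aliquot <= V_total, got "
                f"V_aliquot={self.V_aliquot}, V_total={self.V_total}"
            )
        ts = tuple(float(t) for t in self.times)
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("sampling times must be strictly increasing")
        object.__setattr__(self, "times", ts)


@dataclass(frozen=True)
class DrugContent:
    """Measured and intended drug masses of a particle batch.

    ``content_exceeds_theoretical`` flags (without failing) the physically
    suspect case of measured content above the intended load.
    """

    mass_drug: float
    mass_particles: float
    theoretical_mass: float

    def __post_init__(self) -> None:
        for name in ("mass_drug", "mass_particles", "theoretical_mass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def content_exceeds_theoretical(self) -> bool:
        return self.theoretical_mass > 0 and self.mass_drug > self.theoretical_mass


StepKind = Literal["adsorption", "wash"]


@dataclass(frozen=True)
class CoatingStep:
    kind: StepKind
    layer: int
    loss_mass: float

    def __post_init__(self) -> None:
        if self.kind not in ("adsorption", "wash"):
            raise ValueError(f"step kind must be 'adsorption' or 'wash', got {self.kind!r}")
        if self.layer < 1:
            raise ValueError("layer index must be >= 1")
        if self.loss_mass < 0:
            raise ValueError("loss mass must be >= 0")


@dataclass(frozen=True)
class CoatingRun:
    """Ordered per-step drug losses for one coating condition.

    ``condition`` labels the polyelectrolyte pair and build-up pH (e.g.
    ``"PAH/PSS @ pH 9"``); ``content_basis`` is the drug content against which
    loss percentages are computed.
    """

    condition: str
    steps: tuple[CoatingStep, ...]
    content_basis: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))
        layers = [s.layer for s in self.steps]
        if any(b < a for a, b in zip(layers, layers[1:])):
            raise ValueError("layer indices must be non-decreasing")
        if not self.content_basis > 0:
            raise ValueError("content_basis must be positive")


@dataclass(frozen=True)
class LossSummary:
    """Per-step and aggregate loss percentages for one coating run."""

    condition: str
    per_step: pd.DataFrame  # columns: kind, layer, loss_mass, percent
    per_layer: pd.DataFrame  # columns: layer, percent
    total_percent: float
    wash_exceeds_adsorption: bool  # layer-1 signature: wash loss > adsorption loss


def cumulative_mass_released(
    concentrations: Sequence[float],
    protocol: SamplingProtocol,
    correct_for_sampling: bool = True,
) -> np.ndarray:
    """Cumulative drug mass released at each sampling time.

    With the aliquot correction (default), the cumulative mass at time n is

        cum_n = V_total * C_n + V_aliquot * sum_{i<n} C_i

    i.e. the mass currently in the vessel plus every mass previously carried
    off in aliquots.  With ``correct_for_sampling=False`` only the
    in-vessel term ``V_total * C_n`` is reported (the naive reading some
    release studies use; provided for sensitivity checks).
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.ndim != 1 or conc.size != len(protocol.times):
        raise ValueError("need exactly one concentration per scheduled time")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    in_vessel = protocol.V_total * conc
    if not correct_for_sampling:
        return in_vessel
    removed = protocol.V_aliquot * np.concatenate([[0.0], np.cumsum(conc)[:-1]])
    return in_vessel + removed


def percent_release(mass_released: float, content: float) -> float:
    """Release as a percentage of drug content: ``100 * mass / content``."""
    if content <= 0:
        raise ValueError("drug content must be positive for a percentage")
    if mass_released < 0:
        raise ValueError("released mass must be >= 0")
    return 100.0 * mass_released / content


def drug_loading(content: DrugContent) -> float:
    """Drug loading, percent w/w: ``100 * mass_drug / mass_particles``."""
    if content.mass_particles <= 0:
        raise ValueError("particle mass must be positive")
    return 100.0 * content.mass_drug / content.mass_particles


def encapsulation_efficiency(content: DrugContent) -> float:
    """Encapsulation efficiency: actual vs intended drug mass, percent."""
    if content.theoretical_mass <= 0:
        raise ValueError("theoretical drug mass must be positive")
    return 100.0 * content.mass_drug / content.theoretical_mass


def loss_adjusted_release(
    mass_released: float,
    original_content: float,
    loss_percent: float,
) -> float:
    """Percent release computed on the post-loss content basis.

    After losing ``loss_percent`` of the original content during coating, a
    measured content-based release percentage refers to the reduced content
    ``original_content * (1 - loss/100)``.  This is the arithmetic by which a
    smaller absolute release can read as a much smaller percentage without any
    coating barrier: losing 15% of a 100 ug load leaves 85 ug, so a 5 ug
    release registers as 5.9% against the 20% a 20 ug release from the
    intact load would have shown.
    """
    if loss_percent >= 100:
        raise ValueError("loss_percent must be < 100")
    if loss_percent < 0:
        raise ValueError("loss_percent must be >= 0")
    post_loss = original_content * (1.0 - loss_percent / 100.0)
    return percent_release(mass_released, post_loss)


def loss_summary(run: CoatingRun) -> LossSummary:
    """Per-step percents, per-layer totals and grand total for a coating run.

    Also flags whether the layer-1 wash loss exceeds its adsorption loss --
    the build-up-pH signature: below the protein's isoelectric point the
    positively charged protein desorbs during washing (wash > adsorption),
    above it the protein stays bound to the polycation (wash < adsorption).
    """
    rows = [
        {
            "kind": s.kind,
            "layer": s.layer,
            "loss_mass": s.loss_mass,
            "percent": 100.0 * s.loss_mass / run.content_basis,
        }
        for s in run.steps
    ]
    per_step = pd.DataFrame(rows, columns=["kind", "layer", "loss_mass", "percent"])
    if per_step.empty:
        per_layer = pd.DataFrame(columns=["layer", "percent"])
        return LossSummary(run.condition, per_step, per_layer, 0.0, False)
    per_layer = (
        per_step.groupby("layer", as_index=False)["percent"].sum()
    )
    total = float(per_step["percent"].sum())
    first = per_step[per_step["layer"] == per_step["layer"].min()]
    ads = first[first["kind"] == "adsorption"]["percent"]
    wash = first[first["kind"] == "wash"]["percent"]
    flag = bool(len(ads) and len(wash) and wash.iloc[0] > ads.iloc[0])
    return LossSummary(run.condition, per_step, per_layer, total, flag)


def mean_total_loss(totals: Sequence[float]) -> float:
    """Arithmetic mean of per-condition total-loss percentages."""
    totals = list(totals)
    if not totals:
        raise ValueError("need at least one total-loss value")
    return float(np.mean(totals))


def render_percent(value: float, decimals: int = 1) -> str:
    """Format a percentage with round-half-away-from-zero at the given precision.

    Used only at the reporting layer; all arithmetic stays at full precision.
    """
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def read_coating_runs(path: "str | Path", content_basis: float = 100.0) -> list[CoatingRun]:
    """Read coating runs from CSV with columns condition,layer,step,loss_mass."""
    df = pd.read_csv(path)
    required = {"condition", "layer", "step", "loss_mass"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coating CSV missing columns: {sorted(missing)}")
    runs = []
    for cond, grp in df.groupby("condition", sort=False):
        steps = tuple(
            CoatingStep(kind=row.step, layer=int(row.layer), loss_mass=float(row.loss_mass))
            for row in grp.itertuples()
        )
        runs.append(CoatingRun(condition=str(cond), steps=steps, content_basis=content_basis))
    return runs


def summarize_coating_runs(runs: Iterable[CoatingRun]) -> pd.DataFrame:
    """Pair-by-pH grid of total loss percentages (the printed-table shape).

    Conditions are parsed as ``"<pair> @ <pH label>"``; unparsable labels go
    in a single row under their full name.
    """
    rows = []
    for run in runs:
        summary = loss_summary(run)
        if " @ " in run.condition:
            pair, ph = run.condition.split(" @ ", 1)
        else:
            pair, ph = run.condition, ""
        rows.append({"pair": pair, "pH": ph, "total_percent": summary.total_percent})
    df = pd.DataFrame(rows)
    return df.pivot_table(index="pH", columns="pair", values="total_percent", aggfunc="mean")
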