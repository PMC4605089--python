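"""Synthetic HTL replicate generator.

Emulates the statistical structure of a duplicate-run bench campaign: for
each treatment condition, per-fraction yields are drawn from independent
Gaussians (truncated at zero) around the condition means, converted to masses
on a fixed dry-feed basis, and assembled into validated experiment records.
Gas masses and compositions are attached only for conditions run in the
closed ("2-L") reactor; vented-reactor conditions have them absent, like the
real campaign.

The default configuration IS the reference study design: the four bundled
treatment conditions, duplicate runs, biocrude-yield SDs of 0.4 / 0.2 / 0.1 /
0.2 percentage points (printed for the two non-catalytic conditions; the
midpoint 0.2 assumed for the catalytic ones), feed HHV SD 0.53.  A draw whose
product-mass closure exceeds 105 % of the feed is rejected and redrawn, which
keeps every generated record valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import datasets
from .experiment_model import (
    ACPProfile,
    ExperimentRecord,
    FeedstockComposition,
    FractionProperties,
    GasProfile,
    HTLCondition,
    ProductSlate,
    ValidationError,
)

__all__ = [
    "ConditionSpec",
    "SyntheticConfig",
    "default_config",
    "generate_experiments",
    "recover_parameters",
]

#: fractions drawn per condition, in fixed order
_FRACTIONS = ("biocrude", "solids", "gas", "nvr")


@dataclass
class ConditionSpec:
    """Mean/SD structure of one treatment condition (% of dry feed)."""

    condition_id: str
    condition: HTLCondition
    mean_yields_pct: dict[str, float]          # keys: biocrude, solids, gas, nvr
    sd_yields_pct: dict[str, float]
    crude_hhv_mean: float
    crude_hhv_sd: float = 0.0
    crude_composition: tuple[float, float, float, float] = (75.0, 12.0, 1.5, 0.05)
    #                   (C, H, N, ash) mass %; drawn without noise
    gas_fractions: Optional[dict[str, float]] = None
    acp: Optional[ACPProfile] = None

    def __post_init__(self) -> None:
        for k, m in self.mean_yields_pct.items():
            if not (0.0 <= m <= 100.0):
                raise ValidationError(f"{self.condition_id}: mean {k} = {m} "
                                      "outside [0, 100]")
        for k, s in self.sd_yields_pct.items():
            if s < 0:
                raise ValidationError(f"{self.condition_id}: SD {k} negative")


@dataclass
class SyntheticConfig:
    """Full design of a synthetic campaign."""

    conditions: list[ConditionSpec]
    n_replicates: int = 2
    feed_dry_mass_g: float = 40.0
    feedstock: FeedstockComposition = field(
        default_factory=datasets.yeast_feedstock)
    feed_hhv_sd: float = 0.53
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if self.feed_dry_mass_g <= 0:
            raise ValidationError("feed_dry_mass_g must be > 0")
        if self.feed_hhv_sd < 0:
            raise ValidationError("feed_hhv_sd must be >= 0")


#: default per-condition biocrude-yield SDs (percentage points)
_DEFAULT_BIOCRUDE_SD = {
    "noncat-300": 0.4,
    "cat-300": 0.2,
    "noncat-cosolvent-240": 0.1,
    "cat-cosolvent-240": 0.2,
}
#: assumed SD for fractions whose replicate spread is not reported
_DEFAULT_OTHER_SD = 0.2


def default_config(seed: int = 0) -> SyntheticConfig:
    """The reference four-condition duplicate design."""
    conditions = []
    for rec in datasets.reference_experiments():
        yields = datasets.REFERENCE_YIELDS_PCT[rec.condition_id]
        means = {k: (0.0 if v is None else v) for k, v in yields.items()}
        sds = {k: _DEFAULT_OTHER_SD for k in _FRACTIONS}
        sds["biocrude"] = _DEFAULT_BIOCRUDE_SD[rec.condition_id]
        if yields["gas"] is None:
            sds["gas"] = 0.0  # vented reactor: no gas to draw
        conditions.append(ConditionSpec(
            condition_id=rec.condition_id,
            condition=rec.condition,
            mean_yields_pct=means,
            sd_yields_pct=sds,
            crude_hhv_mean=rec.crude.hhv_mj_per_kg,
            crude_hhv_sd=0.0,
            crude_composition=(rec.crude.carbon_pct, rec.crude.hydrogen_pct,
                               rec.crude.nitrogen_pct, rec.crude.ash_pct),
            gas_fractions=(dict(rec.gas.fractions) if rec.gas else None),
            acp=rec.acp,
        ))
    return SyntheticConfig(conditions=conditions, random_seed=seed)


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated at zero (rejection; falls back to 0 mean/sd 0)."""
    if sd == 0.0:
        return max(0.0, mean)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0.0:
            return x
    return 0.0  # mean << 0: truncation collapses to the boundary


def generate_experiments(config: SyntheticConfig,
                         seed: int | None = None) -> list[ExperimentRecord]:
    """Generate one synthetic campaign (``n_replicates`` records per condition).

    Deterministic for a fixed seed.  Replicate records share the condition id
    of their treatment; the gas block is attached only for closed-reactor
    ("2-L") conditions.
    """
    rng = np.random.default_rng(
        config.random_seed if seed is None else seed)
    feed_g = config.feed_dry_mass_g
    records: list[ExperimentRecord] = []
    for spec in config.conditions:
        vented = spec.condition.reactor_label != "2-L"
        for _ in range(config.n_replicates):
            for _attempt in range(1000):
                draws = {
                    k: _draw_truncated(rng, spec.mean_yields_pct.get(k, 0.0),
                                       spec.sd_yields_pct.get(k, 0.0))
                    for k in _FRACTIONS
                }
                if sum(draws.values()) <= 105.0:
                    break
            else:  # pragma: no cover - unreachable under sane configs
                raise ValidationError(
                    f"{spec.condition_id}: cannot draw a slate closing < 105 %")
            crude_g = draws["biocrude"] / 100.0 * feed_g
            slate = ProductSlate(
                feed_dry_mass_g=feed_g,
                biocrude1_mass_g=datasets.B1_FRACTION * crude_g,
                biocrude2_mass_g=(1.0 - datasets.B1_FRACTION) * crude_g,
                solids_mass_g=draws["solids"] / 100.0 * feed_g,
                nvr_mass_g=draws["nvr"] / 100.0 * feed_g,
                gas_mass_g=None if vented else draws["gas"] / 100.0 * feed_g,
            )
            c, h, n, ash = spec.crude_composition
            crude = FractionProperties(
                carbon_pct=c, hydrogen_pct=h, nitrogen_pct=n, ash_pct=ash,
                oxygen_pct=max(0.0, 100.0 - c - h - n - ash),
                hhv_mj_per_kg=_draw_truncated(rng, spec.crude_hhv_mean,
                                              spec.crude_hhv_sd),
                oxygen_is_by_difference=True,
            )
            gas = (None if vented or spec.gas_fractions is None
                   else GasProfile(dict(spec.gas_fractions)))
            records.append(ExperimentRecord(
                condition_id=spec.condition_id, condition=spec.condition,
                slate=slate, crude=crude, acp=spec.acp, gas=gas,
            ))
    return records


def recover_parameters(records: Sequence[ExperimentRecord]) -> pd.DataFrame:
    """Per-condition sample means/SDs of the fraction yields and crude HHV.

    The estimates are order-invariant and require at least two replicates per
    condition.  Yields are recomputed from masses (percent of dry feed), so
    this is also an end-to-end check of the mass bookkeeping.
    """
    rows = []
    for rec in records:
        s = rec.slate
        rows.append({
            "condition_id": rec.condition_id,
            "biocrude": 100.0 * s.biocrude_mass_g / s.feed_dry_mass_g,
            "solids": 100.0 * s.solids_mass_g / s.feed_dry_mass_g,
            "gas": (np.nan if s.gas_mass_g is None
                    else 100.0 * s.gas_mass_g / s.feed_dry_mass_g),
            "nvr": 100.0 * s.nvr_mass_g / s.feed_dry_mass_g,
            "crude_hhv": rec.crude.hhv_mj_per_kg,
        })
    df = pd.DataFrame(rows)
    counts = df.groupby("condition_id").size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValidationError(f"condition(s) with < 2 replicates: {bad}")
    grouped = df.groupby("condition_id").agg(["mean", "std"])
    grouped.columns = [f"{col}_{stat}" for col, stat in grouped.columns]
    return grouped.sort_index()
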