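"""Derived quantities for HTL product slates.

Given raw product masses and fraction properties, this module computes the
standard bench-scale bookkeeping: percentage yields on a dry-feed basis,
mass-recovery closure, elemental atomic ratios, carbon-hydrogen recovery in
the biocrude, chemical-energy recovery

    ER_biocrude = (HHV_biocrude x m_biocrude) / (HHV_feed x m_feed) x 100 %,

and the one-way ANOVA used to compare replicate yields across treatments.

Printed-value conventions matter here.  Yields are percent of dry,
ash-inclusive feed mass.  ER may legitimately exceed 100 % when co-solvent
mass is incorporated into products.  Oxygen "by difference" is computed but
never overwrites a measured/printed oxygen value: disagreements are surfaced
through :func:`oxygen_difference_report`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .experiment_model import (
    ExperimentRecord,
    FeedstockComposition,
    FractionProperties,
    GasProfile,
    ProductSlate,
    ValidationError,
)

__all__ = [
    "AccountingResult",
    "yield_pct",
    "mass_closure",
    "energy_recovery",
    "ch_recovery",
    "atomic_ratio",
    "oxygen_by_difference",
    "relative_yield_change",
    "anova_one_way",
    "normalize_gas",
    "account_record",
    "account",
    "oxygen_difference_report",
    "ATOMIC_MASS",
]

#: standard atomic masses used for atomic ratios (g mol^-1)
ATOMIC_MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999}


@dataclass
class AccountingResult:
    """All derived quantities for one run (percent of dry feed unless noted)."""

    condition_id: str
    biocrude_yield_pct: float
    solids_yield_pct: float
    gas_yield_pct: float
    nvr_yield_pct: float
    total_recovery_pct: float
    mass_lost_pct: float
    er_biocrude_pct: float
    ch_recovery_pct: float
    oc_atomic_ratio: float
    nc_atomic_ratio: float


def yield_pct(product_mass_g: float, feed_dry_mass_g: float) -> float:
    """Mass yield of a product fraction as percent of dry feed."""
    if feed_dry_mass_g <= 0:
        raise ValidationError("feed_dry_mass_g must be > 0")
    if product_mass_g < 0:
        raise ValidationError("product_mass_g must be >= 0")
    return 100.0 * product_mass_g / feed_dry_mass_g


def mass_closure(slate: ProductSlate) -> tuple[float, float]:
    """Total mass recovery and its complement, percent of dry feed.

    An absent (vented) gas mass contributes zero.  Catalyst mass is excluded
    by construction: the slate never contains it.
    """
    total = (
        yield_pct(slate.biocrude_mass_g, slate.feed_dry_mass_g)
        + yield_pct(slate.solids_mass_g, slate.feed_dry_mass_g)
        + yield_pct(slate.gas_mass_g or 0.0, slate.feed_dry_mass_g)
        + yield_pct(slate.nvr_mass_g, slate.feed_dry_mass_g)
    )
    return total, 100.0 - total


def energy_recovery(biocrude_yield_frac: float, hhv_biocrude: float,
                    hhv_feed: float) -> float:
    """Chemical-energy recovery in biocrude, percent of feed chemical energy.

    ``biocrude_yield_frac`` is the mass yield as a fraction (m_crude/m_feed),
    so the mass terms of the defining ratio collapse into it.  Values above
    100 % are possible when co-solvent mass enters the products.
    """
    if hhv_feed <= 0:
        raise ValidationError("hhv_feed must be > 0")
    if not (0.0 <= biocrude_yield_frac <= 1.05):
        raise ValidationError("biocrude_yield_frac outside [0, 1.05]")
    return 100.0 * biocrude_yield_frac * hhv_biocrude / hhv_feed


def ch_recovery(biocrude_yield_frac: float, crude: FractionProperties,
                feed: FeedstockComposition) -> float:
    """Carbon + hydrogen recovered in biocrude, percent of feed C + H.

    Mass-percent basis on the as-received feed composition.
    """
    feed_ch = feed.carbon_pct + feed.hydrogen_pct
    if feed_ch <= 0:
        raise ValidationError("feed C + H must be > 0")
    return 100.0 * biocrude_yield_frac * (
        (crude.carbon_pct + crude.hydrogen_pct) / feed_ch
    )


def atomic_ratio(element_pct_x: float, element_pct_c: float,
                 atomic_mass_x: float, atomic_mass_c: float = ATOMIC_MASS["C"],
                 ) -> float:
    """Atomic (mole) ratio X/C from mass percentages."""
    if element_pct_c <= 0:
        raise ValidationError("carbon percentage must be > 0")
    if atomic_mass_x <= 0 or atomic_mass_c <= 0:
        raise ValidationError("atomic masses must be > 0")
    return (element_pct_x / atomic_mass_x) / (element_pct_c / atomic_mass_c)


def oxygen_by_difference(c_pct: float, h_pct: float, n_pct: float,
                         include_ash: bool = False,
                         ash_pct: float = 0.0) -> float:
    """Oxygen mass percent as 100 - C - H - N (- ash), floored at zero.

    A result below -2 indicates grossly inconsistent inputs and raises.
    """
    for name, v in (("c_pct", c_pct), ("h_pct", h_pct), ("n_pct", n_pct),
                    ("ash_pct", ash_pct)):
        if not (0.0 <= v <= 100.0):
            raise ValidationError(f"{name} = {v} outside [0, 100]")
    o = 100.0 - c_pct - h_pct - n_pct - (ash_pct if include_ash else 0.0)
    if o < -2.0:
        raise ValidationError(
            f"by-difference oxygen = {o:.2f} < -2: inputs inconsistent"
        )
    return max(0.0, o)


def relative_yield_change(yield_a_pct: float, yield_b_pct: float) -> float:
    """Relative change from yield a to yield b, percent of a."""
    if yield_a_pct <= 0:
        raise ValidationError("yield_a_pct must be > 0")
    return 100.0 * (yield_b_pct - yield_a_pct) / yield_a_pct


def anova_one_way(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA across replicate-yield groups.

    Returns ``(F, p)``.  Requires at least two groups with at least two
    replicates each.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise ValidationError(f"group {i} has < 2 replicates")
    f, p = stats.f_oneway(*[list(map(float, g)) for g in groups])
    return float(f), float(p)


def normalize_gas(gas: GasProfile) -> GasProfile:
    """Scale gas mole fractions to sum to one, preserving species order."""
    total = gas.total()
    if total <= 0:
        raise ValidationError("gas profile has no positive component")
    return GasProfile({k: v / total for k, v in gas.fractions.items()})


def account_record(record: ExperimentRecord,
                   feed: FeedstockComposition) -> AccountingResult:
    """All derived quantities for one experiment record."""
    s = record.slate
    b = yield_pct(s.biocrude_mass_g, s.feed_dry_mass_g)
    sol = yield_pct(s.solids_mass_g, s.feed_dry_mass_g)
    gas = yield_pct(s.gas_mass_g or 0.0, s.feed_dry_mass_g)
    nvr = yield_pct(s.nvr_mass_g, s.feed_dry_mass_g)
    total, lost = mass_closure(s)
    return AccountingResult(
        condition_id=record.condition_id,
        biocrude_yield_pct=b, solids_yield_pct=sol, gas_yield_pct=gas,
        nvr_yield_pct=nvr, total_recovery_pct=total, mass_lost_pct=lost,
        er_biocrude_pct=energy_recovery(b / 100.0, record.crude.hhv_mj_per_kg,
                                        feed.hhv_mj_per_kg),
        ch_recovery_pct=ch_recovery(b / 100.0, record.crude, feed),
        oc_atomic_ratio=atomic_ratio(record.crude.oxygen_pct,
                                     record.crude.carbon_pct,
                                     ATOMIC_MASS["O"]),
        nc_atomic_ratio=atomic_ratio(record.crude.nitrogen_pct,
                                     record.crude.carbon_pct,
                                     ATOMIC_MASS["N"]),
    )


def account(records: Sequence[ExperimentRecord],
            feed: FeedstockComposition) -> pd.DataFrame:
    """Derived-quantities table (one row per record), mirroring the standard
    mass-balance / biocrude-properties presentation."""
    rows = [vars(account_record(r, feed)) for r in records]
    return pd.DataFrame(rows).set_index("condition_id")


def oxygen_difference_report(records: Sequence[ExperimentRecord],
                             tolerance: float = 0.1) -> pd.DataFrame:
    """Compare stored biocrude oxygen against the by-difference convention.

    Published biocrude oxygen columns labelled "by difference" are not always
    reproducible from 100 - C - H - N - ash; this report surfaces the gap per
    record instead of silently overwriting either value.
    """
    rows = []
    for r in records:
        c = r.crude
        expected = oxygen_by_difference(c.carbon_pct, c.hydrogen_pct,
                                        c.nitrogen_pct, include_ash=True,
                                        ash_pct=c.ash_pct)
        rows.append({
            "condition_id": r.condition_id,
            "oxygen_stored_pct": c.oxygen_pct,
            "oxygen_by_difference_pct": expected,
            "gap_pct": c.oxygen_pct - expected,
            "consistent": abs(c.oxygen_pct - expected) <= tolerance,
        })
    return pd.DataFrame(rows).set_index("condition_id")
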