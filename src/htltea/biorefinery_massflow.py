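"""Biorefinery mass-flow model: fermentation feed -> HTL -> upgrading.

Implements the conceptual yeast-HTL platform as a parameter-driven chain of
mass flows.  Biocrude from HTL is hydrotreated to a drop-in renewable fuel
under fixed mass coefficients (defaults: 75 % fuel, 14 % coke, 10 % process
gas per kg biocrude, consuming 0.035 kg H2 and 0.004 kg catalyst per kg
biocrude).  These coefficients do not close to 100 %: the residual

    residual = m_biocrude + m_H2_in - (m_fuel + m_coke + m_gas)

is reported explicitly, never renormalized away, because the coefficients are
stated independently of one another.  Solid char is routed to a process-heat
sink, and the dissolved N and P in the aqueous co-phase (ACP) are tagged as
nutrient-recycle streams back to fermentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .experiment_model import ACPProfile, ValidationError

__all__ = [
    "UpgradingSpec",
    "MassFlowResult",
    "upgrade_biocrude",
    "platform_flow",
    "nutrient_recovery_pct",
]


@dataclass
class UpgradingSpec:
    """Fixed mass coefficients for biocrude upgrading (per kg biocrude)."""

    fuel_yield_frac: float = 0.75
    coke_yield_frac: float = 0.14
    gas_yield_frac: float = 0.10
    h2_consumption: float = 0.035   # kg H2 per kg biocrude
    catalyst_input: float = 0.004   # kg catalyst per kg biocrude

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValidationError(f"{f.name} must be >= 0")
        closure = (self.fuel_yield_frac + self.coke_yield_frac
                   + self.gas_yield_frac)
        if closure > 1.0 + self.h2_consumption + 0.02:
            raise ValidationError(
                f"fuel+coke+gas = {closure:.3f} exceeds closure bound "
                f"{1.0 + self.h2_consumption + 0.02:.3f}"
            )


@dataclass
class MassFlowResult:
    """Per-stream masses (kg) for a platform flow; residual reported, never hidden."""

    feed_kg: float = 0.0
    biocrude_kg: float = 0.0
    solids_to_process_heat_kg: float = 0.0
    fuel_kg: float = 0.0
    coke_kg: float = 0.0
    process_gas_kg: float = 0.0
    h2_in_kg: float = 0.0
    catalyst_in_kg: float = 0.0
    acp_nitrogen_recycle_kg: float = 0.0
    acp_phosphorus_recycle_kg: float = 0.0
    closure_residual_kg: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name != "closure_residual_kg" and getattr(self, f.name) < 0:
                raise ValidationError(f"{f.name} must be >= 0")


def upgrade_biocrude(biocrude_mass_kg: float,
                     spec: UpgradingSpec | None = None) -> MassFlowResult:
    """Upgrading step only: biocrude -> fuel + coke + process gas.

    The closure residual is inputs (biocrude + H2) minus outputs
    (fuel + coke + gas); catalyst is tracked as a consumable, not a mass
    source in the product balance.
    """
    if biocrude_mass_kg < 0:
        raise ValidationError("biocrude_mass_kg must be >= 0")
    spec = spec or UpgradingSpec()
    m = biocrude_mass_kg
    fuel = spec.fuel_yield_frac * m
    coke = spec.coke_yield_frac * m
    gas = spec.gas_yield_frac * m
    h2 = spec.h2_consumption * m
    return MassFlowResult(
        biocrude_kg=m, fuel_kg=fuel, coke_kg=coke, process_gas_kg=gas,
        h2_in_kg=h2, catalyst_in_kg=spec.catalyst_input * m,
        closure_residual_kg=m + h2 - (fuel + coke + gas),
    )


def platform_flow(feed_tonnes: float, biocrude_yield_frac: float,
                  solids_yield_frac: float, acp: ACPProfile | None = None,
                  acp_volume_l: float = 0.0,
                  spec: UpgradingSpec | None = None) -> MassFlowResult:
    """Chain HTL yields into upgrading for a given dry-feed tonnage.

    ``acp_volume_l`` is the recovered aqueous-phase volume; it has no
    sensible default and must be supplied for the nutrient-recycle streams
    to be non-zero.  Dissolved N is Kjeldahl-N x volume and dissolved P is
    total-P x volume (mg L^-1 x L -> kg).
    """
    if feed_tonnes < 0:
        raise ValidationError("feed_tonnes must be >= 0")
    for name, y in (("biocrude_yield_frac", biocrude_yield_frac),
                    ("solids_yield_frac", solids_yield_frac)):
        if not (0.0 <= y <= 1.0):
            raise ValidationError(f"{name} outside [0, 1]")
    if acp_volume_l < 0:
        raise ValidationError("acp_volume_l must be >= 0")
    feed_kg = 1000.0 * feed_tonnes
    biocrude_kg = biocrude_yield_frac * feed_kg
    result = upgrade_biocrude(biocrude_kg, spec)
    result.feed_kg = feed_kg
    result.solids_to_process_heat_kg = solids_yield_frac * feed_kg
    if acp is not None and acp_volume_l > 0:
        mg_to_kg = 1e-6
        result.acp_nitrogen_recycle_kg = (acp.kjeldahl_n_mg_l * acp_volume_l
                                          * mg_to_kg)
        result.acp_phosphorus_recycle_kg = (acp.total_p_mg_l * acp_volume_l
                                            * mg_to_kg)
    return result


def nutrient_recovery_pct(dissolved_mass_kg: float, feed_mass_kg: float,
                          feed_element_pct: float) -> float:
    """Dissolved nutrient in the ACP as percent of that element in the feed."""
    if dissolved_mass_kg < 0:
        raise ValidationError("dissolved_mass_kg must be >= 0")
    element_in_feed = feed_mass_kg * feed_element_pct / 100.0
    if element_in_feed <= 0:
        raise ValidationError("feed element mass must be > 0")
    return 100.0 * dissolved_mass_kg / element_in_feed
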