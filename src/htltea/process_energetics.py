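"""Process energetics for HTL: slurry sensible heat, binary-solvent critical
points, and chemical-energy balance tables.

The sensible-heat model is deliberately simple: constant specific heats and
density over the heating ramp,

    Q = rho x [(1 - f) cp_water + f cp_solids] x (T_target - T_initial) / 1000

in MJ per m^3 of slurry, with ``f`` the solids mass fraction.  With the
default constants (cp_water 4.18, cp_solids 2.0 kJ kg^-1 K^-1, rho 1000
kg m^-3, ambient 25 degC) this reproduces the rule-of-thumb heating duties of
a 10 wt% slurry (~1290 / ~1100 / ~890 MJ m^-3 at 350 / 300 / 250 degC).
Saturated-liquid steam-table enthalpies overshoot these figures; all four
constants are overridable per spec.

Critical points of water-alcohol binary solvents are handled as a two-anchor
lookup (pure water, 1:1 mixture) with linear interpolation in the alcohol
mass fraction — a bookkeeping device, not a thermodynamic mixing model.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .experiment_model import ValidationError

__all__ = [
    "SlurrySpec",
    "CriticalPoint",
    "EnergyBalance",
    "sensible_heat_mj_per_m3",
    "critical_point",
    "chemical_energy_table",
    "WATER_CRITICAL_POINT",
    "CRITICAL_ANCHORS",
]

#: critical point of pure water: (degC, MPa)
WATER_CRITICAL_POINT = (374.1, 22.1)

#: per-alcohol anchor at 1:1 (mass) alcohol:water: (degC, MPa)
CRITICAL_ANCHORS: dict[str, tuple[float, float]] = {
    "isopropanol": (311.3, 10.2),
}


@dataclass
class SlurrySpec:
    """A biomass-water slurry to be heated from ``t_initial_c`` to ``t_target_c``."""

    solids_mass_frac: float
    t_initial_c: float = 25.0
    t_target_c: float = 350.0
    cp_water: float = 4.18    # kJ kg^-1 K^-1
    cp_solids: float = 2.0    # kJ kg^-1 K^-1
    density_kg_m3: float = 1000.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.solids_mass_frac <= 1.0):
            raise ValidationError("solids_mass_frac outside [0, 1]")
        if self.t_target_c < self.t_initial_c:
            raise ValidationError("t_target_c must not be below t_initial_c")
        if self.cp_water <= 0 or self.cp_solids <= 0:
            raise ValidationError("specific heats must be > 0")
        if self.density_kg_m3 <= 0:
            raise ValidationError("density must be > 0")


def sensible_heat_mj_per_m3(spec: SlurrySpec) -> float:
    """Sensible heat to bring one m^3 of slurry to the target temperature (MJ)."""
    f = spec.solids_mass_frac
    cp_mix = (1.0 - f) * spec.cp_water + f * spec.cp_solids  # kJ kg^-1 K^-1
    dt = spec.t_target_c - spec.t_initial_c
    return spec.density_kg_m3 * cp_mix * dt / 1000.0


@dataclass
class CriticalPoint:
    t_critical_c: float
    p_critical_mpa: float
    interpolated: bool = False


def critical_point(alcohol_label: str,
                   alcohol_mass_frac: float) -> CriticalPoint:
    """Critical temperature/pressure of a water-alcohol binary solvent.

    Exact at the two anchors (pure water at fraction 0; the tabulated 1:1
    mixture at fraction 0.5); linear in the alcohol mass fraction elsewhere,
    flagged ``interpolated`` (fractions above 0.5 extrapolate on the same
    line).
    """
    if not (0.0 <= alcohol_mass_frac <= 1.0):
        raise ValidationError("alcohol_mass_frac outside [0, 1]")
    if alcohol_mass_frac == 0.0:
        return CriticalPoint(*WATER_CRITICAL_POINT)
    if alcohol_label not in CRITICAL_ANCHORS:
        raise KeyError(
            f"no critical-point anchor for alcohol {alcohol_label!r}; "
            f"known: {sorted(CRITICAL_ANCHORS)}"
        )
    t_mix, p_mix = CRITICAL_ANCHORS[alcohol_label]
    if alcohol_mass_frac == 0.5:
        return CriticalPoint(t_mix, p_mix)
    t_w, p_w = WATER_CRITICAL_POINT
    w = alcohol_mass_frac / 0.5
    return CriticalPoint(
        t_critical_c=t_w + w * (t_mix - t_w),
        p_critical_mpa=p_w + w * (p_mix - p_w),
        interpolated=True,
    )


@dataclass
class EnergyBalance:
    """Chemical-energy table: per-stream mass x HHV, plus totals."""

    rows: pd.DataFrame             # stream, mass_kg, hhv_mj_per_kg, chemical_energy_mj
    feed_energy_mj: float
    product_energy_mj: float
    product_share_pct: float


def chemical_energy_table(feed: tuple[float, float],
                          products: list[tuple[str, float, float]],
                          ) -> EnergyBalance:
    """Chemical-energy balance of an HTL run.

    ``feed`` is (mass_kg, hhv_mj_per_kg); ``products`` are (label, mass_kg,
    hhv_mj_per_kg) tuples.  Chemical energy per stream is mass x HHV; the
    product share is the product-sum as percent of feed chemical energy.  The
    natural basis is 100 kg dry feed, so feed energy equals 100 x HHV_feed.
    """
    feed_mass, feed_hhv = feed
    if feed_mass < 0 or feed_hhv < 0:
        raise ValidationError("feed mass and HHV must be >= 0")
    rows = [{"stream": "feed", "mass_kg": feed_mass,
             "hhv_mj_per_kg": feed_hhv,
             "chemical_energy_mj": feed_mass * feed_hhv}]
    product_energy = 0.0
    for label, mass, hhv in products:
        if mass < 0 or hhv < 0:
            raise ValidationError(f"stream {label!r}: negative mass or HHV")
        e = mass * hhv
        product_energy += e
        rows.append({"stream": label, "mass_kg": mass,
                     "hhv_mj_per_kg": hhv, "chemical_energy_mj": e})
    feed_energy = feed_mass * feed_hhv
    share = (100.0 * product_energy / feed_energy) if feed_energy > 0 else 0.0
    return EnergyBalance(rows=pd.DataFrame(rows), feed_energy_mj=feed_energy,
                         product_energy_mj=product_energy,
                         product_share_pct=share)
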