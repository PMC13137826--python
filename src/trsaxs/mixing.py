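"""Laminar co-flow mixer model.

Three syringe-driven inlets merge into one channel: protein in the center,
buffer (with or without metal ions) on the sides. Small ions equilibrate
across the channel by transverse diffusion on the Fick time scale
t_D = y^2 / (2D); positions along the channel map to times after mixing via
the mean axial (plug-flow) velocity v = Q / A; and once the protein has
fully diluted, its concentration — hence the normalized forward scattering
I(0)/I(0)_0 — plateaus at the protein inlet's share of the total flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: infinite-dilution aqueous diffusion coefficients, m^2/s
DIFFUSION_COEFFICIENTS = {
    "Mn": 6.88e-10,
    "Fe": 6.05e-10,
    "Cu": 7.33e-10,
    "Zn": 7.15e-10,
}


@dataclass(frozen=True)
class MixingGeometry:
    """Channel geometry and flow program of the microfluidic chip."""

    channel_width_um: float = 100.0
    channel_depth_um: float = 100.0
    channel_length_mm: float = 87.0
    total_flow_rate_ul_min: float = 14.0
    inlet_flow_fractions: tuple = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
    diffusion_coefficients: dict = field(
        default_factory=lambda: dict(DIFFUSION_COEFFICIENTS)
    )

    def __post_init__(self):
        for name in ("channel_width_um", "channel_depth_um",
                     "channel_length_mm", "total_flow_rate_ul_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        f = np.asarray(self.inlet_flow_fractions, dtype=float)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("inlet flow fractions must be >= 0 and sum to 1")

    @property
    def half_width_m(self) -> float:
        return self.channel_width_um * 1e-6 / 2.0

    @property
    def mean_velocity_mm_s(self) -> float:
        """v = Q / (width * depth), in mm/s."""
        q_m3_s = self.total_flow_rate_ul_min * 1e-9 / 60.0
        area_m2 = self.channel_width_um * self.channel_depth_um * 1e-12
        return q_m3_s / area_m2 * 1e3


def diffusion_time(D: float, half_width: float) -> float:
    """Characteristic Fick diffusion time t = y^2 / (2 D), seconds.

    ``D`` in m^2/s, ``half_width`` in meters.
    """
    if D <= 0:
        raise ValueError("diffusion coefficient must be positive")
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    return half_width**2 / (2.0 * D)


def position_to_time(x_mm: float, geom: MixingGeometry = MixingGeometry()) -> float:
    """Residence time (s) at axial position ``x_mm`` under plug flow."""
    if not 0.0 <= x_mm <= geom.channel_length_mm:
        raise ValueError(
            f"x = {x_mm} mm outside channel [0, {geom.channel_length_mm}] mm"
        )
    return x_mm / geom.mean_velocity_mm_s


def time_to_position(t_s: float, geom: MixingGeometry = MixingGeometry()) -> float:
    """Axial position (mm) reached after ``t_s`` seconds under plug flow."""
    x = t_s * geom.mean_velocity_mm_s
    if x > geom.channel_length_mm:
        raise ValueError(f"t = {t_s} s lies beyond the channel outlet")
    return x


def dilution_plateau(geom: MixingGeometry = MixingGeometry(), protein_inlet: int = 1) -> float:
    """Asymptote of I(0)/I(0)_0 after complete mixing.

    By mass balance the fully mixed concentration is the protein inlet's
    flow fraction of the total; I(0) is proportional to concentration.
    """
    if protein_inlet not in (0, 1, 2):
        raise ValueError("protein_inlet must be 0, 1, or 2")
    return float(geom.inlet_flow_fractions[protein_inlet])


def mixing_report(
    geom: MixingGeometry = MixingGeometry(),
    positions_mm=None,
) -> pd.DataFrame:
    """Tabulate t_D per ion plus the position -> time grid.

    Returns a tidy frame with a ``kind`` column: one ``diffusion`` row per
    ion (t_D and the axial distance swept in that time) and one ``position``
    row per requested measurement position.
    """
    rows = []
    v = geom.mean_velocity_mm_s
    for ion, D in geom.diffusion_coefficients.items():
        t = diffusion_time(D, geom.half_width_m)
        rows.append({
            "kind": "diffusion", "label": ion, "D_m2_s": D,
            "time_s": t, "axial_distance_mm": t * v,
        })
    for x in (positions_mm or []):
        rows.append({
            "kind": "position", "label": f"{x:g}mm", "D_m2_s": np.nan,
            "time_s": position_to_time(x, geom), "axial_distance_mm": float(x),
        })
    return pd.DataFrame(rows)
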