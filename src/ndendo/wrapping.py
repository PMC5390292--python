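"""Continuum energetics of membrane wrapping around a nanoparticle tip.

For an infinite, tension-free membrane partially wrapping a spherical
tip of radius ``R`` up to wrapping angle ``theta``, the total energy is
the Helfrich bending cost plus the adhesion gain:

    G_tot(theta) = G_bend + G_ad = [4 pi k_b + 2 pi R^2 k_ad] (1 - cos theta)

with ``k_b`` the membrane bending modulus and ``k_ad`` the (signed) unit
adhesion strength; ``k_ad < 0`` means favorable adhesion.  Because
``G_tot`` is linear in ``1 - cos(theta)``, wrapping is favorable for any
``theta > 0`` iff the bracket is negative, giving the analytic phase
boundary ``k_ad = -2 k_b / R^2`` and critical tip radius
``R_c = sqrt(2 k_b / |k_ad|)``: sharper tips (smaller R) are not wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, kbt_kcal


@dataclass(frozen=True)
class WrappingParams:
    """Parameters of the tip-wrapping energy model.

    ``k_b`` may be given in units of ``kBT`` (converted at
    ``temperature``) or directly in kcal/mol via ``k_b_units``.
    ``k_ad`` is signed, in kcal/mol/nm^2; use
    :func:`adhesion_magnitude_to_signed` for magnitudes reported as
    positive binding strengths.
    """

    k_b: float
    k_ad: float
    tip_radius: float
    temperature: float = DEFAULT_TEMPERATURE_K
    k_b_units: str = "kBT"

    def __post_init__(self) -> None:
        if self.k_b <= 0:
            raise ValueError("bending modulus must be positive")
        if self.tip_radius <= 0:
            raise ValueError("tip radius must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.k_b_units not in ("kBT", "kcal/mol"):
            raise ValueError("k_b_units must be 'kBT' or 'kcal/mol'")

    @property
    def k_b_kcal(self) -> float:
        """Bending modulus in kcal/mol."""
        if self.k_b_units == "kBT":
            return self.k_b * kbt_kcal(self.temperature)
        return self.k_b


def adhesion_magnitude_to_signed(k_ad_magnitude: float) -> float:
    """Convert a positive adhesion strength to the model's signed convention."""
    if k_ad_magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    return -k_ad_magnitude


def g_tot(theta, params: WrappingParams):
    """Total wrapping energy G_tot(theta) in kcal/mol, theta in [0, pi]."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > np.pi):
        raise ValueError("wrapping angle must lie in [0, pi]")
    pref = 4 * np.pi * params.k_b_kcal + 2 * np.pi * params.tip_radius**2 * params.k_ad
    out = pref * (1 - np.cos(theta))
    return float(out) if out.ndim == 0 else out


def is_wrapped(params: WrappingParams) -> bool:
    """True iff G_tot < 0 for theta > 0 (strictly favorable wrapping)."""
    return 4 * np.pi * params.k_b_kcal + 2 * np.pi * params.tip_radius**2 * params.k_ad < 0


def critical_radius(k_b_kcal: float, k_ad: float) -> float:
    """Tip radius R_c = sqrt(2 k_b / |k_ad|) separating wrap from no-wrap.

    ``k_b_kcal`` in kcal/mol, ``k_ad`` signed (< 0) in kcal/mol/nm^2.
    """
    if k_ad >= 0:
        raise ValueError("no finite critical radius without favorable adhesion (k_ad < 0)")
    if k_b_kcal <= 0:
        raise ValueError("bending modulus must be positive")
    return float(np.sqrt(2 * k_b_kcal / abs(k_ad)))


@dataclass(frozen=True)
class PhaseDiagram:
    """Wrap / no-wrap classification over a (k_b, k_ad) grid at fixed R."""

    k_b_grid: np.ndarray          # kcal/mol
    k_ad_grid: np.ndarray         # signed, kcal/mol/nm^2
    tip_radius: float
    wrapped: np.ndarray           # (len(k_b_grid), len(k_ad_grid)) bool

    def boundary_k_ad(self, k_b_kcal) -> np.ndarray:
        """Analytic boundary k_ad = -2 k_b / R^2 (G_tot = 0)."""
        return -2.0 * np.asarray(k_b_kcal, dtype=float) / self.tip_radius**2


def phase_diagram(
    k_b_grid,
    k_ad_grid,
    tip_radius: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
    k_b_units: str = "kBT",
) -> PhaseDiagram:
    """Classify every (k_b, k_ad) grid point as wrapping or not.

    Boundary points (G_tot = 0) are classified as no-wrap, per the strict
    inequality G_tot < 0 for wrapping.
    """
    k_b_grid = np.asarray(k_b_grid, dtype=float)
    k_ad_grid = np.asarray(k_ad_grid, dtype=float)
    if k_b_grid.size == 0 or k_ad_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if tip_radius <= 0:
        raise ValueError("tip radius must be positive")
    scale = kbt_kcal(temperature) if k_b_units == "kBT" else 1.0
    kb_kcal = k_b_grid * scale
    pref = (4 * np.pi * kb_kcal[:, None]
            + 2 * np.pi * tip_radius**2 * k_ad_grid[None, :])
    return PhaseDiagram(
        k_b_grid=kb_kcal, k_ad_grid=k_ad_grid,
        tip_radius=tip_radius, wrapped=pref < 0,
    )
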