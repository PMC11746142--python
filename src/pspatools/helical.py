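"""Rod diameters from radial intensity profiles and helical-lattice arithmetic.

PspA rods are helical polymers described by a screw operation (axial rise in
Å, twist in degrees) plus an n-fold cyclic symmetry Cn. Each diameter class
observed by cryo-EM has its own symmetry triple; from it follow the per-ASU
rise (rise/n), the mass-per-length (n·m/rise for monomer mass m), the number
of monomers in a rod of given length, and the cylindrical lattice geometry
(which chain-index offsets are spatial neighbours).

Diameters are measured the way the field measures them from reconstructions:
read the radius where the rotationally averaged, max-normalized intensity
falls through a cutoff (default 0.3), average over class members, convert to
a diameter and round to 5 Å increments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema

__all__ = [
    "RadialProfile",
    "HelicalSymmetry",
    "RodClass",
    "load_map",
    "radial_profile",
    "diameter_at_cutoff",
    "leaflet_radii",
    "mass_per_length",
    "per_asu_rise",
    "monomer_count",
    "local_turnover",
    "neighbor_offsets",
    "load_symmetry_table",
    "atp_symmetry_table",
    "PSPA_MONOMER_MASS_KDA",
]

#: Monomer mass of Synechocystis PspA in kDa.
PSPA_MONOMER_MASS_KDA = 25.3


@dataclass(frozen=True)
class RadialProfile:
    """Rotationally averaged intensity versus radius, normalized to max 1."""

    radii: np.ndarray  # Å, strictly increasing from 0
    intensities: np.ndarray  # unitless

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii, dtype=float)
        intens = np.asarray(self.intensities, dtype=float)
        if radii.ndim != 1 or radii.shape != intens.shape:
            raise ValueError("radii and intensities must be matching 1D arrays")
        if radii.size < 2 or np.any(np.diff(radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if not np.all(np.isfinite(intens)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "intensities", intens)

    def normalized(self) -> "RadialProfile":
        peak = float(self.intensities.max())
        if peak <= 0:
            raise ValueError("profile has no positive intensity to normalize")
        return RadialProfile(self.radii, self.intensities / peak)


@dataclass(frozen=True)
class HelicalSymmetry:
    """Cn cyclic order plus the helical screw (rise Å, twist degrees)."""

    n: int
    rise: float
    twist: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cyclic order n must be >= 1")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not (-180.0 < self.twist <= 180.0):
            raise ValueError("twist must lie in (-180, 180]")


@dataclass(frozen=True)
class RodClass:
    """One rod diameter class: outer diameter, symmetry and monomer mass."""

    diameter: float  # Å, multiple of 5
    symmetry: HelicalSymmetry
    monomer_mass: float = PSPA_MONOMER_MASS_KDA

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.diameter % 5 != 0:
            raise ValueError("diameter must be a positive multiple of 5 Å")


def load_map(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an MRC/CCP4 density map; return (array, voxel size Å)."""
    import gemmi

    grid = gemmi.read_ccp4_map(str(path)).grid
    arr = np.array(grid, copy=True)
    voxel = float(grid.unit_cell.a / grid.nu)
    return arr, voxel


def radial_profile(
    data: np.ndarray,
    center: Sequence[float] | None = None,
    pixel_size: float = 1.0,
    axis: int = 0,
) -> RadialProfile:
    """Rotationally (and, for 3D, axially) average intensity into radial bins.

    Parameters
    ----------
    data : 2D image or 3D map. For 3D the helical axis is ``axis`` and every
        plane perpendicular to it is averaged together.
    center : in-plane center in pixel coordinates (row, col); defaults to the
        geometric image center.
    pixel_size : Å per pixel; also the radial bin width.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 3:
        planes = np.moveaxis(data, axis, 0)
        data = planes.mean(axis=0)
    if data.ndim != 2:
        raise ValueError("expected a 2D image or 3D map")
    if center is None:
        center = ((data.shape[0] - 1) / 2.0, (data.shape[1] - 1) / 2.0)
    cr, cc = float(center[0]), float(center[1])
    if not (0 <= cr < data.shape[0] and 0 <= cc < data.shape[1]):
        raise ValueError("center lies outside the image")
    rr, cc_idx = np.indices(data.shape)
    radius_px = np.hypot(rr - cr, cc_idx - cc)
    bin_idx = np.round(radius_px).astype(int)
    n_bins = bin_idx.max() + 1
    sums = np.bincount(bin_idx.ravel(), weights=data.ravel(), minlength=n_bins)
    counts = np.bincount(bin_idx.ravel(), minlength=n_bins)
    profile = sums / np.maximum(counts, 1)
    radii = np.arange(n_bins) * pixel_size
    return RadialProfile(radii, profile).normalized()


def diameter_at_cutoff(
    profile: RadialProfile,
    cutoff: float = 0.3,
    increment: float = 5.0,
    class_members: Sequence[RadialProfile] | None = None,
) -> float:
    """Rod diameter (Å) from the outermost falling-edge crossing of ``cutoff``.

    The radius where the normalized profile last falls through the cutoff is
    found with linear interpolation between bins; radii of class members are
    averaged before conversion; the diameter is rounded half-up to the
    nearest ``increment``.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie in (0, 1)")
    profiles = [profile] + list(class_members or [])
    radii = [_falling_edge_radius(p.normalized(), cutoff) for p in profiles]
    mean_radius = float(np.mean(radii))
    raw_diameter = 2.0 * mean_radius
    return _round_half_up(raw_diameter, increment)


def _falling_edge_radius(profile: RadialProfile, cutoff: float) -> float:
    r, y = profile.radii, profile.intensities
    above = y > cutoff
    if not above.any():
        raise ValueError("profile never exceeds the cutoff")
    if above.all():
        raise ValueError("profile never falls below the cutoff: no edge to read")
    i = int(np.flatnonzero(above)[-1])  # last bin above: outermost falling edge
    if i == y.size - 1:
        return float(r[i])
    # linear interpolation between bins i (above) and i+1 (below)
    frac = (y[i] - cutoff) / (y[i] - y[i + 1])
    return float(r[i] + frac * (r[i + 1] - r[i]))


def _round_half_up(value: float, increment: float) -> float:
    return math.floor(value / increment + 0.5) * increment


def leaflet_radii(
    profile: RadialProfile, window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Radii (Å) of the two highest local intensity maxima — the bilayer leaflets.

    Used on profiles of rods with engulfed membrane tubes, where each leaflet
    produces a peak. Peaks are refined to sub-bin precision with a 3-point
    parabola. Returns (inner, outer).
    """
    prof = profile.normalized()
    r, y = prof.radii, prof.intensities
    lo, hi = window if window is not None else (r[0], r[-1])
    (peaks,) = argrelextrema(y, np.greater)
    peaks = [int(p) for p in peaks if lo <= r[p] <= hi]
    if len(peaks) < 2:
        raise ValueError("fewer than two local maxima in the search window")
    top_two = sorted(sorted(peaks, key=lambda p: y[p], reverse=True)[:2])
    refined = [_parabolic_refine(r, y, p) for p in top_two]
    return (refined[0], refined[1])


def _parabolic_refine(r: np.ndarray, y: np.ndarray, i: int) -> float:
    if i == 0 or i == y.size - 1:
        return float(r[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(r[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    return float(r[i] + shift * (r[min(i + 1, y.size - 1)] - r[i]))


def per_asu_rise(sym: HelicalSymmetry) -> float:
    """Axial rise per asymmetric unit (monomer), Å: rise / n."""
    return sym.rise / sym.n


def mass_per_length(sym: HelicalSymmetry, monomer_mass: float = PSPA_MONOMER_MASS_KDA) -> float:
    """Polymer mass per axial Å (kDa/Å): n · monomer_mass / rise."""
    if monomer_mass <= 0:
        raise ValueError("monomer mass must be positive")
    return sym.n * monomer_mass / sym.rise


def monomer_count(
    rod_length_um: float, sym: HelicalSymmetry, sig_figs: int | None = None
) -> float:
    """Number of monomers in a rod of the given length (µm).

    count = length(Å) · n / rise. With ``sig_figs`` the count is rounded to
    that many significant figures (e.g. a 2.6 µm rod of the 215 Å class,
    C1 with 2.52 Å rise, holds ~10,000 monomers at one significant figure).
    """
    if rod_length_um < 0:
        raise ValueError("rod length must be non-negative")
    count = rod_length_um * 1e4 * sym.n / sym.rise
    if sig_figs is not None and count > 0:
        exponent = math.floor(math.log10(count))
        factor = 10.0 ** (exponent - sig_figs + 1)
        count = round(count / factor) * factor
    return count


def local_turnover(bulk_rate_per_h: float, amplification: float) -> tuple[float, float]:
    """Scale a bulk ATPase rate to an effective local rate.

    When only a small fraction of the lattice sites in a rod hydrolyse
    actively, the per-active-site turnover exceeds the bulk rate by the
    amplification factor. Returns (rate h⁻¹, rate min⁻¹).
    """
    if bulk_rate_per_h < 0:
        raise ValueError("bulk rate must be non-negative")
    if amplification < 1:
        raise ValueError("amplification must be >= 1")
    per_h = bulk_rate_per_h * amplification
    return per_h, per_h / 60.0


def neighbor_offsets(
    sym: HelicalSymmetry, radius: float, k_max: int = 40
) -> pd.DataFrame:
    """Rank chain-index offsets of a helical lattice by 3D centroid distance.

    Chains are indexed step-major, cyclic-copy-minor: chain (k, c) sits at
    azimuth k·twist + c·360/n and height k·rise on a cylinder of the given
    radius. For every offset k in [−k_max, k_max] (and every cyclic copy c)
    the chord distance on the cylinder is
    sqrt( (2R·sin(Δφ/2))² + (k·rise)² ).

    Returns a DataFrame with columns (k, c, offset, distance_A) sorted by
    ascending distance, the self-offset (0, 0) excluded. ``offset`` is the
    flat chain index k·n + c.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    rows = []
    for k in range(-k_max, k_max + 1):
        for c in range(sym.n):
            if k == 0 and c == 0:
                continue
            dphi = math.radians(k * sym.twist + c * 360.0 / sym.n)
            chord = 2.0 * radius * abs(math.sin(dphi / 2.0))
            dist = math.hypot(chord, k * sym.rise)
            rows.append((k, c, k * sym.n + c, dist))
    frame = pd.DataFrame(rows, columns=["k", "c", "offset", "distance_A"])
    return frame.sort_values("distance_A", kind="stable", ignore_index=True)


def load_symmetry_table(path: str | Path) -> pd.DataFrame:
    """Load a symmetry-class CSV (diameter_A, cyclic_n, rise_A, twist_deg)."""
    table = pd.read_csv(path)
    required = {"diameter_A", "cyclic_n", "rise_A", "twist_deg"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"symmetry table missing columns: {sorted(missing)}")
    return table


def atp_symmetry_table() -> pd.DataFrame:
    """The 11 refined PspA+ATP diameter classes (180–365 Å) and their symmetries."""
    with resources.as_file(
        resources.files("pspatools.data") / "atp_symmetry_classes.csv"
    ) as path:
        return load_symmetry_table(path)


def rod_classes(table: pd.DataFrame | None = None,
                monomer_mass: float = PSPA_MONOMER_MASS_KDA) -> list[RodClass]:
    """Convert a symmetry table into RodClass objects ordered by diameter."""
    if table is None:
        table = atp_symmetry_table()
    table = table.sort_values("diameter_A")
    return [
        RodClass(
            diameter=float(row.diameter_A),
            symmetry=HelicalSymmetry(int(row.cyclic_n), float(row.rise_A), float(row.twist_deg)),
            monomer_mass=monomer_mass,
        )
        for row in table.itertuples()
    ]
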