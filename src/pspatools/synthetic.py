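"""Seeded synthetic inputs with exact ground truth.

Three generators provide the inputs the analysis stages consume, each with
analytically known truth so estimator accuracy can be quantified:

* **Vesicle fields** — 2D grayscale images plus binary membrane masks.
  Each vesicle is a closed contour (circle with optional low-order Fourier
  perturbation) rendered as a two-leaflet bilayer: two dark concentric
  intensity minima separated by the vesicle's bilayer spacing, matching
  cryo-EM contrast where membranes are dark. A controlled fraction of
  vesicles is nested inside a parent vesicle at a known enclosure distance.
* **Radial profiles** — rotationally averaged rod intensity profiles with a
  known outer radius and optional bilayer leaflet peaks.
* **Helical assemblies** — a toy Cα monomer replicated by a rise/twist/Cn
  screw operator into an assembly with exactly known lattice geometry.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .helical import HelicalSymmetry, RadialProfile
from .models import AssemblyModel, ToyMonomer, chain_name

__all__ = [
    "VesicleSpec",
    "SyntheticField",
    "PlacementError",
    "generate_vesicle_field",
    "threshold_segment",
    "generate_radial_profile",
    "default_toy_monomer",
    "DEFAULT_SEGMENT_MAP",
    "generate_helical_assembly",
    "perturb_monomer",
]

#: Segmentation scale of the membrane analyses, Å per pixel.
DEFAULT_PIXEL_SIZE = 7.0

_N_CONTOUR = 4096  # dense sampling used for truth perimeters/distances


class PlacementError(RuntimeError):
    """Raised when vesicles cannot be placed without forbidden overlap."""


@dataclass
class VesicleSpec:
    """Ground-truth description of one generated vesicle.

    The mid-membrane contour is r(θ) = radius·(1 + Σ aₖ·cos(kθ + φₖ)) in
    pixels. ``perimeter_nm`` is the exact contour length (dense polygonal
    integration × pixel size); ``enclosure_gap`` is the minimum distance in
    Å between this contour and the parent's contour, when nested.
    """

    center: tuple[float, float]  # (row, col) px
    radius: float  # px, mid-membrane
    bilayer_spacing: float  # Å between the two leaflet minima
    contour_perturbation: float = 0.0  # summed relative Fourier amplitude
    fourier: tuple[tuple[int, float, float], ...] = ()  # (k, amp, phase)
    parent: int | None = None
    enclosure_gap: float | None = None  # Å, set iff parent is set
    perimeter_nm: float = 0.0

    def contour(self, n_points: int = _N_CONTOUR) -> np.ndarray:
        """Dense (row, col) polyline of the mid-membrane contour."""
        theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
        r = self.radius_at(theta)
        rows = self.center[0] + r * np.sin(theta)
        cols = self.center[1] + r * np.cos(theta)
        return np.column_stack([rows, cols])

    def radius_at(self, theta: np.ndarray) -> np.ndarray:
        r = np.full_like(np.asarray(theta, dtype=float), self.radius)
        for k, amp, phase in self.fourier:
            r += self.radius * amp * np.cos(k * np.asarray(theta) + phase)
        return r

    def max_radius(self) -> float:
        return self.radius * (1.0 + sum(abs(a) for _, a, _ in self.fourier))


@dataclass
class SyntheticField:
    """One synthetic micrograph: intensity, membrane mask, and ground truth."""

    intensity: np.ndarray  # float32 grayscale
    mask: np.ndarray  # uint8 binary
    pixel_size: float  # Å / px
    truth: list[VesicleSpec]
    seed: int
    contrast: float = 1.0  # membrane dip depth in background-sd units

    @property
    def n_nested(self) -> int:
        return sum(1 for v in self.truth if v.parent is not None)

    @property
    def nested_fraction(self) -> float:
        return self.n_nested / len(self.truth) if self.truth else 0.0

    def save(self, out_dir: str | Path, stem: str = "field") -> dict[str, Path]:
        """Write intensity/mask as TIFF and truth as JSON; return the paths."""
        import tifffile

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "intensity": out / f"{stem}_intensity.tif",
            "mask": out / f"{stem}_mask.tif",
            "truth": out / f"{stem}_truth.json",
        }
        tifffile.imwrite(paths["intensity"], self.intensity.astype(np.float32))
        tifffile.imwrite(paths["mask"], self.mask.astype(np.uint8))
        records = [
            {
                "center": list(v.center),
                "radius_px": v.radius,
                "bilayer_spacing_A": v.bilayer_spacing,
                "contour_perturbation": v.contour_perturbation,
                "fourier": [list(f) for f in v.fourier],
                "parent": v.parent,
                "enclosure_gap_A": v.enclosure_gap,
                "perimeter_nm": v.perimeter_nm,
            }
            for v in self.truth
        ]
        paths["truth"].write_text(
            json.dumps(
                {"pixel_size_A": self.pixel_size, "seed": self.seed, "vesicles": records},
                indent=2,
            )
        )
        return paths


def _contour_length_px(spec: VesicleSpec) -> float:
    pts = spec.contour()
    closed = np.vstack([pts, pts[:1]])
    return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


def _min_contour_distance_px(a: VesicleSpec, b: VesicleSpec) -> float:
    from scipy.spatial import cKDTree

    tree = cKDTree(b.contour())
    d, _ = tree.query(a.contour())
    return float(d.min())


def generate_vesicle_field(
    n_vesicles: int,
    nested_fraction: float = 0.0,
    *,
    image_shape: tuple[int, int] = (1024, 1024),
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    radius_range_px: tuple[float, float] = (18.0, 45.0),
    bilayer_spacing: float | tuple[float, float] = (38.0, 4.0),
    spacing_limits: tuple[float, float] = (25.0, 55.0),
    contour_perturbation: float = 0.0,
    enclosure_gap_range: tuple[float, float] = (50.0, 80.0),
    contrast: float = 1.0,
    noise_sigma: float = 0.0,
    membrane_sigma_px: float = 1.0,
    mask_halfwidth_px: float = 2.0,
    border_margin_px: float = 0.0,
    max_retries: int = 1000,
    seed: int = 0,
) -> SyntheticField:
    """Generate a vesicle field with exact ground truth.

    Parameters
    ----------
    n_vesicles : total number of vesicles.
    nested_fraction : fraction (0–1) of vesicles placed inside a parent;
        exactly ``floor(n_vesicles · nested_fraction)`` get a parent.
    bilayer_spacing : either a fixed spacing in Å or a (mean, sd) pair from
        which per-vesicle spacings are drawn (truncated to
        ``spacing_limits``). The default emulates remodeled membranes with
        a ~38 Å leaflet separation.
    contour_perturbation : summed relative amplitude of low-order (k=2–4)
        Fourier contour modes; 0 gives perfect circles.
    enclosure_gap_range : Å range of the nominal skeleton-to-skeleton gap
        between a nested vesicle and its parent.
    contrast : depth of each leaflet's intensity dip. With noise the image
        is scaled so the background has s.d. 1, making contrast/noise_sigma
        the signal-to-noise ratio.
    noise_sigma : Gaussian noise s.d. before normalization (0 = noiseless).
    mask_halfwidth_px : half-width added around the two leaflets when
        rasterizing the binary membrane mask.
    border_margin_px : extra clearance kept between every vesicle and the
        image border (e.g. the normal-profile half-width used downstream
        by the thickness estimator).

    Raises
    ------
    PlacementError
        If vesicles cannot be placed without forbidden overlap within
        ``max_retries`` attempts each.
    """
    if n_vesicles < 0:
        raise ValueError("n_vesicles must be >= 0")
    if not (0.0 <= nested_fraction <= 1.0):
        raise ValueError("nested_fraction must lie in [0, 1]")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in image_shape)

    n_nested = int(math.floor(n_vesicles * nested_fraction))
    n_top = n_vesicles - n_nested

    def sample_spacing() -> float:
        if isinstance(bilayer_spacing, (int, float)):
            return float(bilayer_spacing)
        mean, sd = bilayer_spacing
        for _ in range(100):
            s = rng.normal(mean, sd)
            if spacing_limits[0] <= s <= spacing_limits[1]:
                return float(s)
        return float(np.clip(mean, *spacing_limits))

    def sample_fourier() -> tuple[tuple[int, float, float], ...]:
        if contour_perturbation <= 0:
            return ()
        modes = (2, 3, 4)
        weights = rng.dirichlet(np.ones(len(modes)))
        return tuple(
            (k, float(contour_perturbation * w), float(rng.uniform(0, 2 * np.pi)))
            for k, w in zip(modes, weights)
        )

    specs: list[VesicleSpec] = []
    margin = mask_halfwidth_px + 2.0

    def footprint(spec: VesicleSpec) -> float:
        # outermost extent of the membrane annulus in px
        return spec.max_radius() + spec.bilayer_spacing / (2 * pixel_size) + margin

    # Vesicles that must host a nested child need interior room for the
    # child plus the enclosure gap; sample their radii from the upper range.
    mean_spacing = (
        float(bilayer_spacing)
        if isinstance(bilayer_spacing, (int, float))
        else float(bilayer_spacing[0])
    )
    min_child_radius = radius_range_px[0] * 0.55
    min_gap_est = mean_spacing / pixel_size + 2 * mask_halfwidth_px + 4.0
    parent_lo = min(
        min_child_radius + min_gap_est + mean_spacing / (2 * pixel_size) + margin + 2,
        radius_range_px[1],
    )
    n_parents = min(n_nested, n_top)

    # --- top-level vesicles: rejection sampling, no overlap between annuli
    for v_index in range(n_top):
        placed = False
        for _ in range(max_retries):
            spacing = sample_spacing()
            lo = max(radius_range_px[0], parent_lo) if v_index < n_parents else radius_range_px[0]
            radius = float(rng.uniform(lo, max(radius_range_px[1], lo + 1)))
            if radius <= spacing / pixel_size:
                continue
            cand = VesicleSpec(
                center=(0.0, 0.0),
                radius=radius,
                bilayer_spacing=spacing,
                contour_perturbation=contour_perturbation,
                fourier=sample_fourier(),
            )
            ext = footprint(cand) + border_margin_px
            if 2 * ext >= min(shape):
                continue
            row = float(rng.uniform(ext, shape[0] - ext))
            col = float(rng.uniform(ext, shape[1] - ext))
            cand.center = (row, col)
            ok = True
            for other in specs:
                sep = math.hypot(row - other.center[0], col - other.center[1])
                if sep < footprint(cand) + footprint(other) + 4.0:
                    ok = False
                    break
            if ok:
                specs.append(cand)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place top-level vesicle after {max_retries} attempts"
            )

    # --- nested vesicles: each inside a randomly chosen top-level parent
    top_indices = list(range(len(specs)))
    # smallest vesicles in the emulated data have ~50 nm perimeter
    min_radius = min_child_radius
    for _ in range(n_nested):
        placed = False
        for _ in range(max_retries):
            if not top_indices:
                break
            # fill childless parents first so high nested fractions pack
            unused = [
                i for i in top_indices
                if not any(s.parent == i for s in specs)
            ]
            pi = int(rng.choice(unused or top_indices))
            parent = specs[pi]
            spacing = sample_spacing()
            gap_px = float(rng.uniform(*enclosure_gap_range)) / pixel_size
            # keep the child annulus clear of the parent annulus so the
            # rendered masks stay separate connected components
            min_gap_px = (
                (spacing + parent.bilayer_spacing) / (2 * pixel_size)
                + 2 * mask_halfwidth_px
                + 4.0
            )
            gap_px = max(gap_px, min_gap_px)
            # parent inner clearance measured from its minimum radius
            parent_inner = parent.radius * (
                1.0 - sum(abs(a) for _, a, _ in parent.fourier)
            )
            r_max = parent_inner - gap_px - spacing / (2 * pixel_size) - margin
            if r_max <= max(min_radius, spacing / pixel_size):
                continue
            radius = float(rng.uniform(max(min_radius, spacing / pixel_size), r_max))
            # offset so the closest approach to the parent realizes the gap
            offset = max(parent_inner - radius - gap_px, 0.0)
            angle = rng.uniform(0, 2 * np.pi)
            cand = VesicleSpec(
                center=(
                    parent.center[0] + offset * math.sin(angle),
                    parent.center[1] + offset * math.cos(angle),
                ),
                radius=radius,
                bilayer_spacing=spacing,
                parent=pi,
            )
            # keep clear of sibling vesicles nested in the same parent
            ok = True
            for j, other in enumerate(specs):
                if other.parent == pi:
                    sep = math.hypot(
                        cand.center[0] - other.center[0],
                        cand.center[1] - other.center[1],
                    )
                    if sep < footprint(cand) + footprint(other) + 4.0:
                        ok = False
                        break
            if ok:
                specs.append(cand)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not nest vesicle after {max_retries} attempts"
            )

    # --- exact truth: perimeters and enclosure gaps from dense contours
    for spec in specs:
        spec.perimeter_nm = _contour_length_px(spec) * pixel_size / 10.0
        if spec.parent is not None:
            spec.enclosure_gap = (
                _min_contour_distance_px(spec, specs[spec.parent]) * pixel_size
            )

    # --- render intensity and mask
    intensity = np.zeros(shape, dtype=np.float64)
    mask = np.zeros(shape, dtype=np.uint8)
    for spec in specs:
        _render_vesicle(
            intensity, mask, spec, pixel_size, contrast, membrane_sigma_px,
            mask_halfwidth_px,
        )
    if noise_sigma > 0:
        intensity += rng.normal(0.0, noise_sigma, size=shape)
        intensity /= noise_sigma  # background: mean 0, s.d. 1

    return SyntheticField(
        intensity=intensity.astype(np.float32),
        mask=mask,
        pixel_size=pixel_size,
        truth=specs,
        seed=seed,
        contrast=contrast / noise_sigma if noise_sigma > 0 else contrast,
    )


def _render_vesicle(
    intensity: np.ndarray,
    mask: np.ndarray,
    spec: VesicleSpec,
    pixel_size: float,
    contrast: float,
    sigma_px: float,
    mask_halfwidth_px: float,
) -> None:
    half_sep = spec.bilayer_spacing / (2.0 * pixel_size)  # px
    ext = int(math.ceil(spec.max_radius() + half_sep + 4 * sigma_px + mask_halfwidth_px + 1))
    r0 = max(int(spec.center[0]) - ext, 0)
    r1 = min(int(spec.center[0]) + ext + 1, intensity.shape[0])
    c0 = max(int(spec.center[1]) - ext, 0)
    c1 = min(int(spec.center[1]) + ext + 1, intensity.shape[1])
    rows, cols = np.mgrid[r0:r1, c0:c1]
    dy = rows - spec.center[0]
    dx = cols - spec.center[1]
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    d = rho - spec.radius_at(theta)  # signed px distance to mid-contour
    dip = np.exp(-0.5 * ((d - half_sep) / sigma_px) ** 2) + np.exp(
        -0.5 * ((d + half_sep) / sigma_px) ** 2
    )
    intensity[r0:r1, c0:c1] -= contrast * dip
    mask[r0:r1, c0:c1] |= (np.abs(d) <= half_sep + mask_halfwidth_px).astype(np.uint8)


def threshold_segment(
    intensity: np.ndarray,
    contrast: float = 1.0,
    threshold_fraction: float = 0.4,
    smooth_sigma: float = 1.0,
    min_object_px: int = 30,
    fill_hole_px: int = 80,
) -> np.ndarray:
    """Classical threshold segmentation of a synthetic image into a membrane mask.

    Membranes are intensity minima, so the mask is where the smoothed image
    falls below ``-threshold_fraction · contrast``. Specks are removed
    (< ``min_object_px``) and pinholes punched into the membrane band by
    noise are filled (< ``fill_hole_px``; vesicle lumina are far larger and
    stay open). This is a fallback for synthetic images only; real
    micrographs require learned segmentation and enter the pipeline as
    precomputed masks.
    """
    from scipy.ndimage import binary_closing, gaussian_filter, label

    smoothed = gaussian_filter(np.asarray(intensity, dtype=float), smooth_sigma)
    raw = smoothed < (-threshold_fraction * contrast)
    structure = np.ones((3, 3), bool)
    cleaned = binary_closing(raw, structure=structure, iterations=1)
    labels, n = label(cleaned, structure=structure)
    if n:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        cleaned = np.isin(labels, np.flatnonzero(sizes >= min_object_px))
    holes, n_holes = label(~cleaned, structure=np.ones((3, 3), bool))
    if n_holes:
        hole_sizes = np.bincount(holes.ravel())
        hole_sizes[0] = 0
        cleaned |= np.isin(holes, np.flatnonzero(
            (hole_sizes > 0) & (hole_sizes < fill_hole_px)
        ))
    return cleaned.astype(np.uint8)


def generate_radial_profile(
    outer_radius: float,
    falloff: float = 2.0,
    leaflet_peaks: tuple[float, float] | None = None,
    noise_sigma: float = 0.0,
    *,
    step: float = 1.0,
    peak_amplitude: float = 0.5,
    peak_sigma: float = 4.0,
    seed: int = 0,
) -> RadialProfile:
    """Synthetic rotationally averaged rod profile, normalized to max 1.

    The base shape is a soft cylinder edge: intensity 1 inside
    ``outer_radius`` decaying over ``falloff`` Å (a hard step when falloff
    is 0). Optional Gaussian bumps at ``leaflet_peaks`` emulate the two
    bilayer leaflets of an engulfed membrane tube.
    """
    if outer_radius <= 0:
        raise ValueError("outer_radius must be positive")
    radii = np.arange(0.0, outer_radius * 1.5 + step, step)
    if falloff <= 0:
        base = (radii < outer_radius).astype(float)
    else:
        base = 1.0 / (1.0 + np.exp((radii - outer_radius) / falloff))
    if leaflet_peaks is not None:
        for peak in leaflet_peaks:
            if not (0.0 <= peak <= outer_radius):
                raise ValueError("leaflet peaks must lie within [0, outer_radius]")
            base += peak_amplitude * np.exp(-0.5 * ((radii - peak) / peak_sigma) ** 2)
    if noise_sigma > 0:
        base = base + np.random.default_rng(seed).normal(0, noise_sigma, radii.size)
    base = np.clip(base, 0.0, None)
    return RadialProfile(radii, base).normalized()


#: Default segment ranges of the toy monomer (inclusive residue ranges),
#: numbered to mimic the PspA fold: α1/α2 hairpin, α3, the α3/α4 loop
#: (hinge 2), α4, the α4/α5 loop (hinge 3) and α5.
DEFAULT_SEGMENT_MAP: dict[str, tuple[int, int]] = {
    "alpha1": (24, 80),
    "hairpin_tip": (81, 84),
    "alpha2": (85, 127),
    "hinge1": (128, 133),
    "alpha3": (134, 155),
    "loop34": (156, 165),
    "alpha4": (166, 186),
    "loop45": (187, 189),
    "alpha5": (190, 215),
}

#: Hairpin core used as the superposition reference (α1 + α2).
DEFAULT_HAIRPIN_RANGE: tuple[int, int] = (24, 127)

_HELIX_RISE = 1.5  # Å per residue along the axis
_HELIX_TWIST = math.radians(100.0)
_HELIX_RADIUS = 2.3  # Å


def _helix_points(start: np.ndarray, direction: np.ndarray, n: int,
                  phase: float = 0.0) -> np.ndarray:
    u = direction / np.linalg.norm(direction)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    i = np.arange(n)
    ang = phase + i * _HELIX_TWIST
    return (
        start[None, :]
        + np.outer(i * _HELIX_RISE, u)
        + _HELIX_RADIUS * (np.outer(np.cos(ang), v) + np.outer(np.sin(ang), w))
    )


def _connector(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    # n intermediate points strictly between a and b
    t = np.linspace(0.0, 1.0, n + 2)[1:-1]
    return a[None, :] + np.outer(t, b - a)


def default_toy_monomer() -> ToyMonomer:
    """Synthetic 200-residue hairpin-like Cα trace (residues 18–217).

    Four helical segments arranged as a flattened zig-zag resembling the
    elongated PspA monomer, with loops at the hinge positions. This is an
    idealized fixture for estimator validation, explicitly not the real
    PspA fold.
    """
    segments: list[np.ndarray] = []
    numbers: list[np.ndarray] = []

    def add(nums: np.ndarray, pts: np.ndarray) -> None:
        numbers.append(nums)
        segments.append(pts)

    # N-terminal flank 18-23 + alpha1 24-80 running +z
    a1 = _helix_points(np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]), 63)
    add(np.arange(18, 81), a1)
    # hairpin tip 81-84
    a2_start = a1[-1] + np.array([10.0, 0.0, 2.0])
    add(np.arange(81, 85), _connector(a1[-1], a2_start, 4))
    # alpha2 85-127 running back -z
    a2 = _helix_points(a2_start, np.array([0.0, 0.0, -1.0]), 43)
    add(np.arange(85, 128), a2)
    # hinge1 128-133: short loop continuing downward with slight x-shift
    a3_start = a2[-1] + np.array([4.0, 0.0, -8.0])
    add(np.arange(128, 134), _connector(a2[-1], a3_start, 6))
    # alpha3 134-155 tilted off -z
    a3_dir = np.array([math.sin(math.radians(20.0)), 0.0, -math.cos(math.radians(20.0))])
    a3 = _helix_points(a3_start, a3_dir, 22)
    add(np.arange(134, 156), a3)
    # loop34 156-165 (hinge 2): turn toward +z
    a4_start = a3[-1] + np.array([10.0, 0.0, 4.0])
    add(np.arange(156, 166), _connector(a3[-1], a4_start, 10))
    # alpha4 166-186 running +z, tilted
    a4_dir = np.array([math.sin(math.radians(15.0)), 0.0, math.cos(math.radians(15.0))])
    a4 = _helix_points(a4_start, a4_dir, 21)
    add(np.arange(166, 187), a4)
    # loop45 187-189 (hinge 3)
    a5_start = a4[-1] + np.array([9.0, 0.0, -3.0])
    add(np.arange(187, 190), _connector(a4[-1], a5_start, 3))
    # alpha5 190-215 running -z + C-terminal flank 216-217
    a5 = _helix_points(a5_start, np.array([0.1, 0.0, -1.0]), 28)
    add(np.arange(190, 218), a5)

    return ToyMonomer(
        np.concatenate(numbers), np.vstack(segments), dict(DEFAULT_SEGMENT_MAP)
    )


def generate_helical_assembly(
    monomer: ToyMonomer,
    sym: HelicalSymmetry,
    n_steps: int,
    radius: float,
) -> AssemblyModel:
    """Replicate a monomer with a rise/twist/Cn operator into an assembly.

    Chain ``k·n + c`` (helical step k, cyclic copy c) is the monomer placed
    at azimuth ``k·twist + c·360/n`` degrees and height ``k·rise`` Å, with
    the monomer centroid shifted to the given cylinder radius. Chain
    indexing is step-major, cyclic-copy-minor.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    base = monomer.coordinates - monomer.coordinates.mean(axis=0)
    base = base + np.array([radius, 0.0, 0.0])
    chains: dict[str, dict[int, np.ndarray]] = {}
    order: list[str] = []
    for k in range(n_steps):
        for c in range(sym.n):
            angle = math.radians(k * sym.twist + c * 360.0 / sym.n)
            rot = Rotation.from_euler("z", angle)
            placed = rot.apply(base) + np.array([0.0, 0.0, k * sym.rise])
            name = chain_name(k * sym.n + c)
            chains[name] = {
                int(num): placed[i]
                for i, num in enumerate(monomer.residue_numbers)
            }
            order.append(name)
    return AssemblyModel(chains, order, source="generate_helical_assembly",
                         rod_diameter=2 * radius)


def perturb_monomer(
    monomer: ToyMonomer,
    hinge: int,
    angle: float,
    axis: Sequence[float] | None = None,
) -> ToyMonomer:
    """Rigidly rotate all residues after ``hinge`` about an axis through its Cα.

    ``angle`` is in degrees. By default the rotation axis is the unit vector
    perpendicular to both the local chain direction at the hinge and the
    principal axis of the distal segment; because it is perpendicular to the
    distal axis, the injected angle equals the axis displacement measured
    downstream, and because it is computed from quantities invariant under
    the rotation itself, rotating by +θ then −θ restores the input exactly.
    """
    idx = monomer.index_of(hinge)
    if idx >= len(monomer) - 3:
        raise ValueError("hinge too close to the C terminus: distal segment empty")
    pivot = monomer.coordinates[idx]
    distal = monomer.coordinates[idx + 1 :]
    if axis is None:
        k = min(3, idx)
        tangent = pivot - monomer.coordinates[idx - k]
        axis_vec = _default_hinge_axis(tangent, distal)
    else:
        axis_vec = np.asarray(axis, dtype=float)
        axis_vec = axis_vec / np.linalg.norm(axis_vec)
    rot = Rotation.from_rotvec(np.radians(angle) * axis_vec)
    out = monomer.copy()
    out.coordinates[idx + 1 :] = rot.apply(distal - pivot) + pivot
    return out


def _default_hinge_axis(tangent: np.ndarray, distal: np.ndarray) -> np.ndarray:
    centered = distal - distal.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    principal = vt[0]
    if np.dot(principal, distal[-1] - distal[0]) < 0:
        principal = -principal
    axis = np.cross(tangent, principal)
    norm = np.linalg.norm(axis)
    if norm < 1e-8:
        # tangent parallel to distal axis: any perpendicular direction works
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, principal)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        axis = np.cross(principal, ref)
        norm = np.linalg.norm(axis)
    return axis / norm
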