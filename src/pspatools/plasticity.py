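"""Monomer conformational plasticity across rod diameter classes.

PspA-family rods of different diameters are built from the same fold in
different conformations. The analyses here quantify that plasticity:

* **superpose** — least-squares (Kabsch) superposition of paired Cα sets,
  used to align monomers on the α1/α2 coiled-coil hairpin;
* **hinge_angles** — displacement angles of the segments distal to the
  three hinge regions (α2/α3 transition, α3/α4 loop, α4/α5 loop) relative
  to a reference monomer;
* **end_to_end** — the Cα(G82)–Cα(P187) "bow" distance tracking monomer
  curvature;
* **contact_series** — Cα distances of inter-subunit residue pairs across
  the diameter series, classified fixed (s.d. of changes < 1 Å) or
  switching (> 1 Å);
* **helix_extent** — helical run length within a segment, tracking helix
  growth at the expense of connecting loops in wider rods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .models import AssemblyModel, ToyMonomer, load_model  # noqa: F401 (re-export)

__all__ = [
    "HingeDefinition",
    "ContactPair",
    "ContactSeries",
    "RigidTransform",
    "DEFAULT_HINGES",
    "FIXED_CONTACT_RESIDUES",
    "SWITCHING_CONTACT_RESIDUES",
    "load_model",
    "superpose",
    "hinge_angles",
    "end_to_end",
    "contact_series",
    "helix_extent",
    "helical_runs",
]


@dataclass(frozen=True)
class HingeDefinition:
    """A hinge: pivot residue range and the segment distal to it."""

    name: str
    pivot_range: tuple[int, int]
    distal_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.pivot_range[1] >= self.distal_range[0]:
            raise ValueError("distal range must start after the pivot range")


#: Default hinge definitions on the toy-monomer numbering. The pivot of
#: hinge 1 sits at the α2/α3 transition (residues 128–133); hinge 2 is the
#: α3/α4 loop (156–165); hinge 3 the short α4/α5 loop. Distal segments are
#: the helices immediately after each hinge.
DEFAULT_HINGES: tuple[HingeDefinition, ...] = (
    HingeDefinition("hinge1", (128, 133), (134, 155)),
    HingeDefinition("hinge2", (156, 165), (166, 186)),
    HingeDefinition("hinge3", (187, 189), (190, 215)),
)

#: Conserved residues whose inter-subunit contacts stay fixed across
#: diameters (s.d. of distance changes < 1 Å in the diameter series).
FIXED_CONTACT_RESIDUES = (71, 74, 88, 91, 196, 212, 44, 55, 125, 128, 138, 142, 168, 179)
#: Conserved residues whose contacts switch (s.d. > 1 Å).
SWITCHING_CONTACT_RESIDUES = (126, 170, 174)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation mapping query onto reference."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @property
    def angle_deg(self) -> float:
        return float(np.degrees(np.linalg.norm(
            Rotation.from_matrix(self.rotation).as_rotvec()
        )))


@dataclass(frozen=True)
class ContactPair:
    """An inter-subunit Cα pair: residue i in chain j0, residue k in chain j0+offset."""

    residue_i: int
    chain_offset: int
    residue_k: int

    def label(self) -> str:
        sign = "+" if self.chain_offset >= 0 else ""
        return f"{self.residue_i}/j{sign}{self.chain_offset}:{self.residue_k}"


@dataclass
class ContactSeries:
    """Distances of one contact pair across the diameter series."""

    pair: ContactPair
    class_labels: list[str]
    distances_A: np.ndarray
    changes_A: np.ndarray  # relative to the smallest-diameter class
    sd_A: float
    classification: str  # "fixed" | "switching"


def superpose(
    query: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of paired Cα sets (Kabsch).

    Returns the proper-rotation transform mapping ``query`` onto
    ``reference`` and the post-fit RMSD in Å. Reflections are never
    returned; mirror-related sets therefore keep a nonzero RMSD.
    """
    q = np.asarray(query, dtype=float)
    r = np.asarray(reference, dtype=float)
    if q.shape != r.shape or q.ndim != 2 or q.shape[1] != 3 or q.shape[0] < 3:
        raise ValueError("need matching (N>=3, 3) coordinate sets")
    qc, rc = q.mean(axis=0), r.mean(axis=0)
    q0, r0 = q - qc, r - rc
    s = np.linalg.svd(q0, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("points are collinear: rotation is degenerate")
    h = q0.T @ r0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = rc - rot @ qc
    transform = RigidTransform(rot, trans)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(q) - r) ** 2, axis=1))))
    return transform, rmsd


def _segment_axis(monomer: ToyMonomer, rng: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    coords = monomer.coords_for(*rng)
    if coords.shape[0] < 4:
        raise ValueError(f"segment {rng} has fewer than 4 residues: axis unstable")
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis, coords.mean(axis=0)


def hinge_angles(
    query: ToyMonomer,
    reference: ToyMonomer,
    hinges: Sequence[HingeDefinition] = DEFAULT_HINGES,
    hairpin_range: tuple[int, int] = (24, 127),
) -> dict[str, float]:
    """Signed hinge displacement angles (degrees) of query vs reference.

    Each hinge angle is measured in the frame of the chain segment proximal
    to that hinge: the query is superposed on the reference over the region
    from the previous hinge's distal segment (the α1/α2 hairpin for the
    first hinge) through the hinge pivot, and the displacement is the angle
    between the principal axes (oriented N→C) fitted to the distal-segment
    Cα of both monomers. Measuring in the proximal frame makes the angles
    local: a pure rotation at one hinge leaves the other hinges at zero.
    The sign is positive when the distal axis tips toward the reference's
    outward radial direction at the hinge (the direction from the reference
    centroid to the hinge, orthogonalized against the reference distal
    axis).
    """
    ordered = sorted(hinges, key=lambda h: h.pivot_range[0])
    align_ranges: dict[str, tuple[int, int]] = {}
    prev_start = hairpin_range[0]
    for hinge in ordered:
        align_ranges[hinge.name] = (prev_start, hinge.pivot_range[1])
        prev_start = hinge.distal_range[0]
    angles: dict[str, float] = {}
    ref_centroid = reference.coordinates.mean(axis=0)
    for hinge in hinges:
        transform, _ = superpose(
            query.coords_for(*align_ranges[hinge.name]),
            reference.coords_for(*align_ranges[hinge.name]),
        )
        aligned = query.copy()
        aligned.coordinates = transform.apply(aligned.coordinates)
        axis_q, _ = _segment_axis(aligned, hinge.distal_range)
        axis_r, seg_centroid = _segment_axis(reference, hinge.distal_range)
        pivot = reference.coords_for(*hinge.pivot_range).mean(axis=0)
        cosang = float(np.clip(np.dot(axis_q, axis_r), -1.0, 1.0))
        magnitude = np.degrees(np.arccos(cosang))
        radial = pivot - ref_centroid
        radial = radial - np.dot(radial, axis_r) * axis_r
        norm = np.linalg.norm(radial)
        if norm > 1e-9:
            radial /= norm
            sign = 1.0 if np.dot(axis_q - axis_r, radial) >= 0 else -1.0
        else:
            sign = 1.0
        angles[hinge.name] = float(sign * magnitude)
    return angles


def end_to_end(model: ToyMonomer, residue_a: int = 82, residue_b: int = 187) -> float:
    """Euclidean Cα–Cα distance (Å) between two residues of one monomer.

    Defaults to the 82–187 pair spanning the bow-shaped monomer; the
    distance grows as the monomer straightens.
    """
    a = model.coordinates[model.index_of(residue_a)]
    b = model.coordinates[model.index_of(residue_b)]
    return float(np.linalg.norm(a - b))


def contact_series(
    models: Sequence[AssemblyModel],
    pairs: Sequence[ContactPair],
    threshold_A: float = 1.0,
    base_chain: int | None = None,
    class_labels: Sequence[str] | None = None,
    population_sd: bool = True,
) -> list[ContactSeries]:
    """Inter-subunit contact distances across a diameter-ordered model series.

    For each pair, the Cα distance between residue_i of a base chain and
    residue_k of the chain ``chain_offset`` positions away is measured in
    every model; changes are taken relative to the first (smallest
    diameter) model and their s.d. classifies the contact as fixed
    (< threshold) or switching (>= threshold).
    """
    if not models:
        raise ValueError("need at least one model")
    labels = (
        list(class_labels)
        if class_labels is not None
        else [m.source or f"model{i}" for i, m in enumerate(models)]
    )
    results = []
    for pair in pairs:
        distances = []
        for label, model in zip(labels, models):
            bi = base_chain if base_chain is not None else model.n_chains // 2
            ji = bi + pair.chain_offset
            if not (0 <= bi < model.n_chains and 0 <= ji < model.n_chains):
                raise ValueError(
                    f"chain offset {pair.chain_offset} unavailable in model "
                    f"{label} for pair {pair.label()}"
                )
            ca_i = model.ca(model.chain_order[bi], pair.residue_i)
            ca_k = model.ca(model.chain_order[ji], pair.residue_k)
            distances.append(float(np.linalg.norm(ca_i - ca_k)))
        distances = np.array(distances)
        changes = distances - distances[0]
        sd = float(changes.std(ddof=0 if population_sd else 1))
        results.append(
            ContactSeries(
                pair=pair,
                class_labels=labels,
                distances_A=distances,
                changes_A=changes,
                sd_A=sd,
                classification="fixed" if sd < threshold_A else "switching",
            )
        )
    return results


def contact_table(series: Sequence[ContactSeries]) -> pd.DataFrame:
    """Flatten contact series into a tidy per-pair/per-class DataFrame."""
    rows = []
    for s in series:
        for label, dist, change in zip(s.class_labels, s.distances_A, s.changes_A):
            rows.append(
                {
                    "pair": s.pair.label(),
                    "class": label,
                    "distance_A": dist,
                    "change_A": change,
                    "sd_A": s.sd_A,
                    "classification": s.classification,
                }
            )
    return pd.DataFrame(rows)


def helical_runs(
    model: ToyMonomer,
    segment: tuple[int, int],
    window_A: tuple[float, float] = (5.9, 6.7),
) -> list[tuple[int, int]]:
    """Maximal runs of helical geometry within a residue segment.

    A residue stretch is helical where the Cα(i)→Cα(i+4) distance lies in
    ``window_A`` (the i,i+4 hydrogen-bonding geometry of an α-helix); a run
    covers the residues spanned by consecutive helical i..i+4 windows.
    """
    start, stop = segment
    sel = (model.residue_numbers >= start) & (model.residue_numbers <= stop)
    nums = model.residue_numbers[sel]
    coords = model.coordinates[sel]
    if nums.size < 7:
        raise ValueError("segment must contain at least 7 residues")
    helical_i = []
    for i in range(nums.size - 4):
        if nums[i + 4] - nums[i] != 4:
            continue  # numbering gap
        d = np.linalg.norm(coords[i + 4] - coords[i])
        if window_A[0] <= d <= window_A[1]:
            helical_i.append(i)
    runs: list[tuple[int, int]] = []
    for i in helical_i:
        lo, hi = int(nums[i]), int(nums[i + 4])
        if runs and lo <= runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], max(runs[-1][1], hi))
        else:
            runs.append((lo, hi))
    return runs


def helix_extent(
    model: ToyMonomer,
    segment: tuple[int, int],
    window_A: tuple[float, float] = (5.9, 6.7),
) -> tuple[int, int] | None:
    """Longest contiguous helical run within ``segment`` (None if none)."""
    runs = helical_runs(model, segment, window_A)
    if not runs:
        return None
    return max(runs, key=lambda r: r[1] - r[0])
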