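# Methods

This note documents the models, estimators and numerical choices behind
`pspatools`, what the synthetic-data generators do and do not emulate, and
the design decisions taken where several reasonable conventions exist.

## Vesicle morphometrics

**Input model.** The membrane analyses consume a binary segmentation mask
(and optionally the grayscale image behind it) at a known pixel size; the
default scale is 7 Å/px, the scale at which the emulated micrographs were
segmented. Producing masks from real micrographs (learned segmentation) is
outside the package; a classical threshold fallback exists for synthetic
images only.

**Skeletons and traces.** Each connected component of the morphological
skeleton (scikit-image thinning; no particular algorithm is canonical here)
becomes one candidate membrane. Pixels are nodes of an 8-adjacency graph in
which diagonal edges that shortcut an existing 4-neighbour are dropped, so a
clean closed curve has degree 2 everywhere. Spurs shorter than `prune_px`
(default 10 px) are removed; any component still containing more than
`max_branch_nodes` (default 0) junction pixels is discarded as ambiguous —
this is the mechanism that drops aggregated/overlapping membrane regions.
Remaining components are walked into ordered traces; only closed traces
(cycles) are analysed as vesicles.

**Perimeter.** The perimeter is the summed Euclidean distance between
neighbouring trace points (× pixel size, reported in nm). A raw 8-connected
pixel path systematically overestimates the length of a smooth curve by
~5% (the classic digital-length bias: a staircase is longer than its
chord). Before summing, the ordered trace is therefore smoothed with a
short circular moving average (5 points; skipped for traces too short to
support it), which removes the quantization at negligible cost in shape
fidelity — on rasterized circles with radius ≥ 20 px the residual error is
a few tenths of a percent. `smooth_window=1` restores the raw estimator.
The equivalent diameter reported in summaries is perimeter/π.

**Nesting and enclosure distance.** Vesicle A is enclosed by vesicle B when
*all* of A's skeleton points fall inside the closed polygon of B's trace
(even-odd rule via shapely); a majority-rule variant is available as a
config switch. Strict containment makes the nesting relation acyclic by
construction (area strictly decreases along any chain). The counted
*double-membrane vesicle* is the inner (enclosed) one; the fraction uses
all closed vesicles as denominator. The enclosure distance is the minimum
point-pair distance between the two skeletons (KD-tree), in Å.

**Bilayer thickness.** For every skeleton point the image is sampled by
bilinear interpolation along the local membrane normal (perpendicular to
the secant through neighbours ±3 points away) over ±`half_width` (default
60 Å) in 0.5 px steps. Profiles are averaged along the trace; the bilayer
appears as two intensity minima (membranes are dark in this contrast
convention). The two lowest local minima whose separation falls in the
plausible window (default 20–100 Å, covering the 27–68 Å range seen in the
emulated data) are refined with 3-point parabolas; their separation is the
thickness. Vesicles with fewer than two usable minima (single dark ring) or
insufficient border clearance record no thickness and are counted as such.

## Synthetic vesicle fields

The generator renders each vesicle as a mid-membrane contour — a circle,
optionally perturbed by low-order (k = 2–4) Fourier modes — with two
Gaussian intensity dips (σ = 1 px) at ±spacing/2 along the contour normal,
i.e. a two-leaflet bilayer whose minima sit exactly one bilayer spacing
apart. Background noise is white Gaussian; with noise the image is
rescaled so the background has mean 0 and s.d. 1, making contrast/σ the
SNR. The mask is the annulus |d| ≤ spacing/2 + 1.5 px around the contour.

Ground truth is exact and computed independently of the rendering path:
perimeters by dense polygonal integration of the analytic contour (4096
vertices), enclosure distances by nearest-neighbour search between dense
contours. Defaults follow the emulated study conditions: pixel size 7 Å,
bilayer spacings drawn from N(38 Å, 4 Å) truncated to 25–55 Å, vesicle
radii 18–45 px (mid-range of the ~100 nm-perimeter SUV population),
enclosure gaps sampled at 50–80 Å but clamped up to the smallest value that
keeps child and parent annuli as separate mask components (≈70–80 Å at
7 Å/px), nested children at least ~10 px in radius (≈50 nm perimeter).
Placement is rejection sampling with a bounded retry count (default 1000);
failure raises an explicit placement error. Vesicles destined to host a
child are drawn from the upper radius range so requested nested fractions
up to 0.5 are realizable.

What the generator does **not** emulate: electron-optical effects (CTF,
dose, detector MTF), realistic protein density, membrane deformations at
contact sites, or segmentation errors of a learned model. Passing the
recovery suites therefore validates the estimators' geometry and
numerics — not robustness to real-micrograph artefacts.

The threshold-segmentation fallback (smooth, threshold at a fraction of the
known contrast, despeckle, fill pinholes smaller than a vesicle lumen) is a
synthetic-image convenience standing in for the segmentation step; at SNR 5
it recovers ~85–90% of vesicles, and its losses are close to unbiased with
respect to nesting, which is what the binomial-CI check on the
double-membrane fraction quantifies.

## Rod diameters and lattice geometry

**Radial profiles.** 2D images (or 3D maps, averaged along the helical
axis) are binned by radius with bin width = pixel size and normalized to
max 1. Diameter readout finds the *outermost* falling-edge crossing of the
intensity cutoff (default 0.3) with linear interpolation between bins —
outermost so that luminal density (rods engulfing narrower rods) cannot
shrink the measured diameter of the outer wall. Radii of profiles from the
same symmetry class are averaged before conversion; diameters are rounded
half-up to 5 Å increments. Leaflet radii of engulfed membrane tubes are the
two highest local maxima, parabola-refined.

**Lattice arithmetic.** For a class with symmetry (Cn, rise Δz, twist Δφ):
per-ASU rise = Δz/n; MPL = n·m/Δz with m = 25.3 kDa by default; a rod of
length L holds L·n/Δz monomers. The shipped table
(`pspatools/data/atp_symmetry_classes.csv`) lists the 11 diameter classes
(180–365 Å) of the nucleotide-incubated sample; across it the per-ASU rise
decreases strictly with diameter and MPL grows linearly (Pearson r ≈ 0.998).
`neighbor_offsets` enumerates chain-index offsets k (step-major,
cyclic-copy-minor indexing — the deposition's chain-numbering convention is
not fixed anywhere, so distances are reported ranked rather than asserting
particular indices) and scores them by the chord distance on the cylinder,
√((2R sin(Δφₖ/2))² + (kΔz)²).

## Monomer plasticity

**Superposition** is the standard Kabsch/orthogonal-Procrustes solution via
SVD with the determinant correction, so reflections are never returned;
collinear point sets are rejected. Monomers are aligned on the α1/α2
coiled-coil hairpin (default residues 24–127 in the toy numbering).

**Hinge angles.** Three hinges are defined by pivot and distal residue
ranges (defaults: pivot 128–133 with distal α3; pivot 156–165 — the
deletable α3/α4 loop — with distal α4; the short α4/α5 loop with distal
α5; all config-overridable since exact helix boundaries are approximate).
Each hinge's displacement is measured *in the frame of its proximal
segment*: the query is superposed on the reference from the previous
hinge's distal start through the pivot, and the angle between the
principal axes (oriented N→C) of the distal segments is reported. This
local convention makes a pure rotation at one hinge read zero at the
others, which is the behaviour a hinge decomposition needs; measuring all
axes in one global hairpin frame would alias upstream rotations into
downstream hinges. The sign convention — positive when the distal axis
tips toward the reference's outward radial direction at the hinge — is one
of several defensible choices; angles are comparable within a series but
only up to a global sign against other conventions.

**Contacts.** For a diameter-ordered model series, each contact pair
(residue i, chain offset, residue k) yields one Cα distance per model;
changes are taken relative to the first (smallest-diameter) class and
their population s.d. (switchable to sample s.d.; the convention is not
fixed by the domain) classifies the pair: fixed < 1 Å ≤ switching. The
conserved-residue defaults seed the residues known to hold fixed
(W71/K74/R88/L91/F196/M212, R44/K55/L125/K128/L138/R142, F168/E179) and
switching (E126/R170/K174) contacts; partner residues are user
configuration.

**Helix extent** marks residue windows whose Cα(i)→Cα(i+4) distance lies
in 5.9–6.7 Å (the i,i+4 geometry of an α-helix) and reports maximal runs,
which tracks helix growth at the expense of connecting loops.

**Toy monomer.** A synthetic 200-residue Cα trace (numbered 18–217) built
from ideal helices (rise 1.5 Å, twist 100°, radius 2.3 Å) arranged as a
hairpin plus two back-folded helices with loops at the hinge positions. It
is deliberately *not* the real fold: it exists so that hinge, bow-distance
and contact estimators can be validated against exactly known injected
perturbations. `perturb_monomer` rotates everything distal to a hinge
about an axis perpendicular to both the local chain direction and the
distal principal axis, so the injected angle equals the measurable axis
displacement and the operation is exactly invertible.

## Biochemistry statistics

Activity is Δ[Pi]/([Protein]·Δt) in h⁻¹ (µM, µM, hours). Standard curves
are ordinary least squares; inversion subtracts the assay background then
the intercept. Group comparisons report mean ± s.e.m. (sample s.d./√n),
10th/90th percentiles by linear interpolation, and flag values outside the
whiskers as outliers. The two-sample t-test is Welch's (unequal variance)
by default — the plain "two-sample t-test" convention leaves this open, and
Welch is the safer default; pooled variance is a switch. Degenerate
zero-variance pairs with equal means return p = 1. The local-turnover
helper scales a bulk rate by an amplification factor (e.g. 3 h⁻¹ × 1000 =
3000 h⁻¹ = 50 min⁻¹) to express per-active-site turnover when only a small
fraction of lattice sites hydrolyse.

## Pipeline

`pspatools run --config <yaml>` executes the stages simulate →
morphometrics → rods → plasticity → biochem on a validated (pydantic)
configuration, writing per-stage CSV/JSON under `out/<stage>/` plus a
manifest with the config hash (output location excluded), package version,
seed and per-stage status. Identical configs reproduce byte-identical
stage outputs; the manifest differs only in its timestamp.

## Problem sizes and limitations

The validation suites run at desk scale: 60-vesicle noiseless fields
(1800²), one 200-vesicle field at SNR 5 (2800²), an 18-point
spacing×pixel-size thickness grid, 2,000-replicate t-test calibration.
Empirical distributions of the emulated study (thickness histograms,
double-membrane fractions per sample, mutant activity levels) require the
original micrographs or deposited models and are not reproduced here; the
optional checks against deposited structures (hinge-2 span, bow-distance
trend) are likewise gated on obtaining those files. Known limitations:
2D analysis only; skeleton-based perimeters assume 1-px-wide connected
segmentations; thickness assumes locally parallel leaflets within the
sampling half-width; `neighbor_offsets` treats chains as cylinder points
(centroid level), not atomic interfaces.
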