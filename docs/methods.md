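# Methods

This note documents the models implemented in `leafgas`, the choices
made where the methods literature leaves latitude, and what the
synthetic generators do and do not emulate.

## Segmented volumes and anatomical traits

Input volumes are 3D label stacks (axes `z, y, x`, `z` adaxial to
abaxial, isotropic voxel size in µm) with seven classes: background,
adaxial/abaxial epidermis, mesophyll cells, intercellular airspace
(IAS), bundle sheath extensions (BSE) and veins.

**Porosity.** θ_IAS = N_IAS / (N_IAS + N_mes-cell). BSE and vein voxels
are excluded from both numerator and denominator: θ_IAS is a property of
the photosynthetic mesophyll, and the BSE share is reported separately
as a cross-sectional percentage, 100·N_BSE/(N_BSE+N_cell+N_IAS),
averaged over slices that contain mesophyll cells or BSE. Whether veins
belong in that denominator is genuinely ambiguous; they are excluded
here (they are embedded in the BSE slabs and small), and the choice is
localized in `bse_area_fraction`. The identity V_IAS/V_mes-cell =
θ/(1−θ) holds to machine precision by construction and is asserted in
tests.

**Depth profiles.** The porosity-depth profile normalizes depth per
(y,x) column to that column's mesophyll extent (epidermes excluded), so
tilted or locally thinned leaves bin consistently. Because every
counted voxel falls in exactly one bin, the voxel-weighted mean of the
bins reproduces the scalar porosity exactly — a conservation property
the tests check at 1e-12.

**Surface area.** SA_mes/V_mes uses a marching-cubes isosurface of the
mesophyll-cell indicator, lightly Gaussian-smoothed (σ = 1 voxel)
first: both naive face counting and marching cubes on the raw binary
mask overestimate curved interfaces through the voxel staircase (≈ +9%
for a sphere of radius 25 voxels), whereas the smoothed 0.5-level
surface is within ~0.3%. The volume is padded by edge replication so
crop faces generate no surface, and triangles whose centroid falls in
the padding are discarded. Marching cubes cannot attribute a surface
patch to a specific neighbouring label, so the total cell-boundary area
is scaled by the 6-neighbour face-count fraction of the boundary that
touches IAS. The sphere and axis-aligned-plane oracles (5% and 2%)
bound the error of the whole scheme.

**Thicknesses** are per-column z-extents averaged over columns that
intersect the leaf; measurement is axis-aligned (a tilted leaf reads
long by 1/cos of the tilt, which is the convention for flat mounted
sections). **Paradermal palisade diameter** labels in-plane connected
mesophyll-cell components at the requested depth fractions and reports
the mean equivalent-circle diameter of components ≥ 10 voxels; cells
clipped by the field of view or by BSE/vein slabs are excluded because
partial profiles bias the diameter downward.

## Diffusion geometry

`L_geo` is the shortest within-IAS path from the nearest stomate,
computed exactly on the 26-neighbour voxel lattice (edge weights 1, √2,
√3 × pitch) by Dijkstra-equivalent propagation (`skimage.graph`'s
minimum-cost-path). Tests verify bit-level agreement with an
independent sparse-graph Dijkstra oracle on dozens of random phantoms.

The lattice metric overestimates true Euclidean length by a
direction-dependent amount of up to ~11% in 3D, so a raw
(L_geo/L_Euc)² would read well above 1 even in empty space. Tortuosity
is therefore evaluated as the ratio of the *obstructed* to the
*unobstructed* lattice shortest path between the same endpoints — both
carry the same directional bias, which cancels, and an obstacle-free
slab gives τ = 1 exactly. The stored `l_euc` field itself remains the
exact Euclidean distance transform to the nearest stomate, and `l_epi`
is the Euclidean distance to the abaxial-epidermis inner surface. The
epidermis feature set includes the stomatal seed voxels: seeds sit in
perforations of the epidermis, and including them restores the intact
surface (and makes λ = 1 exact when stomata tile the whole surface).

τ_leaf and λ_leaf are voxel-weighted means over IAS voxels 6-adjacent
to mesophyll cells ("edge of mesophyll cells"); IAS unreachable from
any stomate is excluded from the means and its fraction is reported
(`reachable_fraction`). When a volume has no cell/IAS interface at all
(an all-airspace test slab), the mean falls back to all IAS voxels with
a warning.

**g_IAS.** θ·D_m/(0.5·L_mes·τ·λ) has units m s⁻¹; it is multiplied by
the ideal-gas molar density P/(RT) to report mol m⁻² s⁻¹ bar⁻¹
(defaults 298.15 K, 1 bar, D_m = 1.54e-5 m² s⁻¹ for CO₂ in air at
25 °C, all overridable). The half-thickness path length is the standard
hypostomatous assumption. The gas-phase share of the mesophyll
resistance is g_m/g_IAS with both on a molar basis. The porous-medium
picture ignores the assimilation-gradient "path shortening" effect, so
computed g_IAS responses to anatomy should be read as potential changes.

## Isotope-based mesophyll conductance

All discriminations are kept in ‰ throughout. Fractionation constants
are stored as positive magnitudes (a = 4.4, a_b = 2.9, a_i = 1.8,
b = 29, f = 11.6 ‰): the predicted-discrimination and photorespiration
expressions require positive magnitudes to produce positive
discrimination, even though sign conventions in the literature
sometimes attach minus signs to b and f. The respiratory fractionation
e is not a constant but the per-record offset δ¹³C_e − δ¹³C_atm
(respired carbon was fixed from greenhouse air, default δ¹³C_atm =
−8‰). The ternary correction uses (1 + a′/1000): a′ is ‰ and the
correction needs the fractional form.

The estimator computes ζ, Δo, a′, t, Δi, Δe, Δf and then
g_m = [(1+t)/(1−t)]·[b − a_i − e·R_d/(A_n+R_d)]·(A_n/C_a)/(Δi−Δo−Δe−Δf).
The identity Δgm = Δi−Δo−Δe−Δf holds exactly in every result. A
non-positive residual denominator is reported as a flagged
`gm_unresolvable` result, never as a negative conductance; a negative
C_c = C_i − A_n/g_m is likewise flagged. Transpiration arrives in CSV
as mmol m⁻² s⁻¹ (the instrument unit) and is converted internally.
R_d is taken as supplied, with no light-correction applied.
`bracket_reference_d13c` implements the alternating reference/plant
vial protocol: each plant sample is paired with the mean of its two
bracketing reference samples, with a single-neighbour fallback at
sequence ends.

The forward simulator is the exact algebraic inverse of this chain: it
computes Δi, Δe, Δf and Δgm from a chosen true g_m, sets
Δo = Δi − Δgm − Δe − Δf, and solves the observed-discrimination
relation for δ¹³C_a before adding i.i.d. Gaussian noise (the only noise
source; real instruments also drift). At zero noise the round trip is
exact to ~1e-15. The default cuvette state (C_a 400, C_i 280, C_e 460
µmol mol⁻¹, A_n 14, R_d 1.5 µmol m⁻² s⁻¹, E 2 mmol m⁻² s⁻¹, g_act
0.25 mol m⁻² s⁻¹, Γ* 40 µmol mol⁻¹, δ¹³C_e −35‰) describes a
well-watered broadleaf in a low-flow cuvette: at ~150 µmol s⁻¹ flow a
14 µmol m⁻² s⁻¹ leaf draws the reference air down by ~60 µmol mol⁻¹,
which sets ζ ≈ 7.7 and hence a realistic noise amplification. Because
g_m enters through 1/Δgm, δ-noise produces a small convexity (Jensen)
bias in the mean recovered g_m — ~1% under the default conditions —
which the tests bound at 2%.

## FvCB A–Ci model

A_n = min(W_c, W_j) − R_d with W_c = V_cmax(C_i−Γ*)/(C_i+K_m) and
W_j = J(C_i−Γ*)/(4C_i+8Γ*); J is the electron transport rate at the
measurement irradiance and equals J_max under saturating light (the
simulated curves assume saturating light). K_m = K_c(1+O/K_o) defaults
to the standard 25 °C tobacco kinetics (710.3 µmol mol⁻¹); TPU
limitation is not modelled. Fitting minimizes least squares over the
hard minimum of the two limitations jointly — no pre-assignment of
points to regimes — from a small multi-start (anchor-point inversions
at C_i ≈ 150 and at the highest C_i, plus perturbations); the kink in
the hard minimum is benign for trust-region least squares and makes the
noise-free round trip exact, which a smoothed minimum would not.
Points are labelled Rubisco- or RuBP-limited by the smaller limitation
at the optimum; if a curve never leaves one regime the unidentified
parameter is flagged rather than silently reported.

## Hydraulics, stomata, statistics

K_leaflet = E/(Ψ_bagged − Ψ_unbagged) (mmol m⁻² s⁻¹ MPa⁻¹): the bagged
leaflet equilibrates with the xylem, so the difference is the
transpiration driving gradient; a negative gradient is flagged with a
warning rather than rejected. The anatomical maximum stomatal
conductance uses the perforated-plate diffusion form g_smax =
(d_w/v)·SD·a_max/[l + (π/2)√(a_max/π)] with the maximal pore area as an
ellipse on the inner pore length and width, and pore depth taken as a
single guard-cell width (a conventional anatomical proxy; the true
depth is rarely measured). d_w = 2.49e-5 m² s⁻¹ and v = 0.0224 m³
mol⁻¹ are overridable.

Pairwise comparison uses Welch two-sample t-tests for all group pairs
judged against α/n_pairs (reported rounded to 4 decimals: 0.05 over 6
pairs → 0.0083); Welch is chosen because equal variances across
species × treatment groups is not defensible. Percent changes are
reported per species relative to the well-watered mean. This
deliberately replaces mixed-model inference: with few ramets per group
the fixed-effects pairwise convention is transparent and reproducible,
at the cost of ignoring plant-level random effects.

## Fluorescence profiles

All outputs are relative (profile maximum = 100%): absolute epi-
illumination fluorescence is not comparable across samples because of
exposure differences and Kautsky decay. Depth profiles average masked
intensity over a strip (default 75 px wide, configurable 50–100) with
per-column normalization of depth to the mesophyll extent; empty bins
are interpolated from neighbours with a warning. BSE-proximity
profiles bin masked intensity by signed lateral distance from each BSE
center, normalize per BSE before averaging (so a bright BSE does not
dominate), and renormalize. Bin assignment is half-open, so an exact
mirror symmetry test must avoid distances landing precisely on bin
edges.

## Synthetic leaf phantoms

The phantom emulates a hypostomatous, heterobaric broadleaf:

* **Layers** (defaults, µm): adaxial epidermis 20, palisade 100, spongy
  80, abaxial epidermis 15, at 2 µm voxels on a 120×128×128 grid.
  Realized thicknesses are rounded to whole voxels and recorded in the
  ground truth.
* **Palisade**: vertical cylinders (default diameter 30 µm) on a
  hexagonal lattice whose spacing is bisected until the rasterized
  porosity matches the target (default 0.2); the truth records the
  equivalent-circle diameter of the rasterized disk. Cylinders must be
  separated by at least one voxel to be recovered individually — at
  2 µm voxels this limits how dense a palisade the diameter estimator
  can resolve, as with real scans.
* **Spongy**: a Gaussian-smoothed noise field (correlation length 8 µm)
  thresholded at the porosity quantile, which hits the target fraction
  exactly up to ties (default 0.4).
* **BSEs**: full-depth slabs joining the epidermes every 60 µm (width
  5 µm) with an embedded vein cylinder — this compartmentalizes the
  airspace laterally, the defining feature of heterobaric leaves.
* **Stomata**: elliptical through-pores of the abaxial epidermis
  (20×8 µm) at the requested density (default 62 mm⁻²), allocated per
  BSE compartment in proportion to its width — real leaves feed every
  compartment — and connected upward to the airspace by a short carved
  channel. In small test fields a compartment may still receive no
  stomate (the density is honoured, not inflated); the unreachable
  airspace fraction is then reported rather than hidden.

All truth fields are recomputed by direct counting on the emitted
volume, so truth consistency is exact by construction and the
interesting checks are generator-vs-target (porosity within ±0.02) and
extractor-vs-truth (thicknesses and diameters within a voxel, BSE share
within 0.5 points).

What the phantom does **not** emulate: grayscale CT physics and
segmentation error, cell-wall thickness, chloroplast placement,
anisotropic cell shapes, and real spongy topology (blob fields
percolate differently from armed spongy cells). Passing recovery tests
therefore demonstrates correctness of the measurement pipeline on known
geometry, not robustness to segmentation noise.

## Problem sizes

Tests and the acceptance script run phantoms at 64³–120×128² voxels
with stomatal densities scaled so that several stomata fall inside the
small lateral fields; these sizes were chosen so that the exact-graph
Dijkstra cross-checks and Monte-Carlo recoveries complete in seconds
per case while keeping every phantom large enough for sub-voxel
tolerances to be meaningful.
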