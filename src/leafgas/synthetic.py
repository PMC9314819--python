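"""Seeded synthetic inputs with known ground truth for every pipeline stage.

Four generators stand in for the study's raw data:

* :func:`generate_leaf_volume` -- a segmented leaf "phantom" with layered
  anatomy (epidermes, palisade of vertical cylinders, spongy blob field),
  bundle-sheath-extension slabs with embedded veins, and stomatal
  perforations of the abaxial epidermis.  Layer porosities are tuned to
  the requested targets, and every ground-truth field is recomputed by
  direct voxel counting on the emitted volume.
* :func:`generate_isotope_records` -- forward-simulated gas-exchange /
  13C-discrimination records for a chosen true mesophyll conductance,
  obtained by running the discrimination bookkeeping forwards and
  inverting the observed-discrimination relation for the plant-air
  isotope ratio.
* :func:`generate_fluorescence_image` -- leaf cross-section fluorescence
  images with a prescribed depth profile and optional lateral bright
  halos around bundle sheath extensions.
* :func:`generate_aci_curve` -- FvCB A-Ci response curves.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from . import isotope as iso
from .optics import FluorImage
from .physiology import fvcb_assimilation, michaelis_km
from .volume import DEFAULT_LABELS, LabeledVolume

__all__ = [
    "LeafPhantomParams",
    "LeafPhantomTruth",
    "generate_leaf_volume",
    "IsotopeSimParams",
    "generate_isotope_records",
    "SimulationError",
    "generate_fluorescence_image",
    "generate_aci_curve",
    "slab_phantom",
]


class SimulationError(ValueError):
    """A forward simulation cannot be carried out for these parameters."""


# ---------------------------------------------------------------------------
# leaf phantom


@dataclass(frozen=True)
class LeafPhantomParams:
    """Geometry and composition of the synthetic leaf.

    Default anatomy is walnut-like: ~215 um leaf with a 100 um palisade
    over an 80 um spongy layer, hypostomatous with ~62 stomata mm-2,
    narrow full-depth BSE slabs joined to vein cylinders.  Thicknesses in
    um; porosities are fractions in [0, 1).
    """

    shape: tuple[int, int, int] = (120, 128, 128)  # (nz, ny, nx) voxels
    voxel_size_um: float = 2.0
    thickness_epidermis_adaxial: float = 20.0
    thickness_palisade: float = 100.0
    thickness_spongy: float = 80.0
    thickness_epidermis_abaxial: float = 15.0
    porosity_palisade: float = 0.2
    porosity_spongy: float = 0.4
    palisade_diameter_um: float = 30.0
    stomatal_density_mm2: float = 62.0
    stomatal_pore_length_um: float = 20.0
    stomatal_pore_width_um: float = 8.0
    bse_spacing_um: float | None = 60.0
    bse_width_um: float = 5.0
    vein_diameter_um: float = 20.0
    spongy_blob_sigma_um: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        nz, ny, nx = self.shape
        vox = self.voxel_size_um
        if vox <= 0:
            raise ValueError("voxel size must be positive")
        thicknesses = (
            self.thickness_epidermis_adaxial,
            self.thickness_palisade,
            self.thickness_spongy,
            self.thickness_epidermis_abaxial,
        )
        if any(t <= 0 for t in thicknesses):
            raise ValueError("all layer thicknesses must be positive")
        if sum(thicknesses) > nz * vox:
            raise ValueError(
                "infeasible geometry: sum of layer thicknesses exceeds volume depth"
            )
        for name in ("porosity_palisade", "porosity_spongy"):
            p = getattr(self, name)
            if not (0.0 <= p < 1.0):
                raise ValueError(f"infeasible geometry: {name} must lie in [0, 1)")
        if self.palisade_diameter_um <= 0 or self.palisade_diameter_um > min(ny, nx) * vox:
            raise ValueError(
                "infeasible geometry: palisade cylinder diameter must be positive "
                "and fit within the lateral extent"
            )
        if self.stomatal_density_mm2 < 0:
            raise ValueError("stomatal density must be nonnegative")
        if self.stomatal_pore_length_um > nx * vox or self.stomatal_pore_width_um > ny * vox:
            raise ValueError("infeasible geometry: stomatal pore exceeds lateral extent")
        if self.bse_spacing_um is not None and self.bse_width_um >= self.bse_spacing_um:
            raise ValueError("infeasible geometry: BSE width must be below BSE spacing")
        if self.vein_diameter_um > self.thickness_palisade + self.thickness_spongy:
            raise ValueError(
                "infeasible geometry: vein diameter exceeds mesophyll thickness"
            )


@dataclass(frozen=True)
class LeafPhantomTruth:
    """Ground truth recomputable by direct counting on the emitted volume."""

    porosity_palisade: float
    porosity_spongy: float
    porosity_mesophyll: float
    thickness_epidermis_adaxial: float
    thickness_palisade: float
    thickness_spongy: float
    thickness_epidermis_abaxial: float
    thickness_leaf: float
    thickness_mesophyll: float
    bse_area_fraction_pct: float
    stomate_centers: np.ndarray  # (n, 3) voxel coordinates (z, y, x)
    palisade_diameter_um: float  # equivalent-circle diameter of the rasterized cylinder


def _hex_centers(spacing: float, ny_um: float, nx_um: float) -> np.ndarray:
    """Hexagonal lattice points covering the (padded) lateral field, in um."""
    dy = spacing * math.sqrt(3.0) / 2.0
    rows = np.arange(-spacing, ny_um + spacing, dy)
    pts = []
    for i, y in enumerate(rows):
        offset = (spacing / 2.0) if (i % 2) else 0.0
        xs = np.arange(-spacing + offset, nx_um + spacing, spacing)
        pts.append(np.column_stack([np.full_like(xs, y), xs]))
    return np.concatenate(pts, axis=0)


def _palisade_lateral_mask(
    spacing: float, radius_um: float, ny: int, nx: int, vox: float
) -> np.ndarray:
    """Boolean (ny, nx) mask of cell material for cylinders on a hex lattice."""
    centers = _hex_centers(spacing, ny * vox, nx * vox)
    yy, xx = np.meshgrid(
        (np.arange(ny) + 0.5) * vox, (np.arange(nx) + 0.5) * vox, indexing="ij"
    )
    pix = np.column_stack([yy.ravel(), xx.ravel()])
    dist, _ = cKDTree(centers).query(pix, k=1)
    return (dist <= radius_um).reshape(ny, nx)


def _solve_palisade_spacing(
    target_porosity: float, radius_um: float, ny: int, nx: int, vox: float
) -> np.ndarray:
    """Bisect the lattice spacing so the rasterized porosity hits the target."""
    d = 2.0 * radius_um
    lo, hi = 0.5 * d, 6.0 * d
    best_mask, best_err = None, np.inf
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        mask = _palisade_lateral_mask(mid, radius_um, ny, nx, vox)
        porosity = 1.0 - mask.mean()
        err = porosity - target_porosity
        if abs(err) < best_err:
            best_mask, best_err = mask, abs(err)
        if err > 0:
            hi = mid
        else:
            lo = mid
    return best_mask


def generate_leaf_volume(
    params: LeafPhantomParams,
) -> tuple[LabeledVolume, LeafPhantomTruth]:
    """Emit a 7-class labeled leaf volume and its counted ground truth.

    Palisade is modeled as vertical cylinders of the requested diameter on
    a hexagonal lattice whose spacing is bisected to the target porosity;
    the spongy layer is a Gaussian-smoothed blob field thresholded at the
    target porosity quantile.  Stomata are through-pores of the abaxial
    epidermis connected upward to the airspace by a short carved channel.
    """
    nz, ny, nx = params.shape
    vox = params.voxel_size_um
    rng = np.random.default_rng(params.seed)
    L = DEFAULT_LABELS
    labels = np.zeros(params.shape, dtype=np.uint8)

    # layer boundaries in voxels (realized thicknesses may differ from the
    # requested um values by rounding; truth records the realized ones)
    t_adx = max(1, round(params.thickness_epidermis_adaxial / vox))
    t_pal = max(1, round(params.thickness_palisade / vox))
    t_spo = max(1, round(params.thickness_spongy / vox))
    t_abx = max(1, round(params.thickness_epidermis_abaxial / vox))
    total = t_adx + t_pal + t_spo + t_abx
    if total > nz:
        raise ValueError("infeasible geometry: rounded layer thicknesses exceed depth")
    z0 = (nz - total) // 2
    za0, za1 = z0, z0 + t_adx                    # adaxial epidermis
    zp0, zp1 = za1, za1 + t_pal                  # palisade
    zs0, zs1 = zp1, zp1 + t_spo                  # spongy
    zb0, zb1 = zs1, zs1 + t_abx                  # abaxial epidermis

    labels[za0:za1] = L["epidermis_adaxial"]
    labels[zb0:zb1] = L["epidermis_abaxial"]

    # palisade: vertical cylinders
    radius = params.palisade_diameter_um / 2.0
    if params.porosity_palisade == 0.0:
        pal_mask = np.ones((ny, nx), dtype=bool)
    else:
        pal_mask = _solve_palisade_spacing(params.porosity_palisade, radius, ny, nx, vox)
    labels[zp0:zp1] = np.where(pal_mask, L["mesophyll_cell"], L["ias"])

    # one rasterized disk, for the equivalent-diameter ground truth
    rr = int(math.ceil(radius / vox)) + 2
    yy, xx = np.meshgrid(
        (np.arange(2 * rr) - rr + 0.5) * vox, (np.arange(2 * rr) - rr + 0.5) * vox,
        indexing="ij",
    )
    disk_area = int((yy**2 + xx**2 <= radius**2).sum())
    eq_diameter = 2.0 * math.sqrt(disk_area / math.pi) * vox

    # spongy: thresholded blob field (quantile -> exact voxel-count porosity)
    if params.porosity_spongy == 0.0:
        labels[zs0:zs1] = L["mesophyll_cell"]
    else:
        noise = rng.standard_normal((t_spo, ny, nx))
        blobs = gaussian_filter(noise, sigma=params.spongy_blob_sigma_um / vox)
        thr = np.quantile(blobs, params.porosity_spongy)
        labels[zs0:zs1] = np.where(blobs < thr, L["ias"], L["mesophyll_cell"])

    # BSEs: full-depth slabs joining the epidermes, with a vein cylinder inside
    if params.bse_spacing_um is not None:
        spacing_vox = params.bse_spacing_um / vox
        half_w = max(1, round(params.bse_width_um / vox / 2.0))
        y_centers = np.arange(spacing_vox / 2.0, ny, spacing_vox).round().astype(int)
        zmid = (zp0 + zb0) // 2
        rvein = params.vein_diameter_um / 2.0 / vox
        zz = np.arange(nz)[:, None] - zmid
        for yc in y_centers:
            ylo, yhi = max(0, yc - half_w), min(ny, yc + half_w + 1)
            labels[zp0:zb0, ylo:yhi, :] = L["bse"]
            dy = np.arange(ylo, yhi)[None, :] - yc
            vein = (zz[zp0:zb0] ** 2 + dy**2) <= rvein**2
            block = labels[zp0:zb0, ylo:yhi, :]
            block[vein] = L["vein"]

    # stomata: jittered through-pores in the abaxial epidermis.  BSE
    # slabs partition the airspace into lateral compartments (the
    # heterobaric condition), and real leaves feed every compartment, so
    # stomata are allocated per compartment in proportion to its width.
    area_mm2 = (ny * vox * 1e-3) * (nx * vox * 1e-3)
    n_stomata = int(round(params.stomatal_density_mm2 * area_mm2))
    centers = []
    if n_stomata > 0:
        half_l = params.stomatal_pore_length_um / 2.0 / vox
        half_w = params.stomatal_pore_width_um / 2.0 / vox
        if params.bse_spacing_um is not None:
            margin = int(math.ceil(half_w)) + max(1, round(params.bse_width_um / vox / 2.0)) + 1
            walls = np.arange(params.bse_spacing_um / vox / 2.0, ny, params.bse_spacing_um / vox)
            bounds = [0.0, *walls.round().tolist(), float(ny)]
            compartments = [
                (lo + margin, hi - margin)
                for lo, hi in zip(bounds[:-1], bounds[1:])
                if hi - lo > 2 * margin + 1
            ]
        else:
            compartments = [(0.0, float(ny))]
        widths = np.array([hi - lo for lo, hi in compartments], dtype=float)
        alloc = n_stomata * widths / widths.sum()
        counts = np.floor(alloc).astype(int)
        for i in np.argsort(alloc - counts)[::-1][: n_stomata - counts.sum()]:
            counts[i] += 1
        grid = []
        for (lo, hi), cnt in zip(compartments, counts):
            step_x = nx / max(cnt, 1)
            for ix in range(cnt):
                grid.append(
                    (
                        rng.uniform(lo, hi),
                        (ix + 0.5) * step_x + rng.uniform(-0.25, 0.25) * step_x,
                    )
                )
        chan_r = max(1.0, half_w)
        yy, xx = np.meshgrid(np.arange(ny, dtype=float), np.arange(nx, dtype=float), indexing="ij")
        for yc, xc in grid:
            pore = ((yy - yc) / half_w) ** 2 + ((xx - xc) / half_l) ** 2 <= 1.0
            labels[zb0:zb1, pore] = L["ias"]
            chan = (yy - yc) ** 2 + (xx - xc) ** 2 <= chan_r**2
            z = zb0 - 1
            carved = 0
            while z >= zs0:
                if np.any(labels[z, chan] == L["ias"]) and carved > 0:
                    break
                labels[z, chan] = L["ias"]
                carved += 1
                z -= 1
            centers.append(
                (zb0, min(int(round(yc)), ny - 1), min(int(round(xc)), nx - 1))
            )

    volume = LabeledVolume(labels, vox, dict(L))

    # ground truth by direct counting on the emitted volume
    def _layer_porosity(lo: int, hi: int) -> float:
        sub = labels[lo:hi]
        n_ias = int((sub == L["ias"]).sum())
        n_cell = int((sub == L["mesophyll_cell"]).sum())
        return n_ias / (n_ias + n_cell) if (n_ias + n_cell) else 0.0

    n_bse = int((labels == L["bse"]).sum())
    n_cell = int((labels == L["mesophyll_cell"]).sum())
    n_ias = int((labels == L["ias"]).sum())
    truth = LeafPhantomTruth(
        porosity_palisade=_layer_porosity(zp0, zp1),
        porosity_spongy=_layer_porosity(zs0, zs1),
        porosity_mesophyll=_layer_porosity(0, nz),
        thickness_epidermis_adaxial=t_adx * vox,
        thickness_palisade=t_pal * vox,
        thickness_spongy=t_spo * vox,
        thickness_epidermis_abaxial=t_abx * vox,
        thickness_leaf=total * vox,
        thickness_mesophyll=(t_pal + t_spo) * vox,
        bse_area_fraction_pct=100.0 * n_bse / (n_bse + n_cell + n_ias),
        stomate_centers=np.array(centers, dtype=int).reshape(-1, 3),
        palisade_diameter_um=eq_diameter,
    )
    return volume, truth


def slab_phantom(
    mesophyll_depth: int = 40,
    ny: int = 40,
    nx: int = 40,
    voxel_size_um: float = 1.0,
    epidermis: int = 3,
    mesophyll_label: str = "ias",
) -> LabeledVolume:
    """Minimal slab leaf: epidermes sandwiching a uniform mesophyll block.

    A convenience fixture for geometry tests -- e.g. an all-airspace
    mesophyll (``mesophyll_label="ias"``) for the unobstructed tortuosity
    limit.
    """
    L = DEFAULT_LABELS
    nz = mesophyll_depth + 2 * epidermis
    labels = np.full((nz, ny, nx), L[mesophyll_label], dtype=np.uint8)
    labels[:epidermis] = L["epidermis_adaxial"]
    labels[nz - epidermis:] = L["epidermis_abaxial"]
    return LabeledVolume(labels, voxel_size_um, dict(L))


# ---------------------------------------------------------------------------
# isotope forward simulation


@dataclass(frozen=True)
class IsotopeSimParams:
    """Cuvette state, true mesophyll conductance and noise model.

    CO2 mole fractions in umol mol-1 with ``ce > ca > ci > gamma_star``
    for a transpiring, assimilating leaf; transpiration in mol m-2 s-1.
    Measurement noise is i.i.d. Gaussian on the plant-air d13C.  The
    default reference-air drawdown (``ce - ca`` = 60 umol mol-1) reflects
    the low cuvette flow used when collecting air for isotope analysis;
    the corresponding zeta keeps the noise amplification of the observed
    discrimination realistic.
    """

    true_gm: float = 0.15
    ca: float = 400.0
    cs: float = 390.0
    ci: float = 280.0
    ce: float = 460.0
    e_trans: float = 0.002
    g_act: float = 0.25
    an: float = 14.0
    rd: float = 1.5
    gamma_star: float = 40.0
    d13c_e: float = -35.0
    d13c_atm: float = -8.0
    noise_sd_d13ca: float = 0.1
    n: int = 200
    seed: int = 0
    constants: iso.IsotopeConstants = field(default_factory=iso.IsotopeConstants)

    def __post_init__(self) -> None:
        if self.true_gm <= 0:
            raise ValueError("true_gm must be positive")
        if not (self.ce > self.ca > self.ci > self.gamma_star > 0):
            raise ValueError("require ce > ca > ci > gamma_star > 0")
        if not (self.ca >= self.cs >= self.ci):
            raise ValueError("require ca >= cs >= ci")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sd_d13ca < 0:
            raise ValueError("noise SD must be nonnegative")


def generate_isotope_records(params: IsotopeSimParams) -> pd.DataFrame:
    """Forward-simulate replicate gas-exchange/isotope records.

    Runs the discrimination components forwards from the true ``g_m``,
    sets the observed discrimination as predicted minus the g_m,
    respiratory and photorespiratory components, inverts the observed-
    discrimination relation for the plant-air d13C, and adds Gaussian
    noise.  The returned table uses the documented CSV header plus a
    ``true_gm`` column for recovery tests.
    """
    p = params
    k = p.constants
    rng = np.random.default_rng(p.seed)

    z = iso.zeta(p.ce, p.ca)
    a_prime = iso.combined_fractionation(p.ca, p.cs, p.ci, k)
    t = iso.ternary_t(a_prime, p.e_trans, p.g_act)
    delta_i = iso.predicted_discrimination(t, a_prime, p.ci, p.ca, k)
    ternary = (1.0 + t) / (1.0 - t)
    e_resp = p.d13c_e - p.d13c_atm
    delta_e = ternary * (e_resp * p.rd / ((p.an + p.rd) * p.ca)) * (p.ci - p.gamma_star)
    delta_f = ternary * k.f * p.gamma_star / p.ca
    delta_gm = ternary * (
        k.b - k.a_i - e_resp * p.rd / (p.an + p.rd)
    ) * p.an / (p.true_gm * p.ca)
    delta_o = delta_i - delta_gm - delta_e - delta_f

    # invert the observed-discrimination relation for d13C_a
    denom = delta_o * (1.0 - z) - 1000.0 * z
    if denom == 0:
        raise SimulationError("observed-discrimination relation is not invertible")
    d13ca = -(1000.0 * z * p.d13c_e + 1000.0 * delta_o + delta_o * z * p.d13c_e) / denom
    if 1000.0 + d13ca - z * (d13ca - p.d13c_e) <= 0:
        raise SimulationError(
            "nonpositive observed-discrimination denominator for these parameters"
        )

    d13ca_obs = d13ca + rng.normal(0.0, p.noise_sd_d13ca, size=p.n)
    return pd.DataFrame(
        {
            "An": p.an,
            "E_mmol": p.e_trans * 1e3,
            "gact": p.g_act,
            "Ca": p.ca,
            "Cs": p.cs,
            "Ci": p.ci,
            "Ce": p.ce,
            "Rd": p.rd,
            "GammaStar": p.gamma_star,
            "d13Ca": d13ca_obs,
            "d13Ce": p.d13c_e,
            "d13Catm": p.d13c_atm,
            "true_gm": p.true_gm,
        }
    )


# ---------------------------------------------------------------------------
# fluorescence cross-section images


def generate_fluorescence_image(
    depth_spec,
    lateral_spec=None,
    shape: tuple[int, int] = (220, 360),
    mesophyll_rows: tuple[int, int] = (20, 200),
    bse_centers_px=None,
    pixel_size_um: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FluorImage, np.ndarray]:
    """Synthesize a cross-section fluorescence image.

    ``depth_spec`` maps relative mesophyll depth (percent, 0 = adaxial
    edge) to nonnegative intensity; ``lateral_spec`` (optional) maps
    signed distance (um) from a BSE center to an additive bright-halo
    factor, applied multiplicatively as ``1 + sum_k lateral_spec(d_k)``.
    Returns the image (with its mesophyll mask) and the BSE center
    columns in pixels.
    """
    nrow, ncol = shape
    r0, r1 = mesophyll_rows
    if not (0 <= r0 < r1 <= nrow):
        raise ValueError("mesophyll_rows must lie within the image")
    rng = np.random.default_rng(seed)

    depth_pct = (np.arange(nrow) - r0 + 0.5) / (r1 - r0) * 100.0
    base = np.asarray(depth_spec(np.clip(depth_pct, 0.0, 100.0)), dtype=float)
    if np.any(base < 0):
        raise ValueError("depth profile spec must be nonnegative")
    img = np.tile(base[:, None], (1, ncol))

    if bse_centers_px is None and lateral_spec is not None:
        spacing = int(round(60.0 / pixel_size_um))
        bse_centers_px = np.arange(spacing // 2, ncol, spacing)
    bse_centers_px = (
        np.asarray(bse_centers_px, dtype=int) if bse_centers_px is not None else np.array([], int)
    )
    if lateral_spec is not None and bse_centers_px.size:
        cols = np.arange(ncol, dtype=float)
        factor = np.ones(ncol)
        for xc in bse_centers_px:
            factor += np.asarray(lateral_spec((cols - xc) * pixel_size_um), dtype=float)
        img *= factor[None, :]

    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, :] = True
    img[~mask] *= 0.05  # faint non-mesophyll signal
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(img, 0.0, None)
    return (
        FluorImage(intensity=img, pixel_size_um=pixel_size_um, mask=mask, adaxial_top=True),
        bse_centers_px,
    )


# ---------------------------------------------------------------------------
# A-Ci curves

DEFAULT_CI_GRID = np.array(
    [50.0, 80.0, 100.0, 150.0, 200.0, 400.0, 600.0, 800.0, 1000.0, 1200.0, 1500.0]
)


def generate_aci_curve(
    v_cmax: float = 100.0,
    j_max: float = 150.0,
    r_d: float = 1.5,
    gamma_star: float = 40.0,
    km: float | None = None,
    noise_sd: float = 0.0,
    ci_grid=None,
    seed: int = 0,
) -> pd.DataFrame:
    """FvCB forward A-Ci table; true parameters travel in ``df.attrs``."""
    if min(v_cmax, j_max, gamma_star) <= 0 or r_d < 0:
        raise ValueError("FvCB parameters must be positive (r_d nonnegative)")
    if km is None:
        km = michaelis_km()
    ci = np.asarray(DEFAULT_CI_GRID if ci_grid is None else ci_grid, dtype=float)
    rng = np.random.default_rng(seed)
    an = fvcb_assimilation(ci, v_cmax, j_max, r_d, gamma_star, km)
    if noise_sd > 0:
        an = an + rng.normal(0.0, noise_sd, size=ci.shape)
    df = pd.DataFrame({"Ci": ci, "An": an})
    df.attrs["true"] = {
        "v_cmax": v_cmax, "j_max": j_max, "r_d": r_d,
        "gamma_star": gamma_star, "km": km,
    }
    return df
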