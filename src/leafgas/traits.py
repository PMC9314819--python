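"""Scalar and depth-resolved anatomical traits from a segmented leaf volume.

Porosity (theta_IAS) is the intercellular-airspace fraction of the
mesophyll, counted over mesophyll-cell and IAS voxels only: bundle
sheath extensions and veins are vascular-associated tissue and are kept
out of both numerator and denominator (the BSE share is reported
separately as a cross-sectional area percentage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from skimage import measure

from .volume import MESOPHYLL_REGION, LabeledVolume

__all__ = [
    "TraitSet",
    "DepthProfile",
    "porosity",
    "vias_to_vcell",
    "sa_mes_per_vmes",
    "thicknesses",
    "porosity_depth_profile",
    "bse_area_fraction",
    "paradermal_palisade_diameter",
    "trait_set",
]


@dataclass
class DepthProfile:
    """Per-bin values over relative mesophyll depth (%; adaxial = 0)."""

    depth_pct: np.ndarray  # bin centers, strictly increasing in [0, 100]
    value: np.ndarray
    counts: np.ndarray  # mesophyll voxels per bin (weights for conservation)


@dataclass
class TraitSet:
    theta_ias: float
    vias_to_vcell: float
    sa_mes_per_vmes: float  # um2 um-3
    l_leaf: float  # um
    l_mes: float
    l_epi_adaxial: float
    l_epi_abaxial: float
    bse_area_fraction_pct: float
    palisade_diameter_um: dict[float, float]  # depth fraction -> mean diameter


def _mesophyll_counts(volume: LabeledVolume) -> tuple[int, int]:
    n_ias = volume.count("ias")
    n_cell = volume.count("mesophyll_cell")
    if n_ias + n_cell == 0:
        raise ValueError("volume contains no mesophyll (cell or IAS) voxels")
    return n_ias, n_cell


def porosity(volume: LabeledVolume) -> float:
    """Mesophyll porosity ``theta_IAS = N_IAS / (N_IAS + N_mes-cell)``."""
    n_ias, n_cell = _mesophyll_counts(volume)
    return n_ias / (n_ias + n_cell)


def vias_to_vcell(volume: LabeledVolume) -> float:
    """Airspace-to-cell volume ratio; equals ``theta / (1 - theta)``."""
    n_ias, n_cell = _mesophyll_counts(volume)
    if n_cell == 0:
        raise ValueError("volume has no mesophyll-cell voxels; ratio undefined")
    return n_ias / n_cell


def _face_counts(cells: np.ndarray, ias: np.ndarray) -> tuple[int, int]:
    """6-neighbour face counts: (cell faces touching IAS, all cell boundary faces).

    Only in-bounds voxel pairs are counted: faces created by cropping the
    sample at the volume edge are not part of the tissue interface.
    """
    to_ias = 0
    boundary = 0
    for axis in range(3):
        for shift in (1, -1):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[axis] = slice(None, -1) if shift == 1 else slice(1, None)
            sl_b[axis] = slice(1, None) if shift == 1 else slice(None, -1)
            a = cells[tuple(sl_a)]
            to_ias += int((a & ias[tuple(sl_b)]).sum())
            boundary += int((a & ~cells[tuple(sl_b)]).sum())
    return to_ias, boundary


def sa_mes_per_vmes(volume: LabeledVolume) -> float:
    """Mesophyll surface area exposed to IAS per mesophyll volume (um2 um-3).

    The cell/airspace interface area is estimated from a marching-cubes
    isosurface of the (lightly Gaussian-smoothed) mesophyll-cell
    indicator: face counting, and marching cubes run directly on the
    binary mask, both overestimate curved interfaces because of the
    voxel staircase, while the smoothed 0.5-level surface tracks the
    underlying interface closely.  The area is scaled by the fraction of
    the cell boundary that actually faces IAS and divided by the total
    mesophyll volume (cells + airspace).
    """
    vox = volume.voxel_size_um
    cells = volume.mask("mesophyll_cell")
    ias = volume.mask("ias")
    n_cell = int(cells.sum())
    n_ias = int(ias.sum())
    if n_cell == 0 or n_ias == 0:
        warnings.warn("no cell/IAS interface (porosity 0 or 1); SA/V = 0", stacklevel=2)
        return 0.0
    # edge replication: tissue is treated as continuing past the crop, so
    # the crop faces generate no spurious isosurface; triangles whose
    # centroid falls in the padding ring are discarded
    pad = 2
    padded = gaussian_filter(np.pad(cells, pad, mode="edge").astype(np.float32), sigma=1.0)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=(vox,) * 3)
    tri = verts[faces]
    centroid = tri.mean(axis=1)
    lo = pad * vox
    hi = (np.array(cells.shape) + pad) * vox
    inside = np.all((centroid >= lo) & (centroid < hi), axis=1)
    edges1 = tri[inside, 1] - tri[inside, 0]
    edges2 = tri[inside, 2] - tri[inside, 0]
    area_total = 0.5 * np.linalg.norm(np.cross(edges1, edges2), axis=1).sum()
    to_ias, boundary = _face_counts(cells, ias)
    if boundary == 0:
        return 0.0
    area_exposed = area_total * (to_ias / boundary)
    v_mes = (n_cell + n_ias) * vox**3
    return float(area_exposed / v_mes)


def thicknesses(volume: LabeledVolume) -> tuple[float, float, float, float]:
    """Mean per-column extents along z: (L_leaf, L_mes, L_epi-ad, L_epi-ab), um.

    Extents are measured axis-aligned per (y, x) column and averaged over
    columns that intersect the leaf.
    """
    vox = volume.voxel_size_um
    for epi in ("epidermis_adaxial", "epidermis_abaxial"):
        if volume.count(epi) == 0:
            raise ValueError(f"volume is missing the {epi} label")
    labels = volume.labels
    nz = labels.shape[0]
    zidx = np.arange(nz)[:, None, None]

    def _extent(mask: np.ndarray) -> np.ndarray:
        any_col = mask.any(axis=0)
        zmin = np.where(mask, zidx, nz).min(axis=0)
        zmax = np.where(mask, zidx, -1).max(axis=0)
        extent = np.where(any_col, zmax - zmin + 1, 0)
        return extent, any_col

    leaf_mask = labels != volume.label_map["background"]
    mes_mask = volume.mask(*MESOPHYLL_REGION)
    leaf_extent, leaf_cols = _extent(leaf_mask)
    mes_extent, _ = _extent(mes_mask)
    ad_count = volume.mask("epidermis_adaxial").sum(axis=0)
    ab_count = volume.mask("epidermis_abaxial").sum(axis=0)

    sel = leaf_cols
    return (
        float(leaf_extent[sel].mean() * vox),
        float(mes_extent[sel].mean() * vox),
        float(ad_count[sel].mean() * vox),
        float(ab_count[sel].mean() * vox),
    )


def porosity_depth_profile(volume: LabeledVolume, n_bins: int = 20) -> DepthProfile:
    """IAS fraction per relative-depth bin over the mesophyll (epidermes excluded).

    Depth is normalized per (y, x) column to that column's mesophyll
    extent, so the profile is robust to leaf-surface tilt.  The
    voxel-count-weighted mean of the bins equals the scalar porosity
    exactly (every cell/IAS voxel lands in exactly one bin).
    """
    if n_bins < 5:
        raise ValueError("n_bins must be >= 5")
    labels = volume.labels
    nz = labels.shape[0]
    L = volume.label_map
    mes_region = volume.mask(*MESOPHYLL_REGION)
    zidx = np.arange(nz)[:, None, None]
    any_col = mes_region.any(axis=0)
    zmin = np.where(mes_region, zidx, nz).min(axis=0)
    extent = np.where(mes_region, zidx, -1).max(axis=0) - zmin + 1

    counted = volume.mask("mesophyll_cell", "ias") & any_col[None, :, :]
    zz, yy, xx = np.nonzero(counted)
    rel = (zz - zmin[yy, xx] + 0.5) / extent[yy, xx]
    bins = np.minimum((rel * n_bins).astype(int), n_bins - 1)
    is_ias = labels[zz, yy, xx] == L["ias"]

    counts = np.bincount(bins, minlength=n_bins)
    ias_counts = np.bincount(bins[is_ias], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        value = np.where(counts > 0, ias_counts / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) / n_bins * 100.0
    return DepthProfile(depth_pct=centers, value=value, counts=counts)


def bse_area_fraction(volume: LabeledVolume) -> float:
    """BSE share of the mesophyll cross-section, percent.

    ``100 * N_BSE / (N_BSE + N_mes-cell + N_IAS)`` computed per z-slice
    and averaged over slices of the mesophyll proper (those containing
    mesophyll cells or BSE; pore-only epidermis slices and veins are
    excluded).  Returns 0 when the volume has no BSE label.
    """
    L = volume.label_map
    labels = volume.labels
    bse = (labels == L["bse"]).sum(axis=(1, 2))
    cell = (labels == L["mesophyll_cell"]).sum(axis=(1, 2))
    ias = (labels == L["ias"]).sum(axis=(1, 2))
    denom = bse + cell + ias
    valid = (bse + cell) > 0
    if not valid.any():
        return 0.0
    return float((100.0 * bse[valid] / denom[valid]).mean())


def paradermal_palisade_diameter(
    volume: LabeledVolume,
    depth_fractions=(0.2, 0.4, 0.6),
    min_area_voxels: int = 10,
) -> dict[float, float]:
    """Mean equivalent-circle diameter of mesophyll cells in paradermal slices.

    For each depth fraction (measured from the adaxial mesophyll surface)
    the paradermal slice is extracted, in-plane connected components of
    the mesophyll-cell label are measured, and components above the
    minimum-area speckle threshold contribute their equivalent-circle
    diameter (um).  Cells clipped by the field of view or by vascular
    tissue (components touching the slice border or adjacent to BSE or
    vein labels) are excluded, as partial profiles bias the diameter
    downward.  Depths whose slice holds no whole cells map to NaN with a
    warning.
    """
    vox = volume.voxel_size_um
    out: dict[float, float] = {}
    fractions = list(depth_fractions)
    if not fractions:
        return out
    if any(not (0.0 < f < 1.0) for f in fractions):
        raise ValueError("depth fractions must lie in (0, 1)")
    mes_region = volume.mask(*MESOPHYLL_REGION)
    zs = np.nonzero(mes_region.any(axis=(1, 2)))[0]
    if zs.size == 0:
        raise ValueError("volume has no mesophyll region")
    z_top, z_bottom = zs[0], zs[-1]
    L = volume.label_map
    for f in fractions:
        z = int(round(z_top + f * (z_bottom - z_top)))
        slice_labels = volume.labels[z]
        plane = slice_labels == L["mesophyll_cell"]
        vascular = np.isin(slice_labels, [L["bse"], L["vein"]])
        clipped = binary_dilation(vascular, iterations=1)
        lab = measure.label(plane, connectivity=1)
        border = np.zeros_like(plane)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        excluded = set(np.unique(lab[border | clipped])) - {0}
        props = [
            p
            for p in measure.regionprops(lab)
            if p.area >= min_area_voxels and p.label not in excluded
        ]
        if not props:
            warnings.warn(f"no whole mesophyll cells at depth fraction {f}", stacklevel=2)
            out[f] = float("nan")
            continue
        out[f] = float(np.mean([p.equivalent_diameter_area for p in props]) * vox)
    return out


def trait_set(
    volume: LabeledVolume,
    depth_fractions=(0.2, 0.4, 0.6),
) -> TraitSet:
    """Convenience bundle of all scalar traits for one volume."""
    l_leaf, l_mes, l_ad, l_ab = thicknesses(volume)
    return TraitSet(
        theta_ias=porosity(volume),
        vias_to_vcell=vias_to_vcell(volume),
        sa_mes_per_vmes=sa_mes_per_vmes(volume),
        l_leaf=l_leaf,
        l_mes=l_mes,
        l_epi_adaxial=l_ad,
        l_epi_abaxial=l_ab,
        bse_area_fraction_pct=bse_area_fraction(volume),
        palisade_diameter_um=paradermal_palisade_diameter(volume, depth_fractions),
    )
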