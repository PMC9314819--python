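"""Stomate-seeded distance fields, tortuosity, path lengthening and g_IAS.

CO2 entering through a stomate reaches a mesophyll cell wall along a
path confined to the intercellular airspace (IAS).  Tortuosity compares
that within-airspace geodesic with the unobstructed straight-line
distance, ``tau = (L_geo / L_Euc)^2``; lateral path lengthening compares
the straight-line distance to the nearest stomate with the perpendicular
distance to the abaxial epidermis, ``lambda = L_Euc / L_epi``, capturing
the detour imposed by discrete stomatal spacing.  Both are averaged over
IAS voxels at the edge of mesophyll cells.  Together with porosity and
mesophyll thickness they set the gas-phase conductance

    g_IAS = theta_IAS * D_m / (0.5 * L_mes * tau_leaf * lambda_leaf)

converted to mol m-2 s-1 bar-1 with the ideal-gas molar density P/(RT).

Numerical note: L_geo is the exact shortest path on the 26-neighbour
voxel lattice (chamfer weights 1, sqrt2, sqrt3 times the voxel pitch).
That lattice metric overestimates Euclidean length by a
direction-dependent few percent, so tortuosity is evaluated as the ratio
of the obstructed to the *unobstructed* lattice shortest path, which
cancels the metric bias (an empty medium gives tau = 1 exactly).  The
stored ``l_euc`` field itself is the exact Euclidean distance transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, distance_transform_edt, generate_binary_structure
from skimage.graph import MCP_Geometric

from .volume import LabeledVolume

__all__ = [
    "DistanceFields",
    "DiffusionTraits",
    "detect_stomata",
    "distance_fields",
    "leaf_tortuosity",
    "leaf_path_lengthening",
    "g_ias",
    "gias_contribution",
    "diffusion_traits",
]

R_GAS = 8.31446  # J mol-1 K-1
D_CO2_AIR_25C = 1.54e-5  # m2 s-1, CO2 in air at 25 C


@dataclass
class DistanceFields:
    """Per-voxel distance maps (um), plus the stomatal seed coordinates.

    ``l_geo``: within-IAS geodesic from the nearest stomate (inf where an
    IAS voxel is unreachable; NaN outside the IAS).  ``l_euc``: Euclidean
    distance to the nearest stomate.  ``l_epi``: Euclidean distance to the
    abaxial epidermis inner surface (epidermis voxels plus the stomatal
    perforations that interrupt it).  ``l_lattice``: unobstructed
    shortest path to the nearest stomate in the same 26-neighbour lattice
    metric as ``l_geo``; tortuosity uses ``l_geo / l_lattice``.
    """

    l_geo: np.ndarray
    l_euc: np.ndarray
    l_epi: np.ndarray
    l_lattice: np.ndarray
    seeds: np.ndarray  # (n, 3) voxel coordinates
    voxel_size_um: float

    def unreachable_fraction(self, volume: LabeledVolume) -> float:
        ias = volume.mask("ias")
        return float(np.isinf(self.l_geo[ias]).mean())


@dataclass
class DiffusionTraits:
    tau_leaf: float
    lambda_leaf: float
    theta_ias: float
    l_mes_um: float
    g_ias: float  # mol m-2 s-1 bar-1
    d_m: float
    temperature_k: float
    pressure_bar: float
    reachable_fraction: float


def detect_stomata(volume: LabeledVolume) -> np.ndarray:
    """Stomatal seed voxels: IAS voxels lying within the abaxial epidermis band.

    Stomata perforate the abaxial epidermis, so any IAS voxel between the
    first and last z-slice containing abaxial epidermis is part of a
    pore.  Returns ``(n, 3)`` voxel coordinates.
    """
    ab = volume.mask("epidermis_abaxial")
    zs = np.nonzero(ab.any(axis=(1, 2)))[0]
    if zs.size == 0:
        raise ValueError("volume has no abaxial epidermis; cannot detect stomata")
    band = np.zeros(volume.shape, dtype=bool)
    band[zs[0]: zs[-1] + 1] = True
    seeds = np.argwhere(band & volume.mask("ias"))
    if seeds.shape[0] == 0:
        raise ValueError("no stomatal perforations found in the abaxial epidermis")
    return seeds


def distance_fields(
    volume: LabeledVolume, stomata: np.ndarray | None = None
) -> DistanceFields:
    """Compute all stomate-seeded distance maps for a volume.

    ``stomata`` is an optional ``(n, 3)`` array of seed voxel coordinates
    (z, y, x); every seed must be an IAS voxel.  When omitted, seeds are
    detected as abaxial-epidermis perforations.
    """
    vox = volume.voxel_size_um
    ias = volume.mask("ias")
    if stomata is None:
        stomata = detect_stomata(volume)
    stomata = np.atleast_2d(np.asarray(stomata, dtype=int))
    if stomata.shape[0] == 0:
        raise ValueError("at least one stomate seed is required")
    for seed in stomata:
        if not ias[tuple(seed)]:
            raise ValueError(f"stomate seed {tuple(seed)} is not an IAS voxel")
    starts = [tuple(s) for s in stomata]

    costs = np.where(ias, 1.0, np.inf)
    geo, _ = MCP_Geometric(costs, fully_connected=True).find_costs(starts=starts)
    l_geo = np.where(ias, geo * vox, np.nan)

    free, _ = MCP_Geometric(np.ones_like(costs), fully_connected=True).find_costs(starts=starts)
    l_lattice = free * vox

    seed_mask = np.zeros(volume.shape, dtype=bool)
    seed_mask[tuple(stomata.T)] = True
    l_euc = distance_transform_edt(~seed_mask, sampling=vox)
    inner_surface = volume.mask("epidermis_abaxial") | seed_mask
    l_epi = distance_transform_edt(~inner_surface, sampling=vox)

    return DistanceFields(
        l_geo=l_geo, l_euc=l_euc, l_epi=l_epi, l_lattice=l_lattice,
        seeds=stomata, voxel_size_um=vox,
    )


def _mesophyll_edge(volume: LabeledVolume) -> np.ndarray:
    """IAS voxels 6-adjacent to mesophyll-cell voxels."""
    cells = volume.mask("mesophyll_cell")
    six = generate_binary_structure(3, 1)
    return volume.mask("ias") & binary_dilation(cells, structure=six)


def _edge_or_all_ias(volume: LabeledVolume) -> np.ndarray:
    edge = _mesophyll_edge(volume)
    if not edge.any():
        warnings.warn(
            "no mesophyll-cell/IAS interface; averaging over all IAS voxels",
            stacklevel=3,
        )
        edge = volume.mask("ias")
    return edge


def leaf_tortuosity(fields: DistanceFields, volume: LabeledVolume) -> float:
    """Mean ``(L_geo / L_line)^2`` over mesophyll-edge IAS voxels (>= 1).

    Unreachable voxels (no airspace path from any stomate) are excluded.
    """
    edge = _edge_or_all_ias(volume)
    valid = edge & np.isfinite(fields.l_geo) & (fields.l_lattice > 0)
    if not valid.any():
        raise ValueError("no reachable mesophyll-edge voxels; tortuosity undefined")
    ratio = fields.l_geo[valid] / fields.l_lattice[valid]
    return float(np.mean(ratio**2))


def leaf_path_lengthening(fields: DistanceFields, volume: LabeledVolume) -> float:
    """Mean ``L_Euc / L_epi`` over mesophyll-edge IAS voxels (>= 1)."""
    edge = _edge_or_all_ias(volume)
    valid = edge & (fields.l_epi > 0)
    if not valid.any():
        raise ValueError("no valid mesophyll-edge voxels; path lengthening undefined")
    return float(np.mean(fields.l_euc[valid] / fields.l_epi[valid]))


def g_ias(
    theta_ias: float,
    tau_leaf: float,
    lambda_leaf: float,
    l_mes: float,
    d_m: float = D_CO2_AIR_25C,
    temperature: float = 298.15,
    pressure_bar: float = 1.0,
) -> float:
    """Gas-phase IAS conductance, mol m-2 s-1 bar-1.

    ``l_mes`` is the mesophyll thickness in metres; the diffusion path
    length is half of it (hypostomatous leaf).  The porous-medium
    velocity ``theta * D_m / (0.5 L_mes tau lambda)`` (m s-1) is
    converted to a molar flux basis with the ideal-gas molar density
    ``P / (R T)``.
    """
    for name, v in (
        ("theta_ias", theta_ias), ("tau_leaf", tau_leaf), ("lambda_leaf", lambda_leaf),
        ("l_mes", l_mes), ("d_m", d_m), ("temperature", temperature),
        ("pressure_bar", pressure_bar),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    velocity = theta_ias * d_m / (0.5 * l_mes * tau_leaf * lambda_leaf)
    molar_density = pressure_bar * 1e5 / (R_GAS * temperature)  # mol m-3 per bar basis
    return velocity * molar_density


def gias_contribution(g_m: float, g_ias_val: float) -> float:
    """Share of total mesophyll resistance residing in the gas phase.

    ``(1/g_IAS) / (1/g_m) = g_m / g_IAS``; both conductances must be on a
    common molar basis (convert a per-bar g_IAS by multiplying by the
    pressure in bar).  Raises if ``g_m > g_IAS``: the series total cannot
    exceed one of its components.
    """
    if g_m <= 0 or g_ias_val <= 0:
        raise ValueError("conductances must be positive")
    if g_m > g_ias_val:
        raise ValueError("g_m exceeds g_IAS: total conductance cannot exceed a series component")
    return g_m / g_ias_val


def diffusion_traits(
    volume: LabeledVolume,
    stomata: np.ndarray | None = None,
    d_m: float = D_CO2_AIR_25C,
    temperature: float = 298.15,
    pressure_bar: float = 1.0,
) -> DiffusionTraits:
    """One-call pipeline: distance fields -> tau, lambda, theta, g_IAS."""
    from .traits import porosity, thicknesses

    fields = distance_fields(volume, stomata)
    tau = leaf_tortuosity(fields, volume)
    lam = leaf_path_lengthening(fields, volume)
    theta = porosity(volume)
    _, l_mes_um, _, _ = thicknesses(volume)
    g = g_ias(theta, tau, lam, l_mes_um * 1e-6, d_m, temperature, pressure_bar)
    return DiffusionTraits(
        tau_leaf=tau,
        lambda_leaf=lam,
        theta_ias=theta,
        l_mes_um=l_mes_um,
        g_ias=g,
        d_m=d_m,
        temperature_k=temperature,
        pressure_bar=pressure_bar,
        reachable_fraction=1.0 - fields.unreachable_fraction(volume),
    )
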