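"""Water-exposed surface area (ESA), density fields and permeation
counts over trajectory frames.

The molecular surface is represented as a point cloud: each atom's van
der Waals sphere is sampled on a Fibonacci lattice and a point is kept
when a 1.4 A probe placed along its outward normal clears every other
atom (probe-rolling rejection).  Each point carries an effective area
(its sphere's area divided by the sample count) and an MHP value.  The
water-exposed subset of a frame consists of the points with a water
oxygen within the contact cutoff, restricted to the axial span between
the selectivity filter and the activation gate; its area binned along
z and along MHP, averaged over the analysis window, gives the ESA
profiles.  ESA with MHP > 0 is the hydrophobic fraction ESA_H.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mhp import MHPField, MHPParams
from .structure import FrameSeries, Structure

__all__ = ["SurfacePointCloud", "ESAProfile", "DensityField", "DeltaESA",
           "PermeationCount", "connolly_points", "exposed_subset",
           "esa_profile", "delta_esa", "density_profiles",
           "count_permeation"]


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    ct = 1.0 - 2.0 * i / n
    st = np.sqrt(np.maximum(1.0 - ct * ct, 0.0))
    return np.column_stack([st * np.cos(phi), st * np.sin(phi), ct])


@dataclass
class SurfacePointCloud:
    """Surface points with per-point effective area, MHP and owner atom."""
    points: np.ndarray           # (P, 3)
    areas: np.ndarray            # (P,) A^2
    mhp: np.ndarray              # (P,) logP units (NaN if not evaluated)
    owner_atom: np.ndarray       # (P,) atom index into source structure

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def subset(self, mask) -> "SurfacePointCloud":
        mask = np.asarray(mask)
        return SurfacePointCloud(self.points[mask], self.areas[mask],
                                 self.mhp[mask], self.owner_atom[mask])


def connolly_points(structure: Structure, probe: float = 1.4,
                    density: float = 5.0, compute_mhp: bool = True,
                    params: MHPParams = MHPParams(),
                    atom_mask=None) -> SurfacePointCloud:
    """Point representation of the molecular surface with effective areas.

    ``density`` is the requested points per square angstrom of sphere
    surface.  Exact duplicate atoms (same centre and radius) are merged
    before sampling so degenerate input does not double the surface.
    """
    mask = structure.is_protein if atom_mask is None \
        else np.asarray(atom_mask, dtype=bool)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError("no atoms for surface generation")
    coords = structure.coords[idx]
    radii = structure.vdw_radius[idx]
    if np.isnan(radii).any():
        raise ValueError("VdW radii not assigned")
    # merge exact duplicates
    _, uniq = np.unique(np.round(np.column_stack([coords, radii]), 6),
                        axis=0, return_index=True)
    keep = np.sort(uniq)
    coords, radii, idx = coords[keep], radii[keep], idx[keep]

    tree = cKDTree(coords)
    rmax = radii.max()
    pts, areas, owners = [], [], []
    for a in range(len(idx)):
        r = radii[a]
        n = max(int(round(density * 4.0 * np.pi * r * r)), 12)
        dirs = _fibonacci_sphere(n)
        probe_centers = coords[a] + (r + probe) * dirs
        near = tree.query_ball_point(coords[a], r + 2 * probe + rmax)
        near = [j for j in near if j != a]
        open_mask = np.ones(n, dtype=bool)
        if near:
            near = np.array(near)
            d = np.linalg.norm(
                probe_centers[:, None, :] - coords[near][None, :, :],
                axis=2)
            open_mask = (d >= radii[near][None, :] + probe - 1e-9).all(
                axis=1)
        if open_mask.any():
            pts.append(coords[a] + r * dirs[open_mask])
            areas.append(np.full(open_mask.sum(),
                                 4.0 * np.pi * r * r / n))
            owners.append(np.full(open_mask.sum(), idx[a], dtype=int))
    if not pts:
        points = np.empty((0, 3))
        areas_arr = np.empty(0)
        owner = np.empty(0, dtype=int)
    else:
        points = np.vstack(pts)
        areas_arr = np.concatenate(areas)
        owner = np.concatenate(owners)
    mhp = np.full(len(points), np.nan)
    if compute_mhp and len(points):
        field_ = MHPField(structure, params)
        mhp = field_.at_points(points)
    return SurfacePointCloud(points, areas_arr, mhp, owner)


def exposed_subset(cloud: SurfacePointCloud, water_oxygens,
                   region=None, cutoff: float = 1.4) -> SurfacePointCloud:
    """Points with a water oxygen within ``cutoff``, inside the axial
    ``region`` (z0, z1).  No waters -> empty subset (valid)."""
    keep = np.ones(len(cloud.points), dtype=bool)
    if region is not None:
        z0, z1 = region
        keep &= (cloud.points[:, 2] >= z0) & (cloud.points[:, 2] <= z1)
    water_oxygens = np.asarray(water_oxygens, dtype=float).reshape(-1, 3)
    if len(water_oxygens) == 0:
        return cloud.subset(np.zeros(len(cloud.points), dtype=bool))
    d, _ = cKDTree(water_oxygens).query(cloud.points)
    keep &= d <= cutoff
    return cloud.subset(keep)


def _water_oxygen_mask(s: Structure) -> np.ndarray:
    return (s.category == "water") & (s.element == "O")


def _region_zwindow(s: Structure, coords, region_residues) -> tuple:
    """Axial window between boundary residues, from their Ca z means."""
    lo, hi = region_residues
    zs = []
    for rid in (lo, hi):
        m = s.is_protein & (s.res_id == rid) & (s.atom_name == "CA")
        if not m.any():
            raise KeyError(f"boundary residue {rid} not found")
        zs.append(float(coords[m, 2].mean()))
    return (min(zs), max(zs))


@dataclass
class ESAProfile:
    """Frame-averaged water-exposed surface area along the pore axis.

    ``esa_total``/``esa_hydrophobic`` are A^2 per z bin; the MHP
    histogram shares the same total area (conservation)."""
    z_edges: np.ndarray
    esa_total: np.ndarray
    esa_hydrophobic: np.ndarray
    mhp_edges: np.ndarray
    esa_by_mhp: np.ndarray
    region: tuple
    n_frames: int
    region_area: float            # frame-mean total surface area in region

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def integrated_total(self) -> float:
        return float(self.esa_total.sum())

    @property
    def integrated_hydrophobic(self) -> float:
        return float(self.esa_hydrophobic.sum())

    def to_table(self):
        import pandas as pd
        return pd.DataFrame({"z": self.z_centers,
                             "esa_total": self.esa_total,
                             "esa_hydrophobic": self.esa_hydrophobic})


def esa_profile(series: FrameSeries, region=None, region_residues=None,
                window=None, probe: float = 1.4, density: float = 5.0,
                z_bin: float = 1.0, mhp_bin: float = 0.1,
                cutoff: float = 1.4, rebuild_surface: bool = True,
                params: MHPParams = MHPParams()) -> ESAProfile:
    """ESA(z) and ESA-vs-MHP distributions averaged over the window.

    The surface cloud is rebuilt from the protein coordinates of every
    frame (set ``rebuild_surface=False`` to reuse the first frame's
    cloud for speed on static input).  ``region`` is an explicit (z0,
    z1) axial window; ``region_residues`` instead derives it per frame
    from boundary residue Ca positions (filter and gate residues).
    """
    if window is not None:
        series = series.window(window)
    topo = series.topology
    wmask = _water_oxygen_mask(topo)
    pmask = topo.is_protein

    cloud0 = None
    z_all, regions = [], []
    per_frame = []
    for fi in range(series.n_frames):
        coords = series.coords[fi]
        if region_residues is not None:
            reg = _region_zwindow(topo, coords, region_residues)
        elif region is not None:
            reg = tuple(region)
        else:
            reg = (coords[pmask, 2].min(), coords[pmask, 2].max())
        regions.append(reg)
        if rebuild_surface or cloud0 is None:
            fs = topo.copy()
            fs.coords = coords.copy()
            cloud0 = connolly_points(fs, probe, density, True, params,
                                     atom_mask=pmask)
        in_region = (cloud0.points[:, 2] >= reg[0]) \
            & (cloud0.points[:, 2] <= reg[1])
        exp = exposed_subset(cloud0, coords[wmask], reg, cutoff)
        per_frame.append((exp, float(cloud0.areas[in_region].sum())))
        z_all.append(reg)

    z0 = min(r[0] for r in regions)
    z1 = max(r[1] for r in regions)
    z_edges = np.arange(z0, z1 + z_bin, z_bin)
    mhp_vals = np.concatenate([e.mhp for e, _ in per_frame]) \
        if per_frame else np.empty(0)
    m_lo = np.floor(min(np.nanmin(mhp_vals), -1.0) / mhp_bin) * mhp_bin \
        if len(mhp_vals) else -1.0
    m_hi = np.ceil(max(np.nanmax(mhp_vals), 1.0) / mhp_bin) * mhp_bin \
        if len(mhp_vals) else 1.0
    mhp_edges = np.arange(m_lo, m_hi + mhp_bin, mhp_bin)

    esa_t = np.zeros(len(z_edges) - 1)
    esa_h = np.zeros(len(z_edges) - 1)
    esa_m = np.zeros(len(mhp_edges) - 1)
    area_sum = 0.0
    for exp, reg_area in per_frame:
        area_sum += reg_area
        if len(exp.points) == 0:
            continue
        esa_t += np.histogram(exp.points[:, 2], bins=z_edges,
                              weights=exp.areas)[0]
        hyd = exp.mhp > 0
        esa_h += np.histogram(exp.points[hyd, 2], bins=z_edges,
                              weights=exp.areas[hyd])[0]
        esa_m += np.histogram(np.clip(exp.mhp, mhp_edges[0],
                                      mhp_edges[-1]), bins=mhp_edges,
                              weights=exp.areas)[0]
    n = series.n_frames
    return ESAProfile(z_edges, esa_t / n, esa_h / n, mhp_edges,
                      esa_m / n, (z0, z1), n, area_sum / n)


@dataclass
class DeltaESA:
    """Mean ESA change B - A with replica scatter (sd >= 0)."""
    delta_total: float
    delta_hydrophobic: float
    sd_total: float
    sd_hydrophobic: float
    state_a: str = "A"
    state_b: str = "B"


def _integrated(rep) -> tuple[float, float]:
    if isinstance(rep, ESAProfile):
        return rep.integrated_total, rep.integrated_hydrophobic
    t, h = rep
    return float(t), float(h)


def delta_esa(replicas_a, replicas_b, state_a: str = "A",
              state_b: str = "B") -> DeltaESA:
    """Region-integrated ESA difference between two states.

    Each replica is an :class:`ESAProfile` (or an (ESA_T, ESA_H) pair);
    at least 2 replicas per state.  The quoted sd combines the
    per-state replica standard deviations in quadrature.
    """
    if len(replicas_a) < 2 or len(replicas_b) < 2:
        raise ValueError("need at least 2 replicas per state")
    ta, ha = np.array([_integrated(r) for r in replicas_a]).T
    tb, hb = np.array([_integrated(r) for r in replicas_b]).T
    sd_t = float(np.hypot(tb.std(ddof=1), ta.std(ddof=1)))
    sd_h = float(np.hypot(hb.std(ddof=1), ha.std(ddof=1)))
    return DeltaESA(float(tb.mean() - ta.mean()),
                    float(hb.mean() - ha.mean()), sd_t, sd_h,
                    state_a, state_b)


@dataclass
class DensityField:
    """Time-averaged number density grid and its axial profile."""
    edges: tuple                  # (x_edges, y_edges, z_edges)
    density: np.ndarray           # particles / A^3
    axial_z: np.ndarray           # bin centers
    axial_counts: np.ndarray      # mean particle count per z bin (cylinder)
    species: str
    cylinder_radius: float

    @property
    def mean_count(self) -> float:
        vol = np.prod([e[1] - e[0] for e in self.edges])
        return float(self.density.sum() * vol)


def density_profiles(series: FrameSeries, species: str, axis=None,
                     voxel: float = 1.0, cylinder_radius: float = 8.0,
                     z_bin: float = 1.0) -> DensityField:
    """3D number density of a species averaged over frames, plus the 1D
    axial profile inside a pore cylinder.

    ``species``: "water" (oxygens), "ion", or a residue name.
    """
    topo = series.topology
    if species == "water":
        mask = _water_oxygen_mask(topo)
    elif species == "ion":
        mask = topo.category == "ion"
    else:
        mask = topo.res_name == species
    if not mask.any():
        raise ValueError(f"species {species!r} absent from topology")

    all_pts = series.coords[:, mask, :].reshape(-1, 3)
    pad = 1e-9
    lo = all_pts.min(axis=0) - pad
    hi = all_pts.max(axis=0) + pad
    edges = [np.arange(lo[k], hi[k] + voxel, voxel) for k in range(3)]
    h, _ = np.histogramdd(all_pts, bins=edges)
    density = h / (series.n_frames * voxel ** 3)

    z_edges = np.arange(lo[2], hi[2] + z_bin, z_bin)
    counts = np.zeros(len(z_edges) - 1)
    for fi in range(series.n_frames):
        pts = series.coords[fi, mask, :]
        if axis is not None:
            ax_xy = np.array([axis.point(z)[:2] for z in pts[:, 2]])
            r = np.linalg.norm(pts[:, :2] - ax_xy, axis=1)
            pts = pts[r <= cylinder_radius]
        counts += np.histogram(pts[:, 2], bins=z_edges)[0]
    counts /= series.n_frames
    return DensityField(tuple(edges), density,
                        0.5 * (z_edges[:-1] + z_edges[1:]), counts,
                        species, cylinder_radius)


@dataclass
class PermeationCount:
    """Full interval traversals with hysteresis buffers."""
    total: int
    upward: int
    downward: int
    interval: tuple
    buffer: float


def count_permeation(series: FrameSeries, species: str, interval,
                     buffer: float = 2.0) -> PermeationCount:
    """Count particles whose axial trace fully traverses ``interval``.

    A crossing requires reaching beyond ``buffer`` past both ends
    (hysteresis suppresses recrossing noise at the boundaries).
    """
    topo = series.topology
    if species == "water":
        mask = _water_oxygen_mask(topo)
    elif species == "ion":
        mask = topo.category == "ion"
    else:
        mask = topo.res_name == species
    if not mask.any():
        raise ValueError(f"species {species!r} absent from topology")
    z0, z1 = sorted(interval)
    zs = series.coords[:, mask, 2]      # (frames, particles)
    up = down = 0
    for p in range(zs.shape[1]):
        side = 0
        for z in zs[:, p]:
            if z < z0 - buffer:
                if side == +1:
                    down += 1
                side = -1
            elif z > z1 + buffer:
                if side == -1:
                    up += 1
                side = +1
    return PermeationCount(up + down, up, down, (z0, z1), buffer)
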