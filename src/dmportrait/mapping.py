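"""Ray-traced cylindrical projection of the van der Waals surface.

A rectilinear (z, angle) grid is laid on a cylinder that encloses the
protein around the pore axis (or a single-helix axis).  From each grid
node's axial point a ray is cast outward, orthogonal to the local axis
tangent, and traced to its nearest intersection with any atom's van der
Waals sphere.  The traced property (MHP, decomposed into self/induced
parts by the subunit owning the hit atom, or a per-residue score) is
evaluated at the hit point and assigned to the node.  Tracing uses a
voxel grid with 3DDDA traversal: voxels are visited ordered along the
ray and the walk stops as soon as the closest intersection found lies
inside the voxel span already covered.

Integration of a 2D map over the rotation angle (mean over non-miss
nodes per z row) yields 1D axial profiles of self, induced and total
MHP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mhp import MHPField, MHPParams

__all__ = ["VoxelGrid", "CylindricalMap", "AxialProfile", "ContactMask",
           "trace_map", "integrate_profile", "helix_axis",
           "helix_map_with_contacts", "StraightAxis"]


class VoxelGrid:
    """Per-voxel candidate atom lists for ray-sphere queries.

    Every atom whose sphere's bounding box overlaps a voxel appears in
    that voxel's list (a superset of true sphere-voxel overlaps, which
    preserves correctness).
    """

    def __init__(self, coords, radii, voxel_size: float = 3.0):
        self.coords = np.asarray(coords, dtype=float)
        self.radii = np.asarray(radii, dtype=float)
        if voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        self.h = float(voxel_size)
        self.lo = (self.coords - self.radii[:, None]).min(axis=0) - 1e-9
        hi = (self.coords + self.radii[:, None]).max(axis=0) + 1e-9
        self.shape = np.maximum(
            np.ceil((hi - self.lo) / self.h).astype(int), 1)
        cells: dict[tuple, list] = {}
        lo_idx = np.floor((self.coords - self.radii[:, None] - self.lo)
                          / self.h).astype(int)
        hi_idx = np.floor((self.coords + self.radii[:, None] - self.lo)
                          / self.h).astype(int)
        lo_idx = np.clip(lo_idx, 0, self.shape - 1)
        hi_idx = np.clip(hi_idx, 0, self.shape - 1)
        for a in range(len(self.coords)):
            for i in range(lo_idx[a, 0], hi_idx[a, 0] + 1):
                for j in range(lo_idx[a, 1], hi_idx[a, 1] + 1):
                    for k in range(lo_idx[a, 2], hi_idx[a, 2] + 1):
                        cells.setdefault((i, j, k), []).append(a)
        self.cells = {k: np.array(v, dtype=int) for k, v in cells.items()}

    def traverse(self, origin, direction, t_max):
        """Yield (atom_candidates, t_exit) voxel by voxel along the ray
        (Amanatides--Woo incremental traversal), ordered by ray length."""
        o = np.asarray(origin, dtype=float)
        d = np.asarray(direction, dtype=float)
        # clip the ray to the grid box
        t0 = 0.0
        t1 = float(t_max)
        hi_edge = self.lo + self.shape * self.h
        for ax in range(3):
            if abs(d[ax]) < 1e-300:
                if o[ax] < self.lo[ax] or o[ax] > hi_edge[ax]:
                    return
                continue
            ta = (self.lo[ax] - o[ax]) / d[ax]
            tb = (hi_edge[ax] - o[ax]) / d[ax]
            if ta > tb:
                ta, tb = tb, ta
            t0 = max(t0, ta)
            t1 = min(t1, tb)
        if t0 > t1:
            return
        p = o + (t0 + 1e-12) * d
        ijk = np.floor((p - self.lo) / self.h).astype(int)
        ijk = np.clip(ijk, 0, self.shape - 1)
        step = np.where(d > 0, 1, -1)
        t_next = np.full(3, np.inf)
        t_delta = np.full(3, np.inf)
        for ax in range(3):
            if abs(d[ax]) > 1e-300:
                next_edge = self.lo[ax] + (ijk[ax] + (step[ax] > 0)) \
                    * self.h
                t_next[ax] = (next_edge - o[ax]) / d[ax]
                t_delta[ax] = self.h / abs(d[ax])
        while True:
            t_exit = float(t_next.min())
            cand = self.cells.get(tuple(ijk))
            if cand is not None:
                yield cand, min(t_exit, t1)
            if t_exit > t1:
                return
            ax = int(np.argmin(t_next))
            ijk[ax] += step[ax]
            if ijk[ax] < 0 or ijk[ax] >= self.shape[ax]:
                return
            t_next[ax] += t_delta[ax]

    def trace(self, origin, direction, t_max):
        """Nearest ray-sphere intersection: (atom index, t) or (-1, inf).

        Tangent rays (zero discriminant) count as hits; rays starting
        inside a sphere hit its exit point.
        """
        o = np.asarray(origin, dtype=float)
        d = np.asarray(direction, dtype=float)
        best_t = np.inf
        best_a = -1
        for cand, t_exit in self.traverse(o, d, t_max):
            oc = self.coords[cand] - o
            b = oc @ d
            disc = b * b - (np.einsum("ij,ij->i", oc, oc)
                            - self.radii[cand] ** 2)
            ok = disc >= 0
            if ok.any():
                sq = np.sqrt(disc[ok])
                t_in = b[ok] - sq
                t_out = b[ok] + sq
                t_hit = np.where(t_in >= 0, t_in,
                                 np.where(t_out >= 0, t_out, np.inf))
                k = int(np.argmin(t_hit))
                if t_hit[k] < best_t:
                    best_t = float(t_hit[k])
                    best_a = int(cand[ok][k])
            if best_t <= t_exit:
                break
        if best_t > t_max:
            return -1, np.inf
        return best_a, best_t


class StraightAxis:
    """A straight axis line with the PoreAxis evaluation interface."""

    def __init__(self, point_on_axis, direction):
        self.origin = np.asarray(point_on_axis, dtype=float)
        d = np.asarray(direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("zero direction")
        self.direction = d / n
        if abs(self.direction[2]) < 1e-8:
            raise ValueError("axis must not be normal to z "
                             "(z-parameterisation)")

    def point(self, z):
        t = (float(z) - self.origin[2]) / self.direction[2]
        return self.origin + t * self.direction

    def tangent(self, z):
        return self.direction.copy()

    def frame(self, z):
        t = self.direction
        ref = np.array([1.0, 0.0, 0.0])
        if abs(t @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(t, ref)
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        return u, v


@dataclass
class CylindricalMap:
    """(z, angle) property map with ray-hit metadata.

    ``values`` is the traced property (total MHP for MHP maps);
    ``self_part``/``induced_part`` are filled for MHP properties.
    ``hit_atom`` is -1 on misses; miss nodes carry NaN values.
    """
    z_grid: np.ndarray
    angle_grid: np.ndarray            # degrees, [0, 360)
    values: np.ndarray                # (nz, na)
    hit_atom: np.ndarray              # (nz, na) int, -1 = miss
    hit_subunit: np.ndarray           # (nz, na) int, -1 = miss
    hit_points: np.ndarray            # (nz, na, 3)
    projection_radius: float
    property_name: str = "mhp_total"
    self_part: np.ndarray | None = None
    induced_part: np.ndarray | None = None

    @property
    def miss(self) -> np.ndarray:
        return self.hit_atom < 0

    def write_text(self, path, sidecar=None):
        """Plain matrix text (rows: z, columns: angle) + JSON sidecar."""
        import json
        np.savetxt(path, self.values, fmt="%.5f")
        meta = {
            "z_min": float(self.z_grid[0]), "z_max": float(self.z_grid[-1]),
            "z_step": float(self.z_grid[1] - self.z_grid[0])
            if len(self.z_grid) > 1 else 0.0,
            "angle_step": float(self.angle_grid[1] - self.angle_grid[0])
            if len(self.angle_grid) > 1 else 0.0,
            "property": self.property_name,
            "units": "octanol-water logP"
            if self.property_name.startswith("mhp") else "dimensionless",
            "projection_radius": float(self.projection_radius),
            "n_miss": int(self.miss.sum()),
        }
        with open(sidecar or str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


@dataclass
class AxialProfile:
    """Angle-integrated 1D profiles; total = self + induced at every z."""
    z_grid: np.ndarray
    self_part: np.ndarray
    induced_part: np.ndarray
    total: np.ndarray
    undefined: np.ndarray             # z rows that were entirely miss

    def to_table(self):
        import pandas as pd
        return pd.DataFrame({"z": self.z_grid, "self": self.self_part,
                             "induced": self.induced_part,
                             "total": self.total})


@dataclass
class ContactMask:
    """Nodes whose surface hit point lies within the contact distance of
    any atom of the configured neighbour residues."""
    mask: np.ndarray
    criterion_distance: float
    neighbor_residues: tuple


def _angle_directions(angle_step: float, u, v):
    """Unit in-plane directions for the angular grid.

    When the grid divides into quadrants (360/step divisible by 4) the
    directions of quadrants 1-3 are exact quarter-turn images of
    quadrant 0, so C4-symmetric input maps are periodic to rounding
    error.
    """
    n = int(round(360.0 / angle_step))
    if abs(n * angle_step - 360.0) > 1e-9:
        raise ValueError("angle_step must divide 360")
    angles = np.arange(n) * angle_step
    if n % 4 == 0:
        q = n // 4
        a0 = np.radians(angles[:q])
        ab = np.column_stack([np.cos(a0), np.sin(a0)])
        quads = [ab]
        for _ in range(3):
            prev = quads[-1]
            quads.append(np.column_stack([-prev[:, 1], prev[:, 0]]))
        ab = np.vstack(quads)
    else:
        a = np.radians(angles)
        ab = np.column_stack([np.cos(a), np.sin(a)])
    dirs = ab[:, 0:1] * u[None, :] + ab[:, 1:2] * v[None, :]
    return angles, dirs


def trace_map(structure, axis, z_range=None, z_step: float = 0.5,
              angle_step: float = 2.0, property: str = "mhp",
              atom_mask=None, contributors=None, owner_subunit=None,
              residue_scores=None, params: MHPParams = MHPParams(),
              voxel_size: float = 3.0) -> CylindricalMap:
    """Trace the cylindrical projection map of ``property``.

    Parameters
    ----------
    structure : Structure with radii (and constants for MHP) assigned.
    axis : PoreAxis or StraightAxis.
    property : "mhp" (total with self/induced parts), or
        "residue_score" (lookup in ``residue_scores`` keyed by
        (chain_id, residue_number); nodes of unscored residues are NaN).
    atom_mask : optional boolean mask choosing the traced (surface)
        atoms; defaults to all protein atoms.
    contributors : optional boolean mask of atoms allowed to contribute
        to MHP sums (e.g. the helix's own subunit for self-MHP helix
        maps); defaults to all protein atoms.  When a subset is passed,
        its chains are re-indexed, so give ``owner_subunit`` explicitly
        (the owning subunit index within the contributor subset).
    """
    prot_mask = structure.is_protein if atom_mask is None \
        else np.asarray(atom_mask, dtype=bool)
    idx = np.flatnonzero(prot_mask)
    if len(idx) == 0:
        raise ValueError("no atoms selected for tracing")
    coords = structure.coords[idx]
    radii = structure.vdw_radius[idx]
    if np.isnan(radii).any():
        raise ValueError("VdW radii not assigned")
    grid = VoxelGrid(coords, radii, voxel_size)

    if z_range is None:
        if hasattr(axis, "z_range"):
            z_range = axis.z_range
        else:
            z_range = (coords[:, 2].min(), coords[:, 2].max())
    zs = np.arange(z_range[0], z_range[1] + 0.5 * z_step, z_step)

    # projection radius: encloses all traced atoms in every section
    # (bounded by the max distance from any sampled axis point)
    axis_pts = np.array([axis.point(z) for z in zs])
    dmax = 0.0
    for p in axis_pts[:: max(len(axis_pts) // 8, 1)]:
        dmax = max(dmax, float(
            (np.linalg.norm(coords - p, axis=1) + radii).max()))
    projection_radius = dmax + 0.5

    field = None
    if property == "mhp":
        contrib_structure = structure if contributors is None else \
            structure.select(np.asarray(contributors, dtype=bool))
        field = MHPField(contrib_structure, params)
    elif property == "residue_score":
        if residue_scores is None:
            raise ValueError("residue_scores required for score maps")
    elif property != "none":
        raise ValueError(f"unknown property {property!r}")

    nz = len(zs)
    u, v = axis.frame(zs[0])
    angles, _ = _angle_directions(angle_step, u, v)
    na = len(angles)
    values = np.full((nz, na), np.nan)
    self_p = np.full((nz, na), np.nan)
    induced_p = np.full((nz, na), np.nan)
    hit_atom = np.full((nz, na), -1, dtype=int)
    hit_sub = np.full((nz, na), -1, dtype=int)
    hit_pts = np.full((nz, na, 3), np.nan)

    for zi, z in enumerate(zs):
        o = axis.point(z)
        u, v = axis.frame(z)
        _, dirs = _angle_directions(angle_step, u, v)
        for ai in range(na):
            a, t = grid.trace(o, dirs[ai], projection_radius)
            if a < 0:
                continue
            gidx = int(idx[a])
            p = o + t * dirs[ai]
            hit_atom[zi, ai] = gidx
            hit_sub[zi, ai] = structure.subunit_index[gidx]
            hit_pts[zi, ai] = p
            if property == "mhp":
                owner = owner_subunit if owner_subunit is not None \
                    else int(structure.subunit_index[gidx])
                mv = field.decomposed(p, max(owner, 0))
                self_p[zi, ai] = mv.self_part
                induced_p[zi, ai] = mv.induced_part
                values[zi, ai] = mv.self_part + mv.induced_part
            elif property == "residue_score":
                key = (str(structure.chain_id[gidx]),
                       int(structure.res_id[gidx]))
                values[zi, ai] = residue_scores.get(key, np.nan)
            else:
                values[zi, ai] = t
    prop_name = {"mhp": "mhp_total", "residue_score": "residue_score",
                 "none": "hit_distance"}[property]
    return CylindricalMap(zs, angles, values, hit_atom, hit_sub, hit_pts,
                          projection_radius, prop_name,
                          self_p if property == "mhp" else None,
                          induced_p if property == "mhp" else None)


def integrate_profile(m: CylindricalMap) -> AxialProfile:
    """Mean over non-miss angular nodes per z row, for each component."""
    if m.self_part is None:
        raise ValueError("profile integration requires an MHP map")
    hit = ~m.miss
    n_hit = hit.sum(axis=1)
    undefined = n_hit == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sp = np.nanmean(np.where(hit, m.self_part, np.nan), axis=1)
        ip = np.nanmean(np.where(hit, m.induced_part, np.nan), axis=1)
    sp[undefined] = np.nan
    ip[undefined] = np.nan
    return AxialProfile(m.z_grid, sp, ip, sp + ip, undefined)


def helix_axis(ca_coords):
    """Axis of a helix from its Ca coordinates.

    Returns (center, direction): the line through the Ca centre of mass
    along the long principal axis (largest-eigenvalue eigenvector of the
    Ca gyration tensor), signed towards increasing global z (towards +x,
    then +y, when the axis is normal to z).
    """
    ca = np.asarray(ca_coords, dtype=float)
    if ca.ndim != 2 or len(ca) < 4:
        raise ValueError("need at least 4 CA atoms")
    center = ca.mean(axis=0)
    t = ca - center
    gyr = t.T @ t / len(ca)
    w, v = np.linalg.eigh(gyr)
    if (w[2] - w[1]) < 1e-6 * max(w[2], 1e-12):
        raise ValueError("degenerate inertia tensor: no unique long axis")
    axis = v[:, 2]
    for comp in (2, 0, 1):
        if abs(axis[comp]) > 1e-10:
            if axis[comp] < 0:
                axis = -axis
            break
    return center, axis


def helix_map_with_contacts(structure, helix_residues, neighbor_residues,
                            helix_chain=None, neighbor_chains=None,
                            z_step: float = 0.5, angle_step: float = 2.0,
                            contact_distance: float = 7.0,
                            params: MHPParams = MHPParams()):
    """Self-MHP map over one helix surface plus the neighbour contact mask.

    ``helix_residues`` = (first, last) author numbers on ``helix_chain``
    (default: first protein chain).  The map is traced on the helix
    fragment's own surface around its inertial axis, with MHP summed
    over the helix's own subunit only (self MHP).  The mask marks nodes
    whose hit point lies within ``contact_distance`` of any atom of
    ``neighbor_residues`` on ``neighbor_chains`` (default: all other
    protein chains).
    """
    chains = structure.protein_chains
    if helix_chain is None:
        helix_chain = chains[0]
    if neighbor_chains is None:
        neighbor_chains = [c for c in chains if c != helix_chain]
    lo, hi = helix_residues
    hmask = (structure.chain_id == helix_chain) \
        & (structure.res_id >= lo) & (structure.res_id <= hi) \
        & structure.is_protein
    if not hmask.any():
        raise ValueError("helix selection is empty")
    ca = structure.coords[hmask & (structure.atom_name == "CA")]
    center, direction = helix_axis(ca)
    axis = StraightAxis(center, direction)
    own = structure.subunit_index == \
        structure.subunit_index[np.flatnonzero(hmask)[0]]
    zlo = structure.coords[hmask, 2].min()
    zhi = structure.coords[hmask, 2].max()
    m = trace_map(structure, axis, z_range=(zlo, zhi), z_step=z_step,
                  angle_step=angle_step, property="mhp", atom_mask=hmask,
                  contributors=own, owner_subunit=0, params=params)

    nlo, nhi = neighbor_residues
    nmask = np.isin(structure.chain_id, neighbor_chains) \
        & (structure.res_id >= nlo) & (structure.res_id <= nhi) \
        & structure.is_protein
    mask = np.zeros(m.values.shape, dtype=bool)
    if not nmask.any():
        warnings.warn("empty neighbour selection: contact mask all false")
    else:
        tree = cKDTree(structure.coords[nmask])
        pts = m.hit_points[~m.miss]
        d, _ = tree.query(pts)
        mask[~m.miss] = d < contact_distance
    return m, ContactMask(mask, contact_distance, (nlo, nhi))
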