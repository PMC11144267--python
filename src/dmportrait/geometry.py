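"""Pore axis construction and HOLE-style pore-radius profiling.

The pore axis of a C4 channel is the spline through the centres of mass
of Ca quadruplets (the same residue in the four subunits).  The pore
radius at an axial position is the radius of the largest sphere that
fits without overlapping any van der Waals sphere, with the sphere
centre free to move in the plane normal to the local axis tangent
(local optimisation seeded on the axis, as in Hole2).  R_gate is the
exact minimum of the profile over the gate region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.optimize import minimize
from scipy.spatial import cKDTree

__all__ = ["PoreAxis", "RadiusProfile", "build_pore_axis",
           "radius_profile", "gate_radius"]


@dataclass
class PoreAxis:
    """Smooth curve point(z) through quadruplet centres of mass."""
    control_points: np.ndarray          # (M, 3), sorted by z

    def __post_init__(self):
        cp = np.asarray(self.control_points, dtype=float)
        if cp.ndim != 2 or cp.shape[0] < 2:
            raise ValueError("need at least 2 control points")
        order = np.argsort(cp[:, 2])
        cp = cp[order]
        if np.any(np.diff(cp[:, 2]) <= 0):
            raise ValueError("control points must be strictly ordered in z")
        self.control_points = cp
        k = min(3, len(cp) - 1)
        self._spline = make_interp_spline(cp[:, 2], cp[:, :2], k=k)
        self._dspline = self._spline.derivative()

    @property
    def z_range(self) -> tuple[float, float]:
        return (float(self.control_points[0, 2]),
                float(self.control_points[-1, 2]))

    def point(self, z):
        z = np.asarray(z, dtype=float)
        xy = self._spline(z)
        return np.concatenate([np.atleast_2d(xy),
                               np.atleast_1d(z)[:, None]], axis=1) \
            if z.ndim else np.array([xy[0], xy[1], float(z)])

    def tangent(self, z) -> np.ndarray:
        """Unit tangent at z (dz component is 1 before normalisation)."""
        dxy = self._dspline(float(z))
        t = np.array([dxy[0], dxy[1], 1.0])
        return t / np.linalg.norm(t)

    def frame(self, z):
        """Orthonormal in-plane basis (u, v) normal to the tangent."""
        t = self.tangent(z)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(t @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(t, ref)
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        return u, v


@dataclass
class RadiusProfile:
    """Pore radius along the axis; ``capped`` marks z where no atom
    limited the sphere within the search range."""
    z_grid: np.ndarray
    radius: np.ndarray
    centers: np.ndarray = None
    capped: np.ndarray = field(default=None)
    gate_region: tuple[float, float] | None = None

    def __post_init__(self):
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if self.capped is None:
            self.capped = np.zeros(len(self.z_grid), dtype=bool)

    @property
    def r_gate(self) -> float:
        if self.gate_region is None:
            raise ValueError("no gate region configured")
        return gate_radius(self, self.gate_region)

    def to_table(self):
        import pandas as pd
        return pd.DataFrame({"z": self.z_grid, "radius": self.radius,
                             "capped": self.capped})


def build_pore_axis(structure, axis_residues, chains=None) -> PoreAxis:
    """Spline through centres of mass of Ca quadruplets.

    ``axis_residues`` are author residue numbers present (with a Ca) in
    every subunit; ``chains`` defaults to all protein chains.
    """
    chains = chains or structure.protein_chains
    points = []
    for rid in axis_residues:
        cas = []
        for ch in chains:
            try:
                cas.append(structure.coords[structure.ca_index(ch, rid)])
            except KeyError:
                raise KeyError(
                    f"axis residue {rid} missing (or no CA) in chain {ch}")
        points.append(np.mean(cas, axis=0))
    if len(points) < 2:
        raise ValueError("need at least 2 axis control points")
    return PoreAxis(np.array(points))


def _pore_radius_at(coords, radii, tree, center0, u, v, max_radius,
                    step_limit):
    """Maximise min_i(|c - x_i| - R_i) over in-plane displacements."""
    # every atom that could limit any centre within the step box
    search = max_radius + radii.max() + 1.5 * step_limit
    near = tree.query_ball_point(center0, search)
    coords_n = coords[near]
    radii_n = radii[near]

    def clearance(ab):
        if len(coords_n) == 0:
            return max_radius
        c = center0 + ab[0] * u + ab[1] * v
        d = np.linalg.norm(coords_n - c, axis=1) - radii_n
        return min(d.min(), max_radius)

    if len(coords_n) == 0:
        return max_radius, center0.copy()

    # coarse grid pre-search locates the right basin, Nelder-Mead
    # polishes from the best coarse seeds (the clearance landscape can
    # hold several local maxima off the axis)
    g = np.arange(-step_limit, step_limit + 1e-9, 0.25)
    ga, gb = np.meshgrid(g, g)
    ab_grid = np.column_stack([ga.ravel(), gb.ravel()])
    centers = center0 + ab_grid[:, 0, None] * u + ab_grid[:, 1, None] * v
    d = np.linalg.norm(centers[:, None, :] - coords_n[None], axis=2) \
        - radii_n[None]
    coarse = d.min(axis=1)
    order = np.argsort(coarse)[::-1]
    seeds = [ab_grid[i] for i in order[:3]]
    if coarse[order[0]] < max_radius:
        seeds.append(np.zeros(2))

    def objective(ab):
        # box constraint: evaluate at the clipped point with a linear
        # penalty (clearance is 1-Lipschitz, slope 2 dominates it)
        inside = np.clip(ab, -step_limit, step_limit)
        return -clearance(inside) + 2.0 * np.abs(ab - inside).sum()

    best_r, best_ab = -np.inf, np.zeros(2)
    for seed in seeds:
        res = minimize(objective, np.asarray(seed),
                       method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-6,
                                "maxiter": 200})
        ab = np.clip(res.x, -step_limit, step_limit)
        r = clearance(ab)
        if r > best_r:
            best_r, best_ab = r, ab
        if best_r >= max_radius:
            break
    return best_r, center0 + best_ab[0] * u + best_ab[1] * v


def radius_profile(structure, axis: PoreAxis, z_step: float = 0.25,
                   z_range=None, max_radius: float = 15.0,
                   step_limit: float = 2.5,
                   gate_region=None) -> RadiusProfile:
    """HOLE-like pore radius profile along the axis.

    At each z the largest clearance sphere is found by Nelder--Mead over
    centre positions in the plane normal to the local tangent, seeded at
    the axis point and step-limited (``step_limit``) so the sphere
    stays in the lumen instead of escaping through inter-helix gaps.  Radii above ``max_radius`` are capped and
    flagged.
    """
    prot = structure.protein()
    if prot.n_atoms == 0:
        raise ValueError("no protein atoms")
    radii = prot.vdw_radius
    if np.isnan(radii).any():
        raise ValueError("VdW radii not assigned")
    tree = cKDTree(prot.coords)
    z0, z1 = z_range if z_range is not None else axis.z_range
    zs = np.arange(z0, z1 + 0.5 * z_step, z_step)
    rs = np.empty(len(zs))
    caps = np.zeros(len(zs), dtype=bool)
    centers = np.empty((len(zs), 3))
    for k, z in enumerate(zs):
        p0 = axis.point(z)
        u, v = axis.frame(z)
        r, c = _pore_radius_at(prot.coords, radii, tree, p0, u, v,
                               max_radius, step_limit)
        rs[k] = max(r, 0.0)
        caps[k] = r >= max_radius
        centers[k] = c
    return RadiusProfile(zs, rs, centers, caps, gate_region)


def gate_radius(profile: RadiusProfile, gate_region) -> float:
    """Exact minimum of the radius profile over ``gate_region`` (z0, z1).

    On ties the minimum value is returned (the reported position, when
    needed, is the lowest-z occurrence).
    """
    z0, z1 = gate_region
    inside = (profile.z_grid >= z0) & (profile.z_grid <= z1)
    if not inside.any():
        raise ValueError("gate region contains no profile points")
    return float(profile.radius[inside].min())
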