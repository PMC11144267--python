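"""Synthetic C4-symmetric pore fixtures.

Generates ideal four-helix bundles that stand in for the S6 bundle of a
tetrameric channel: each subunit is an ideal helix built from internal
coordinates (standard backbone bond lengths/angles, per-residue phi/psi)
with heavy-atom side chains grafted from ideal residue templates, four
copies placed on a circle by exact quarter-turn rotations so the
assembly has bit-exact C4 symmetry.  The lumen radius is calibrated to a
target.  Pseudo-hydration frames (uniform lumen waters, axial ions,
seeded Gaussian protein jitter) emulate trajectory input; they carry no
solvation physics.

The default pore mimics the published S6 architecture: a hydrophobic
Ile ring ("gate") with an Asn ring one turn above it on the pore-facing
face, the remaining lumen face Leu/Ala.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .structure import Structure, FrameSeries, assign_radii, \
    assign_hydrophobicity

__all__ = ["PoreSpec", "make_c4_pore", "make_hydrated_frames",
           "make_helix", "ALPHA_DIHEDRALS", "PI_DIHEDRALS",
           "EXTENDED_DIHEDRALS"]

# ideal backbone geometry (angstrom, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.5

ALPHA_DIHEDRALS = (-57.0, -47.0)
PI_DIHEDRALS = (-57.0, -70.0)
EXTENDED_DIHEDRALS = (-180.0, 180.0)


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF: position d with |cd|=bond, angle(b,c,d), dihedral(a,b,c,d)."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(theta),
                  bond * np.sin(theta) * np.cos(chi),
                  bond * np.sin(theta) * np.sin(chi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _kabsch(mobile, target):
    """Rotation R, translation t with R @ mobile_i + t ~ target_i."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, tc - r @ mc


_TEMPLATE_CACHE: dict[str, tuple] = {}


def _sidechain_template(res_name: str):
    """Ideal heavy-atom side chain + backbone frame from the CCD."""
    if res_name not in _TEMPLATE_CACHE:
        import biotite.structure.info as info
        res = info.residue(res_name)
        res = res[res.element != "H"]
        names = list(res.atom_name)
        frame = np.array([res.coord[names.index(n)]
                          for n in ("N", "CA", "C")])
        keep = [i for i, n in enumerate(names)
                if n not in ("N", "CA", "C", "O", "OXT")]
        _TEMPLATE_CACHE[res_name] = (frame,
                                     [names[i] for i in keep],
                                     res.coord[keep].copy(),
                                     [res.element[i] for i in keep])
    return _TEMPLATE_CACHE[res_name]


def make_helix(sequence, dihedrals=ALPHA_DIHEDRALS, chain_id="A",
               first_res_id=1) -> Structure:
    """Build an ideal helix (or extended chain) from internal coordinates.

    ``dihedrals``: a single (phi, psi) pair applied to every residue, or
    a list of per-residue pairs.  Heavy atoms only.
    """
    nres = len(sequence)
    if np.ndim(dihedrals[0]) == 0 and len(dihedrals) == 2:
        dihedrals = [tuple(dihedrals)] * nres
    if len(dihedrals) != nres:
        raise ValueError("one (phi, psi) pair per residue required")

    bb = []  # list of dicts per residue
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([B_N_CA, 0.0, 0.0])
    theta = np.radians(A_N_CA_C)
    c = ca + B_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])
    bb.append({"N": n, "CA": ca, "C": c})
    for i in range(1, nres):
        phi_prev, psi_prev = dihedrals[i - 1]
        phi_i = dihedrals[i][0]
        p = bb[-1]
        n = _place(p["N"], p["CA"], p["C"], B_C_N, A_CA_C_N, psi_prev)
        ca = _place(p["CA"], p["C"], n, B_N_CA, A_C_N_CA, 180.0)
        c = _place(p["C"], n, ca, B_CA_C, A_N_CA_C, phi_i)
        bb.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens: anti to the next amide nitrogen
    for i, res in enumerate(bb):
        psi = dihedrals[i][1]
        res["O"] = _place(res["N"], res["CA"], res["C"], B_C_O, A_CA_C_O,
                          psi + 180.0)

    coords, names, resnames, resids, elements = [], [], [], [], []
    for i, (res_name, res) in enumerate(zip(sequence, bb)):
        for nm in ("N", "CA", "C", "O"):
            coords.append(res[nm])
            names.append(nm)
            elements.append(nm[0])
            resnames.append(res_name)
            resids.append(first_res_id + i)
        if res_name != "GLY":
            frame, sc_names, sc_coords, sc_elements = \
                _sidechain_template(res_name)
            rot, trans = _kabsch(frame, np.array([res["N"], res["CA"],
                                                  res["C"]]))
            for nm, xyz, el in zip(sc_names, sc_coords @ rot.T + trans,
                                   sc_elements):
                coords.append(xyz)
                names.append(nm)
                elements.append(el)
                resnames.append(res_name)
                resids.append(first_res_id + i)
    s = Structure(np.array(coords), elements, names, resnames, resids,
                  [chain_id] * len(coords))
    assign_radii(s)
    assign_hydrophobicity(s)
    return s


def _rot_z_exact(coords, quarter_turns):
    """Exact rotation by multiples of 90 degrees about z."""
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    q = quarter_turns % 4
    if q == 0:
        out = (x, y)
    elif q == 1:
        out = (-y, x)
    elif q == 2:
        out = (-x, -y)
    else:
        out = (y, -x)
    return np.column_stack([out[0], out[1], z])


def _default_sequence(length, gate_index, hydrophobic_lumen=True):
    seq = ["ALA"] * length
    for i in range(0, length, 7):
        seq[i] = "LEU"
    if hydrophobic_lumen:
        seq[gate_index] = "ILE"
        if gate_index >= 4:
            seq[gate_index - 4] = "ASN"   # one turn above the gate ring
    else:
        seq[gate_index] = "SER"
        if gate_index >= 4:
            seq[gate_index - 4] = "ASN"
    return seq


@dataclass
class PoreSpec:
    """Specification of a synthetic C4 pore.

    ``lumen_radius`` is the target minimal pore radius (angstrom);
    ``gate_index`` the 0-based residue whose side chain faces the pore
    at the constriction.  ``tilt`` tips each helix off the pore axis.
    """
    helix_length: int = 22
    sequence: list | None = None
    lumen_radius: float = 2.3
    gate_index: int = 12
    hydrophobic_lumen: bool = True
    tilt: float = 0.0            # degrees
    dihedrals: tuple = ALPHA_DIHEDRALS
    seed: int = 0
    n_helices: int = 4           # fixed C4

    def resolved_sequence(self):
        if self.sequence is not None:
            if len(self.sequence) != self.helix_length:
                raise ValueError("sequence length != helix_length")
            return list(self.sequence)
        return _default_sequence(self.helix_length, self.gate_index,
                                 self.hydrophobic_lumen)


def _oriented_monomer(spec: PoreSpec) -> Structure:
    """Helix aligned with +z, centred at origin, gate side chain at
    azimuth 180 deg (facing -x, i.e. towards the pore axis once the
    helix is shifted to +x)."""
    seq = spec.resolved_sequence()
    helix = make_helix(seq, spec.dihedrals, chain_id="A")
    ca = helix.coords[helix.atom_name == "CA"]
    center = ca.mean(axis=0)
    t = ca - center
    w, v = np.linalg.eigh(t.T @ t)
    axis = v[:, -1]
    if axis[2] < 0:
        axis = -axis
    ref = np.array([1.0, 0.0, 0.0])
    u1 = np.cross(ref, axis)
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(axis, u1)
    rot = np.array([u1, u2, axis])      # rows: new x, y, z axes
    coords = (helix.coords - center) @ rot.T
    # azimuth of the gate side chain (outermost side-chain atom)
    gate_mask = (helix.res_id == 1 + spec.gate_index) \
        & ~np.isin(helix.atom_name, ["N", "CA", "C", "O"])
    if not gate_mask.any():
        gate_mask = (helix.res_id == 1 + spec.gate_index) \
            & (helix.atom_name == "CA")
    g = coords[gate_mask]
    far = g[np.argmax(np.hypot(g[:, 0], g[:, 1]))]
    phi0 = np.arctan2(far[1], far[0])
    dphi = np.pi - phi0
    cd, sd = np.cos(dphi), np.sin(dphi)
    coords = coords @ np.array([[cd, sd, 0], [-sd, cd, 0], [0, 0, 1.0]]).T
    if spec.tilt:
        tt = np.radians(spec.tilt)
        ct, st = np.cos(tt), np.sin(tt)
        coords = coords @ np.array([[ct, 0, st], [0, 1, 0],
                                    [-st, 0, ct]]).T
    out = helix.copy()
    out.coords = coords
    return out


def _min_lumen(coords, radii):
    return float((np.hypot(coords[:, 0], coords[:, 1]) - radii).min())


def _grid_pore_min(coords, radii, zs, halfwidth: float = 2.0) -> float:
    """min over z of the largest sphere inscribable in the lumen plane,
    by coarse-then-fine grid search over in-plane centre positions."""
    best_over_z = np.inf
    for z in zs:
        near = np.abs(coords[:, 2] - z) < 8.0
        c, r = coords[near], radii[near]

        def biggest(cx, cy, grid):
            centers = np.column_stack([
                np.add.outer(grid, np.zeros_like(grid)).ravel() + cx,
                np.add.outer(np.zeros_like(grid), grid).ravel() + cy,
                np.full(grid.size ** 2, z)])
            d = np.linalg.norm(centers[:, None, :] - c[None], axis=2) \
                - r[None]
            clear = d.min(axis=1)
            k = int(np.argmax(clear))
            return float(clear[k]), centers[k, 0], centers[k, 1]

        v, bx, by = biggest(0.0, 0.0,
                            np.arange(-halfwidth, halfwidth + 0.1, 0.2))
        v, _, _ = biggest(bx, by, np.arange(-0.12, 0.13, 0.02))
        best_over_z = min(best_over_z, v)
    return best_over_z


def _assemble(mono: Structure, d: float) -> Structure:
    coords, names, resnames, resids, chains, elements = \
        [], [], [], [], [], []
    base = mono.coords + np.array([d, 0.0, 0.0])
    for q in range(4):
        coords.append(_rot_z_exact(base, q))
        names.extend(mono.atom_name)
        resnames.extend(mono.res_name)
        resids.extend(mono.res_id)
        elements.extend(mono.element)
        chains.extend([string.ascii_uppercase[q]] * mono.n_atoms)
    s = Structure(np.vstack(coords), elements, names, resnames, resids,
                  chains)
    assign_radii(s)
    assign_hydrophobicity(s)
    return s


def make_c4_pore(spec: PoreSpec = PoreSpec()) -> Structure:
    """Assemble the four-helix pore with the target lumen radius.

    The radial helix placement is first coarse-tuned on the clearance
    between the z axis and the nearest van der Waals sphere, then
    refined so that the minimal pore radius in the HOLE sense (largest
    inscribed sphere, free to move off-axis) over the central band
    matches ``spec.lumen_radius``.  Raises for infeasible geometry.
    """
    if spec.lumen_radius <= 0:
        raise ValueError("lumen radius must be positive")
    mono = _oriented_monomer(spec)
    radii = mono.vdw_radius
    inner = _min_lumen(mono.coords, radii)   # most negative: inward reach
    d = spec.lumen_radius - inner + 1.0
    for _ in range(12):
        shifted = mono.coords + np.array([d, 0.0, 0.0])
        cur = _min_lumen(shifted, radii)
        err = spec.lumen_radius - cur
        if abs(err) < 0.02:
            break
        d += err
    else:
        raise ValueError("lumen calibration failed (infeasible geometry)")
    if d <= 0:
        raise ValueError("infeasible geometry: helices overlap the axis")

    # refine against the maximal-inscribed-sphere lumen radius (the
    # HOLE-sense pore radius: the sphere may sit off-axis between the
    # side chains), measured on a deterministic dense grid over the
    # constriction band around the innermost gate-ring atom
    shifted = mono.coords + np.array([d, 0.0, 0.0])
    inner_atom = int(np.argmin(np.hypot(shifted[:, 0], shifted[:, 1])
                               - radii))
    z_inner = float(mono.coords[inner_atom, 2])
    zs = np.arange(z_inner - 3.0, z_inner + 3.01, 0.5)

    def measure(dd):
        s = _assemble(mono, dd)
        return s, _grid_pore_min(s.coords, s.vdw_radius, zs)

    s, m = measure(d)
    prev_d, prev_m = None, None
    for _ in range(15):
        err = spec.lumen_radius - m
        if abs(err) < 0.03:
            return s
        if prev_d is None or abs(m - prev_m) < 1e-9:
            step = err
        else:
            slope = (m - prev_m) / (d - prev_d)
            slope = min(max(slope, 0.3), 3.0)
            step = err / slope
        prev_d, prev_m = d, m
        d += step
        if d <= 0:
            raise ValueError("infeasible geometry: helices overlap "
                             "the axis")
        s, m = measure(d)
    raise ValueError("lumen calibration failed (infeasible geometry)")


def make_hydrated_frames(s: Structure, n_frames: int = 20,
                         water_density: float = 0.3,
                         water_radius: float | None = None,
                         ion_count: int = 0,
                         jitter: float = 0.05,
                         dry_zband=None,
                         ion_walk=None,
                         seed: int = 0) -> FrameSeries:
    """Pseudo-hydration frames over a synthetic pore.

    Waters (single O particles, resname HOH) are placed uniformly at
    random inside the lumen cylinder each frame (``water_density`` per
    cubic angstrom over the cylinder volume), optionally excluding a dry
    z-band; ions (NA) sit on the axis, or walk linearly from
    ``ion_walk=(z_start, z_end)`` across the frames.  Protein
    coordinates receive Gaussian jitter per frame.  Deterministic for a
    fixed seed.
    """
    if jitter < 0 or jitter > 0.5:
        raise ValueError("jitter must be small (<= 0.5 A)")
    rng = np.random.default_rng(seed)
    prot = s.protein()
    zlo = prot.coords[:, 2].min() + 2.0
    zhi = prot.coords[:, 2].max() - 2.0
    if water_radius is None:
        # cover the lumen and the first shell of the pore wall
        water_radius = max(2.0, _min_lumen(prot.coords,
                                           prot.vdw_radius) + 3.0)
    volume = np.pi * water_radius ** 2 * (zhi - zlo)
    n_w = max(1, int(round(water_density * volume)))

    def sample_waters():
        pts = np.empty((n_w, 3))
        k = 0
        while k < n_w:
            cand = np.column_stack([
                rng.uniform(-water_radius, water_radius, 4 * n_w),
                rng.uniform(-water_radius, water_radius, 4 * n_w),
                rng.uniform(zlo, zhi, 4 * n_w)])
            ok = np.hypot(cand[:, 0], cand[:, 1]) <= water_radius
            if dry_zband is not None:
                ok &= ~((cand[:, 2] >= dry_zband[0])
                        & (cand[:, 2] <= dry_zband[1]))
            cand = cand[ok]
            take = min(len(cand), n_w - k)
            pts[k:k + take] = cand[:take]
            k += take
        return pts

    if ion_walk is not None:
        ion_count = max(ion_count, 1)
    ion_z0 = rng.uniform(zlo, zhi, size=ion_count)

    frames = []
    for fi in range(n_frames):
        pc = prot.coords + rng.normal(0.0, jitter, prot.coords.shape) \
            if jitter > 0 else prot.coords.copy()
        wat = sample_waters()
        ions = np.column_stack([np.zeros(ion_count), np.zeros(ion_count),
                                ion_z0.copy()]) if ion_count else \
            np.empty((0, 3))
        if ion_walk is not None and ion_count:
            frac = fi / max(n_frames - 1, 1)
            ions[0, 2] = ion_walk[0] + frac * (ion_walk[1] - ion_walk[0])
        frames.append(np.vstack([pc, wat, ions]))

    topo = Structure(
        frames[0],
        list(prot.element) + ["O"] * n_w + ["NA"] * ion_count,
        list(prot.atom_name) + ["O"] * n_w + ["NA"] * ion_count,
        list(prot.res_name) + ["HOH"] * n_w + ["NA"] * ion_count,
        list(prot.res_id) + list(range(1, n_w + 1))
        + list(range(n_w + 1, n_w + ion_count + 1)),
        list(prot.chain_id) + ["W"] * n_w + ["I"] * ion_count,
        list(prot.category) + ["water"] * n_w + ["ion"] * ion_count)
    assign_radii(topo)
    assign_hydrophobicity(topo, on_missing="nan")
    return FrameSeries(topo, np.array(frames),
                       np.arange(n_frames, dtype=float))
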