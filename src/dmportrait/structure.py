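"""Structure and trajectory I/O with atomic parameter assignment.

The central container is :class:`Structure`, a column-oriented set of
atom records (coordinates, element, van der Waals radius, atomic
hydrophobicity constant, residue identity) partitioned into subunits by
chain.  Structures are read from PDB/mmCIF with gemmi, preserving author
residue numbering and resolving alternate locations to the highest
occupancy conformer (first seen wins ties).  Trajectory frames are read
through MDAnalysis into a :class:`FrameSeries`.

Atomic hydrophobicity constants are per-heavy-atom octanol--water logP
contributions after the Wildman--Crippen typing, shipped as versioned
data (``data/wildman_crippen_residue_logp.json``); hydrogens, when
present, contribute zero because their share is already folded into
their heavy neighbour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "AtomRecord", "Structure", "FrameSeries",
    "load_structure", "assign_radii", "assign_hydrophobicity",
    "load_frames", "write_multimodel_pdb",
]

WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP", "TIP3", "SPC", "H2O"}
ION_RESNAMES = {"NA", "CL", "K", "CA", "MG", "ZN", "SOD", "CLA", "POT",
                "CAL", "LI", "RB", "CS", "BR", "IOD", "F"}
BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}
STANDARD_AA = {"ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY",
               "HIS", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER",
               "THR", "TRP", "TYR", "VAL"}


def _data_json(name: str) -> dict:
    with resources.files("dmportrait.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass
class AtomRecord:
    """A single atom, as returned by :meth:`Structure.atom`."""
    position: np.ndarray
    element: str
    vdw_radius: float
    hydro_const: float
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    subunit_index: int


class Structure:
    """Column-oriented atom set with a subunit partition.

    Parameters
    ----------
    coords : (N, 3) float array, angstrom
    element, atom_name, res_name, chain_id : (N,) string arrays
    res_id : (N,) int array (author numbering)
    category : (N,) strings in {"protein", "water", "ion", "other"}
    """

    def __init__(self, coords, element, atom_name, res_name, res_id,
                 chain_id, category=None, occupancy=None):
        self.coords = np.ascontiguousarray(coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        self.element = np.asarray(element, dtype="U2")
        self.atom_name = np.asarray(atom_name, dtype="U6")
        self.res_name = np.asarray(res_name, dtype="U4")
        self.res_id = np.asarray(res_id, dtype=np.int64)
        self.chain_id = np.asarray(chain_id, dtype="U4")
        if category is None:
            category = np.full(n, "protein", dtype="U7")
        self.category = np.asarray(category, dtype="U7")
        self.occupancy = (np.ones(n) if occupancy is None
                          else np.asarray(occupancy, dtype=float))
        for arr in (self.element, self.atom_name, self.res_name,
                    self.res_id, self.chain_id, self.category,
                    self.occupancy):
            if len(arr) != n:
                raise ValueError("field length mismatch")
        self.vdw_radius = np.full(n, np.nan)
        self.hydro_const = np.full(n, np.nan)
        self._rebuild_partition()

    # -- partition ---------------------------------------------------------

    def _rebuild_partition(self):
        """Assign subunit indices to protein chains in file order."""
        self.subunit_index = np.full(self.n_atoms, -1, dtype=np.int32)
        prot = self.category == "protein"
        chains = []
        for c in self.chain_id[prot]:
            if c not in chains:
                chains.append(c)
        self._protein_chains = chains
        for i, c in enumerate(chains):
            self.subunit_index[prot & (self.chain_id == c)] = i

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def n_subunits(self) -> int:
        return len(self._protein_chains)

    @property
    def protein_chains(self) -> list[str]:
        return list(self._protein_chains)

    @property
    def is_protein(self) -> np.ndarray:
        return self.category == "protein"

    def subunit_atoms(self, index: int) -> np.ndarray:
        """Indices of protein atoms belonging to subunit ``index``."""
        if not 0 <= index < self.n_subunits:
            raise IndexError(f"subunit {index} out of range")
        return np.flatnonzero(self.subunit_index == index)

    # -- selection ---------------------------------------------------------

    def select(self, mask) -> "Structure":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        s = Structure(self.coords[idx], self.element[idx],
                      self.atom_name[idx], self.res_name[idx],
                      self.res_id[idx], self.chain_id[idx],
                      self.category[idx], self.occupancy[idx])
        s.vdw_radius = self.vdw_radius[idx].copy()
        s.hydro_const = self.hydro_const[idx].copy()
        return s

    def protein(self) -> "Structure":
        return self.select(self.is_protein)

    def residue_atoms(self, chain_id: str, residue_number: int) -> np.ndarray:
        """Atom indices of one residue; raises KeyError when absent."""
        idx = np.flatnonzero((self.chain_id == chain_id)
                             & (self.res_id == residue_number))
        if len(idx) == 0:
            raise KeyError(f"residue {chain_id}/{residue_number} not present")
        return idx

    def ca_index(self, chain_id: str, residue_number: int) -> int:
        idx = self.residue_atoms(chain_id, residue_number)
        ca = idx[self.atom_name[idx] == "CA"]
        if len(ca) == 0:
            raise KeyError(f"no CA in residue {chain_id}/{residue_number}")
        return int(ca[0])

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(self.coords[i].copy(), str(self.element[i]),
                          float(self.vdw_radius[i]),
                          float(self.hydro_const[i]),
                          str(self.chain_id[i]), int(self.res_id[i]),
                          str(self.res_name[i]), str(self.atom_name[i]),
                          int(self.subunit_index[i]))

    def copy(self) -> "Structure":
        return self.select(np.arange(self.n_atoms))

    # -- output ------------------------------------------------------------

    def to_table(self) -> "pandas.DataFrame":  # noqa: F821
        import pandas as pd
        return pd.DataFrame({
            "chain": self.chain_id, "res_id": self.res_id,
            "res_name": self.res_name, "atom_name": self.atom_name,
            "element": self.element, "category": self.category,
            "subunit": self.subunit_index,
            "x": self.coords[:, 0], "y": self.coords[:, 1],
            "z": self.coords[:, 2],
            "vdw_radius": self.vdw_radius, "hydro_const": self.hydro_const,
        })

    def write_tsv(self, path):
        self.to_table().to_csv(path, sep="\t", index=False,
                               float_format="%.4f")

    def write_pdb(self, path):
        with open(path, "w") as fh:
            fh.write(_pdb_block(self))
            fh.write("END\n")


def _pdb_block(s: Structure, serial_start: int = 1) -> str:
    lines = []
    serial = serial_start
    for i in range(s.n_atoms):
        rec = "ATOM  " if s.category[i] == "protein" else "HETATM"
        name = s.atom_name[i]
        # PDB name column convention: element right-aligned in cols 13-14
        name_f = f" {name:<3s}" if len(name) < 4 and len(s.element[i]) < 2 \
            else f"{name:<4s}"
        x, y, z = s.coords[i]
        lines.append(
            f"{rec}{serial % 100000:5d} {name_f} {s.res_name[i]:<3s}"
            f" {s.chain_id[i][:1] or 'A'}{s.res_id[i] % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{s.occupancy[i]:6.2f}{0.0:6.2f}"
            f"          {s.element[i]:>2s}")
        serial += 1
    return "\n".join(lines) + "\n"


# -- reading ---------------------------------------------------------------

def load_structure(path, fmt: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Alternate locations are resolved to the highest-occupancy conformer
    (first seen on ties); waters and monoatomic ions are kept but
    categorised separately from protein.  Author residue numbering is
    preserved.  Radii and hydrophobicity constants are assigned.
    """
    import gemmi
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "pdb" or (fmt is None and path.suffix.lower() in
                            (".pdb", ".ent")):
            st = gemmi.read_pdb(str(path))
        elif fmt in ("cif", "mmcif") or (fmt is None and
                                         path.suffix.lower() == ".cif"):
            st = gemmi.make_structure_from_block(
                gemmi.cif.read(str(path)).sole_block())
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from None
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]

    rows = []
    for chain in model:
        for res in chain:
            seen: dict[str, tuple[float, int]] = {}
            picked = []
            for atom in res:
                occ = atom.occ if atom.occ > 0 else 1.0
                alt = atom.altloc.strip("\x00").strip()
                prev = seen.get(atom.name)
                if prev is None:
                    seen[atom.name] = (occ, len(picked))
                    picked.append(atom)
                elif alt and occ > prev[0]:
                    seen[atom.name] = (occ, prev[1])
                    picked[prev[1]] = atom
                elif not alt and \
                        not picked[prev[1]].altloc.strip("\x00").strip():
                    raise ValueError(
                        f"duplicate atom {chain.name}/{res.seqid.num}"
                        f"/{atom.name} in {path}")
            if res.is_water():
                cat = "water"
            elif res.name.strip() in ION_RESNAMES and len(res) == 1:
                cat = "ion"
            elif res.name.strip() in STANDARD_AA or \
                    (any(a.name == "CA" for a in res)
                     and any(a.name == "N" for a in res)):
                cat = "protein"
            else:
                cat = "other"
            for atom in picked:
                rows.append((atom.pos.x, atom.pos.y, atom.pos.z,
                             atom.element.name.upper(), atom.name,
                             res.name.strip(), res.seqid.num,
                             chain.name, cat, atom.occ))
    if not rows:
        raise ValueError(f"{path}: no atoms")
    cols = list(zip(*rows))
    s = Structure(np.array(cols[0:3]).T, cols[3], cols[4], cols[5],
                  cols[6], cols[7], cols[8], cols[9])
    if s.n_subunits == 0:
        raise ValueError(f"{path}: zero protein atoms")
    assign_radii(s)
    assign_hydrophobicity(s, on_missing="nan")
    return s


def assign_radii(s: Structure, table: dict | None = None) -> Structure:
    """Assign per-atom van der Waals radii from the element table."""
    if table is None:
        table = _data_json("vdw_radii.json")["radii"]
    default = table.get("default", 1.8)
    for el in np.unique(s.element):
        r = table.get(el.upper(), default)
        s.vdw_radius[s.element == el] = r
    return s


def assign_hydrophobicity(s: Structure, scheme: dict | None = None,
                          on_missing: str = "error") -> Structure:
    """Assign Wildman--Crippen hydrophobicity constants to heavy atoms.

    Protein heavy atoms are typed by (residue name, atom name); explicit
    hydrogens get 0 (their share is folded into the heavy-atom
    constants).  Non-protein atoms get 0 and are excluded from MHP sums
    downstream.

    ``on_missing``: "error" raises listing the offending residues,
    "nan" leaves the constant unassigned (NaN), "zero" forces 0.
    """
    if scheme is None:
        scheme = _data_json("wildman_crippen_residue_logp.json")
    residues = scheme["residues"]
    terminal = scheme.get("terminal", {})
    missing = set()
    out = np.zeros(s.n_atoms)
    for i in range(s.n_atoms):
        if s.category[i] != "protein":
            continue
        if s.element[i] == "H":
            continue
        name = s.atom_name[i]
        entry = residues.get(s.res_name[i])
        if entry is not None and name in entry:
            out[i] = entry[name]
        elif name in terminal:
            out[i] = terminal[name]
        else:
            missing.add((s.res_name[i], name,
                         f"{s.chain_id[i]}/{s.res_id[i]}"))
            out[i] = np.nan
    if missing and on_missing == "error":
        raise ValueError("untypeable atoms: "
                         + ", ".join(sorted(f"{r}:{a} ({w})"
                                            for r, a, w in missing)))
    if missing and on_missing == "zero":
        out = np.nan_to_num(out)
    s.hydro_const = out
    return s


# -- trajectory frames -----------------------------------------------------

@dataclass
class FrameSeries:
    """Coordinate frames over a fixed topology.

    ``coords`` has shape (n_frames, n_atoms, 3) in angstrom; ``times``
    are in ps (frame index for readers that carry no time).
    """
    topology: Structure
    coords: np.ndarray
    times: np.ndarray = field(default=None)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or \
                self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("frame atom count does not match topology")
        if self.times is None:
            self.times = np.arange(len(self.coords), dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.coords):
            raise ValueError("times/frames length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    def frame_structure(self, i: int) -> Structure:
        s = self.topology.copy()
        s.coords = self.coords[i].copy()
        return s

    def window(self, spec) -> "FrameSeries":
        """Select an analysis window.

        ``spec``: None (all frames), a float f in (0, 1] (the last
        fraction f of frames, e.g. 0.25 for the last quarter), or a
        (t0, t1) time interval in the units of ``times``.
        """
        if spec is None:
            keep = np.arange(self.n_frames)
        elif np.isscalar(spec):
            f = float(spec)
            if not 0 < f <= 1:
                raise ValueError("fraction window must be in (0, 1]")
            n = int(round(f * self.n_frames))
            keep = np.arange(self.n_frames - n, self.n_frames)
        else:
            t0, t1 = spec
            keep = np.flatnonzero((self.times >= t0) & (self.times <= t1))
        if len(keep) == 0:
            raise ValueError("empty analysis window")
        return FrameSeries(self.topology, self.coords[keep],
                           self.times[keep])


def load_frames(topology: Structure, trajectory, window=None) -> FrameSeries:
    """Read trajectory frames (any MDAnalysis-readable coordinate format,
    e.g. multi-model PDB, XTC, DCD) over ``topology``; keep ``window``."""
    import MDAnalysis as mda
    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    try:
        u.load_new(str(trajectory))
    except IndexError:
        raise ValueError(
            f"trajectory {trajectory} atom count does not match the "
            f"topology ({topology.n_atoms} atoms)") from None
    except (ValueError, OSError, IOError) as exc:
        raise ValueError(f"cannot read trajectory {trajectory}: {exc}") \
            from None
    if u.trajectory.n_atoms != topology.n_atoms:
        raise ValueError(
            f"trajectory has {u.trajectory.n_atoms} atoms, topology "
            f"{topology.n_atoms}")
    coords, times = [], []
    for ts in u.trajectory:
        coords.append(ts.positions.astype(float).copy())
        times.append(float(ts.time))
    series = FrameSeries(topology, np.array(coords), np.array(times))
    return series.window(window)


def write_multimodel_pdb(series: FrameSeries, path):
    """Write frames as a multi-model PDB (text trajectory)."""
    s = series.topology.copy()
    with open(path, "w") as fh:
        for i in range(series.n_frames):
            s.coords = series.coords[i]
            fh.write(f"MODEL     {i + 1:4d}\n")
            fh.write(_pdb_block(s))
            fh.write("ENDMDL\n")
        fh.write("END\n")
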