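"""Molecular hydrophobicity potential (MHP) evaluation.

The MHP at a point j is the superposition of attenuated atomic
contributions  sum_i f_i * exp(-r_ij / 2)  over protein heavy atoms
within a hard cutoff r_cut = 9 A, where f_i is the atom's octanol-water
logP constant.  For multimeric pores the sum splits into a *self* part
(atoms of the subunit that owns the surface point) and an *induced*
part (atoms of all other subunits); their sum is the total by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["MHPParams", "MHPValue", "MHPField",
           "mhp_at_point", "mhp_decomposed"]


@dataclass(frozen=True)
class MHPParams:
    """Kernel parameters: exp(-r/decay_length) attenuation, hard cutoff."""
    decay_length: float = 2.0   # A
    r_cut: float = 9.0          # A; contributions are identically 0 beyond

    def __post_init__(self):
        if self.r_cut <= 0 or self.decay_length <= 0:
            raise ValueError("decay_length and r_cut must be positive")


@dataclass(frozen=True)
class MHPValue:
    """Decomposed MHP at one point, octanol-water logP units."""
    total: float
    self_part: float
    induced_part: float


class MHPField:
    """Evaluator bound to one structure (KD-tree reused across points).

    Only protein heavy atoms contribute; waters, ions and other
    heteroatoms are excluded.  Raises if any contributing atom lacks a
    hydrophobicity constant.
    """

    def __init__(self, structure, params: MHPParams = MHPParams()):
        self.params = params
        self.structure = structure
        mask = structure.is_protein & (structure.element != "H")
        self._idx = np.flatnonzero(mask)
        self._coords = structure.coords[self._idx]
        self._f = structure.hydro_const[self._idx]
        self._subunit = structure.subunit_index[self._idx]
        self._tree = cKDTree(self._coords) if len(self._idx) else None

    def _contributions(self, point):
        if self._tree is None:
            return np.empty(0, dtype=int), np.empty(0)
        near = self._tree.query_ball_point(np.asarray(point, dtype=float),
                                           self.params.r_cut)
        near = np.asarray(near, dtype=int)
        if len(near) == 0:
            return near, np.empty(0)
        f = self._f[near]
        if np.isnan(f).any():
            bad = self._idx[near[np.isnan(f)]]
            names = {f"{self.structure.res_name[i]}:"
                     f"{self.structure.atom_name[i]}" for i in bad}
            raise ValueError("atoms without hydrophobicity constants in "
                             "range: " + ", ".join(sorted(names)))
        r = np.linalg.norm(self._coords[near]
                           - np.asarray(point, dtype=float), axis=1)
        inside = r < self.params.r_cut
        return near[inside], f[inside] * np.exp(
            -r[inside] / self.params.decay_length)

    def at_point(self, point) -> float:
        """Total MHP at one point (logP units)."""
        _, contrib = self._contributions(point)
        return float(contrib.sum())

    def decomposed(self, point, owner_subunit: int) -> MHPValue:
        """Self/induced/total decomposition against ``owner_subunit``."""
        if not 0 <= owner_subunit < max(self.structure.n_subunits, 1):
            raise IndexError(f"owner subunit {owner_subunit} out of range")
        near, contrib = self._contributions(point)
        own = self._subunit[near] == owner_subunit
        self_part = float(contrib[own].sum())
        induced = float(contrib[~own].sum())
        return MHPValue(self_part + induced, self_part, induced)

    def at_points(self, points) -> np.ndarray:
        points = np.atleast_2d(points)
        return np.array([self.at_point(p) for p in points])


def mhp_at_point(point, structure, params: MHPParams = MHPParams()) -> float:
    return MHPField(structure, params).at_point(point)


def mhp_decomposed(point, structure, owner_subunit: int,
                   params: MHPParams = MHPParams()) -> MHPValue:
    return MHPField(structure, params).decomposed(point, owner_subunit)
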