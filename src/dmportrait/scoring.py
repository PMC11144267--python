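"""Per-residue 3D-1D environment-profile scoring and cross-state
correlation.

Each residue is assigned an environment class from three features
computed in the full (tetrameric) assembly: the buried side-chain area
(reference side-chain area in an extended Gly-X-Gly tripeptide minus
the solvent-accessible side-chain area here), the fraction of that
buried area covered by polar atoms, and the secondary structure
(helix/sheet/other).  Thresholds follow the classic six-class scheme
(exposed E; partial P1/P2; buried B1/B2/B3), crossed with secondary
structure into 18 classes.  The 3D-1D score is a pure table lookup
score(amino acid, class); higher values mean a more favourable
environment.  Profiles from different states or channels are compared
by Pearson correlation along a fixed residue alignment.

Solvent-accessible areas use a 1.4 A probe (Shrake-Rupley via biotite);
explicit waters are excluded from the environment.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field

import numpy as np

from .structure import Structure, BACKBONE_NAMES
from .structure import _data_json   # shared versioned-data loader

__all__ = ["ResidueEnvironment", "ScoreProfile", "AlignmentMap",
           "EnvironmentCalculator", "residue_environment",
           "score_profile", "profile_correlation", "correlation_matrix",
           "reference_sidechain_area"]


def _to_biotite(s: Structure):
    import biotite.structure as struc
    arr = struc.AtomArray(s.n_atoms)
    arr.coord = np.asarray(s.coords, dtype=np.float32)
    arr.chain_id = s.chain_id.astype("U4")
    arr.res_id = s.res_id
    arr.res_name = s.res_name.astype("U3")
    arr.atom_name = s.atom_name.astype("U6")
    arr.element = s.element.astype("U2")
    arr.hetero = ~s.is_protein
    return arr


def _sasa(s: Structure, point_number: int = 960) -> np.ndarray:
    import biotite.structure as struc
    arr = _to_biotite(s)
    radii = np.asarray(s.vdw_radius, dtype=np.float32)
    if np.isnan(radii).any():
        raise ValueError("VdW radii not assigned")
    out = struc.sasa(arr, probe_radius=1.4, vdw_radii=radii,
                     point_number=point_number)
    return np.nan_to_num(np.asarray(out, dtype=float))


@functools.lru_cache(maxsize=None)
def reference_sidechain_area(res_name: str) -> float:
    """Side-chain SASA (A^2) of X in an extended Gly-X-Gly tripeptide."""
    from .fixtures import make_helix, EXTENDED_DIHEDRALS
    tri = make_helix(["GLY", res_name, "GLY"], EXTENDED_DIHEDRALS)
    areas = _sasa(tri)
    mask = _sidechain_mask(tri, np.flatnonzero(tri.res_id == 2))
    return float(areas[mask].sum())


def _sidechain_mask(s: Structure, res_idx) -> np.ndarray:
    """Side-chain atom indices; Gly contributes its CA."""
    names = s.atom_name[res_idx]
    sc = ~np.isin(names, list(BACKBONE_NAMES))
    if not sc.any():
        sc = names == "CA"
    return np.asarray(res_idx)[sc]


@dataclass(frozen=True)
class ResidueEnvironment:
    """Computed environment features and the resulting class label."""
    chain_id: str
    residue_number: int
    residue_name: str
    buried_area: float          # A^2
    polar_fraction: float       # [0, 1]
    secondary_structure: str    # helix / sheet / other
    env_class: str              # e.g. "B1-helix"


@dataclass
class ScoreProfile:
    """3D-1D scores over a residue window of one state.

    Missing residues are absent from ``residue_numbers`` (never
    zero-filled).  ``metadata`` records the score table identity.
    """
    residue_numbers: np.ndarray
    scores: np.ndarray
    state: str = ""
    channel: str = ""
    environments: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return dict(zip((int(r) for r in self.residue_numbers),
                        (float(s) for s in self.scores)))

    def to_table(self):
        import pandas as pd
        return pd.DataFrame({"residue": self.residue_numbers,
                             "score": self.scores,
                             "state": self.state, "channel": self.channel})


class EnvironmentCalculator:
    """Environment classes for many residues of one structure.

    Computes the full-assembly per-atom SASA once; the polar-coverage
    term re-runs SASA on a local neighbourhood with polar (N, O) atoms
    of the surroundings removed, per residue.  Explicit waters and ions
    are excluded throughout.
    """

    def __init__(self, structure: Structure, point_number: int = 960):
        self.full = structure
        self.s = structure.protein()
        self.point_number = point_number
        self.areas = _sasa(self.s, point_number)
        self.thresholds = _data_json("bowie_environment_classes.json")
        self._sse_cache: dict[str, dict[int, str]] = {}

    # -- secondary structure ----------------------------------------------

    def _sse(self, chain: str) -> dict[int, str]:
        if chain not in self._sse_cache:
            import biotite.structure as struc
            arr = _to_biotite(self.s)
            arr = arr[arr.chain_id == chain]
            sse = struc.annotate_sse(arr)
            res_ids = sorted(set(int(r) for r in arr.res_id))
            mapping = {"a": "helix", "b": "sheet", "c": "other"}
            self._sse_cache[chain] = {
                rid: mapping.get(str(code), "other")
                for rid, code in zip(res_ids, sse)}
        return self._sse_cache[chain]

    # -- per-residue features ---------------------------------------------

    def _polar_covered(self, res_idx, sc_idx) -> float:
        """Side-chain area uncovered when surrounding polar atoms are
        removed, minus the actual exposed area (A^2 gained)."""
        s = self.s
        center = s.coords[sc_idx].mean(axis=0)
        near = np.linalg.norm(s.coords - center, axis=1) < 12.0
        near[sc_idx] = True
        polar = np.isin(s.element, ["N", "O"])
        polar[res_idx] = False          # keep the residue itself intact
        keep = near & ~polar
        sub = s.select(keep)
        areas = _sasa(sub, self.point_number)
        # locate the side chain inside the subset
        old_to_new = np.cumsum(keep) - 1
        a_nopolar = float(areas[old_to_new[sc_idx]].sum())
        a_exposed = float(self.areas[sc_idx].sum())
        return max(a_nopolar - a_exposed, 0.0)

    def environment(self, chain_id: str, residue_number: int) \
            -> ResidueEnvironment:
        s = self.s
        res_idx = s.residue_atoms(chain_id, residue_number)
        res_name = str(s.res_name[res_idx[0]])
        sc_idx = _sidechain_mask(s, res_idx)
        a_ref = reference_sidechain_area(res_name)
        a_exposed = float(self.areas[sc_idx].sum())
        buried = max(a_ref - a_exposed, 0.0)
        if buried > 1e-6:
            f = min(self._polar_covered(res_idx, sc_idx) / buried, 1.0)
        else:
            f = 0.0
        ss = self._sse(chain_id).get(int(residue_number), "other")
        th = self.thresholds
        if buried < th["buried_area"]["exposed_max"]:
            env = "E"
        elif buried < th["buried_area"]["partial_max"]:
            env = "P1" if f < th["polar_fraction"]["partial_split"] \
                else "P2"
        elif f < th["polar_fraction"]["buried_split_1"]:
            env = "B1"
        elif f < th["polar_fraction"]["buried_split_2"]:
            env = "B2"
        else:
            env = "B3"
        return ResidueEnvironment(chain_id, int(residue_number), res_name,
                                  buried, f, ss, f"{env}-{ss}")


def residue_environment(structure: Structure, chain_id: str,
                        residue_number: int) -> ResidueEnvironment:
    """Environment class of one residue in the full assembly."""
    return EnvironmentCalculator(structure).environment(chain_id,
                                                        residue_number)


@functools.lru_cache(maxsize=1)
def _score_table() -> tuple[dict, dict]:
    data = _data_json("score3d1d_synthetic.json")
    return data["scores"], data["meta"]


def lookup_score(res_name: str, env_class: str) -> float:
    scores, _ = _score_table()
    try:
        return scores[f"{res_name}:{env_class}"]
    except KeyError:
        raise KeyError(f"no score for {res_name} in class {env_class}")


def score_profile(structure: Structure, residues, chains=None,
                  state: str = "", channel: str = "",
                  calculator: EnvironmentCalculator | None = None) \
        -> ScoreProfile:
    """Per-residue 3D-1D scores over ``residues`` (iterable of author
    numbers, or a (first, last) inclusive pair).

    Scores are averaged over ``chains`` (default: all subunits, the
    C4-mean profile).  Residues absent from the structure are omitted.
    """
    if len(residues) == 2 and np.isscalar(residues[0]) \
            and residues[1] >= residues[0] + 2:
        residues = range(int(residues[0]), int(residues[1]) + 1)
    calc = calculator or EnvironmentCalculator(structure)
    chains = list(chains) if chains is not None \
        else structure.protein_chains
    nums, scores, envs = [], [], []
    for rid in residues:
        vals, res_envs = [], []
        for ch in chains:
            try:
                env = calc.environment(ch, rid)
            except KeyError:
                continue
            vals.append(lookup_score(env.residue_name, env.env_class))
            res_envs.append(env)
        if vals:
            nums.append(int(rid))
            scores.append(float(np.mean(vals)))
            envs.append(res_envs)
    _, meta = _score_table()
    return ScoreProfile(np.array(nums), np.array(scores), state, channel,
                        envs, {"score_table": meta.get("name"),
                               "score_table_sha256": meta.get("sha256"),
                               "synthetic_table": meta.get("synthetic",
                                                           False)})


class AlignmentMap:
    """Position-wise residue-number alignment across channels.

    ``columns`` maps a channel label to an equal-length list of author
    residue numbers (injective per column).
    """

    def __init__(self, columns: dict):
        lengths = {len(v) for v in columns.values()}
        if len(lengths) != 1:
            raise ValueError("alignment columns differ in length")
        for label, col in columns.items():
            if len(set(col)) != len(col):
                raise ValueError(f"column {label} is not injective")
        self.columns = {k: list(map(int, v)) for k, v in columns.items()}

    @classmethod
    def from_tsv(cls, path):
        import pandas as pd
        df = pd.read_csv(path, sep="\t")
        return cls({c: df[c].tolist() for c in df.columns})

    def pairing(self, channel_a: str, channel_b: str) -> dict[int, int]:
        return dict(zip(self.columns[channel_a], self.columns[channel_b]))


def profile_correlation(a: ScoreProfile, b: ScoreProfile,
                        alignment: AlignmentMap | None = None) -> float:
    """Pearson R between two profiles along the alignment.

    Without an alignment, residues pair by equal author numbers.
    Positions missing on either side are dropped pairwise; at least 3
    shared positions are required.
    """
    da, db = a.as_dict(), b.as_dict()
    if alignment is None:
        pairs = [(da[r], db[r]) for r in da if r in db]
    else:
        mapping = alignment.pairing(a.channel, b.channel)
        pairs = [(da[r], db[mapping[r]]) for r in da
                 if r in mapping and mapping[r] in db]
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} aligned scored positions")
    x, y = np.array(pairs).T
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a score profile")
    from scipy.stats import pearsonr
    return float(pearsonr(x, y).statistic)


def correlation_matrix(profiles, alignment: AlignmentMap | None = None):
    """Symmetric matrix of pairwise profile correlations (unit diagonal).

    Returns (labels, matrix)."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    labels = [f"{p.channel}:{p.state}" if p.channel or p.state else str(i)
              for i, p in enumerate(profiles)]
    n = len(profiles)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = profile_correlation(profiles[i], profiles[j], alignment)
            mat[i, j] = mat[j, i] = r
    return labels, mat
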