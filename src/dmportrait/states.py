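"""Pore-state classification: pi-bulge detection and the state call.

Backbone hydrogen bonds are detected with the DSSP electrostatic
criterion (amide H rebuilt from the preceding carbonyl when absent,
E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) kcal/mol, bonded
when E < -0.5).  A pi-bulge is called when at least two consecutive
residues accept i -> i+5 bonds inside an otherwise helical stretch.

The state call combines five evidence fields -- S6 conformation, gate
radius, hydration/conduction (unknown for static input), gate
hydrophobicity and packing/contact summaries -- through a fixed rule
table: alpha-helical S6 gives alpha_closed (intermediate when the gate
is wide, the "alpha-open"-like transitional case); a pi-bulge with a
wide, hydrated or conducting gate gives pi_open; a pi-bulge with a
narrow, dry gate gives pi_closed; everything else is intermediate.
Gate-width brackets: wide >= 2.0 A, narrow <= 1.5 A (heuristic brackets
around reported open 2.8-2.9 A vs closed 0.5-1.3 A gates).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["HBond", "HelixConformation", "StateEvidence", "StateCall",
           "backbone_hbonds", "detect_pi_bulge", "call_state",
           "rule_table", "WIDE_GATE", "NARROW_GATE"]

WIDE_GATE = 2.0     # A
NARROW_GATE = 1.5   # A
HB_ENERGY_CUTOFF = -0.5   # kcal/mol


@dataclass(frozen=True)
class HBond:
    acceptor: int     # residue number providing C=O
    donor: int        # residue number providing N-H
    energy: float     # kcal/mol


@dataclass
class HelixConformation:
    residue_range: tuple
    bulge: tuple | None       # residue interval classified pi, or None
    n_i4: int
    n_i5: int
    hbonds: list

    @property
    def label(self) -> str:
        return "pi-bulge" if self.bulge is not None else "alpha"


def _backbone(structure, chain_id, residue_range):
    lo, hi = residue_range
    res = {}
    missing = []
    for rid in range(lo, hi + 1):
        try:
            idx = structure.residue_atoms(chain_id, rid)
        except KeyError:
            missing.append(rid)
            continue
        entry = {}
        for nm in ("N", "CA", "C", "O"):
            sel = idx[structure.atom_name[idx] == nm]
            if len(sel):
                entry[nm] = structure.coords[int(sel[0])]
        if not {"N", "C", "O"} <= set(entry):
            missing.append(rid)
            continue
        entry["name"] = str(structure.res_name[idx[0]])
        res[rid] = entry
    if missing:
        raise ValueError(f"missing backbone atoms for residues {missing} "
                         f"in chain {chain_id}")
    return res


def backbone_hbonds(structure, chain_id, residue_range,
                    energy_cutoff: float = HB_ENERGY_CUTOFF):
    """DSSP-criterion backbone H-bonds within a residue range.

    The amide hydrogen of residue j is placed 1.0 A from N along the
    C(j-1)=O(j-1) bond direction; residues without a predecessor in the
    range (and prolines) act as acceptors only.
    """
    res = _backbone(structure, chain_id, residue_range)
    bonds = []
    q = 0.084 * 332.0
    for j, rj in res.items():
        if rj["name"] == "PRO" or (j - 1) not in res:
            continue
        prev = res[j - 1]
        co = prev["C"] - prev["O"]
        h = rj["N"] + co / np.linalg.norm(co)
        for i, ri in res.items():
            if j - i < 2:     # local pairs carry no helix information
                continue
            r_on = np.linalg.norm(ri["O"] - rj["N"])
            r_ch = np.linalg.norm(ri["C"] - h)
            r_oh = np.linalg.norm(ri["O"] - h)
            r_cn = np.linalg.norm(ri["C"] - rj["N"])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue      # clashing geometry, not an H-bond
            e = q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if e < energy_cutoff:
                bonds.append(HBond(i, j, float(e)))
    return bonds


def detect_pi_bulge(structure, chain_id, residue_range,
                    min_run: int = 2) -> HelixConformation:
    """Detect a pi-helical segment inside a pore-lining helix.

    A bulge is reported when >= ``min_run`` consecutive residues i
    accept an i -> i+5 backbone H-bond; the reported interval spans the
    first acceptor to the last donor.
    """
    bonds = backbone_hbonds(structure, chain_id, residue_range)
    i4 = sorted(b.acceptor for b in bonds if b.donor - b.acceptor == 4)
    i5 = sorted(b.acceptor for b in bonds if b.donor - b.acceptor == 5)
    bulge = None
    run = []
    for a in i5:
        if run and a == run[-1] + 1:
            run.append(a)
        else:
            run = [a]
        if len(run) >= min_run:
            bulge = (run[0], run[-1] + 5)
    return HelixConformation(tuple(residue_range), bulge, len(i4),
                             len(i5), bonds)


@dataclass
class StateEvidence:
    """Per-criterion evidence record for the state call.

    ``hydrated``/``conducting`` may be None for static-only input;
    the descriptive fields (gate hydrophobicity, packing, contact
    complementarity) are carried into the call record.
    """
    s6_conformation: str              # "alpha" | "pi"
    r_gate: float                     # A
    hydrated: bool | None = None
    conducting: bool | None = None
    gate_hydrophobic: bool | None = None
    packing_favorable: bool | None = None
    contacts_complementary: bool | None = None


@dataclass
class StateCall:
    label: str          # alpha_closed | pi_closed | pi_open | intermediate
    confidence: str     # "high" | "low"
    evidence: StateEvidence

    def as_dict(self) -> dict:
        return {"label": self.label, "confidence": self.confidence,
                "evidence": asdict(self.evidence)}


def call_state(evidence: StateEvidence) -> StateCall:
    """Deterministic state label from the evidence record."""
    if evidence.s6_conformation not in ("alpha", "pi"):
        raise ValueError("s6_conformation must be 'alpha' or 'pi'")
    r = float(evidence.r_gate)
    if not np.isfinite(r) or r < 0:
        raise ValueError("r_gate must be a finite non-negative radius")
    wet = evidence.hydrated
    cond = evidence.conducting

    if evidence.s6_conformation == "alpha":
        if r >= WIDE_GATE:
            return StateCall("intermediate", "high", evidence)
        return StateCall("alpha_closed", "high", evidence)

    if r >= WIDE_GATE:
        if cond or wet:
            return StateCall("pi_open", "high", evidence)
        if cond is False and wet is False:
            # wide but demonstrably dry: transitional
            return StateCall("intermediate", "high", evidence)
        return StateCall("pi_open", "low", evidence)
    if r <= NARROW_GATE:
        if cond or wet:
            return StateCall("intermediate", "low", evidence)
        conf = "high" if wet is False else "low"
        return StateCall("pi_closed", conf, evidence)
    return StateCall("intermediate", "high", evidence)


def rule_table():
    """Enumerate the discrete rule domain -> labels (for docs/tests)."""
    rows = []
    for conf in ("alpha", "pi"):
        for r, rclass in ((1.0, "narrow"), (1.75, "borderline"),
                          (2.5, "wide")):
            for wet in (True, False, None):
                for cond in (True, False, None):
                    call = call_state(StateEvidence(conf, r, wet, cond))
                    rows.append({"s6": conf, "gate": rclass,
                                 "hydrated": wet, "conducting": cond,
                                 "label": call.label,
                                 "confidence": call.confidence})
    return rows
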