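"""Generate the synthetic 3D-1D residue/environment score table.

The published 3D-1D profile score table is derived from a database of
well-packed reference structures; that table is not redistributable
here, so the package ships a SYNTHETIC stand-in built from a simple,
fully documented compatibility model: a residue scores high when its
side-chain polarity matches the polarity of its environment class, with
the weight of the match growing with burial, plus a small secondary-
structure propensity term.  Scores land in roughly [-1, 1], higher =
more favourable environment, preserving the sign conventions and the
correlation machinery downstream.  Absolute values are NOT the
published ones; the table name and checksum travel in profile metadata.

Usage:  python scripts/make_score_table.py
Writes: src/dmportrait/data/score3d1d_synthetic.json
"""

import hashlib
import json
from pathlib import Path

DATA = Path(__file__).resolve().parents[1] / "src" / "dmportrait" / "data"

BACKBONE = {"N", "CA", "C", "O", "OXT"}

# environment class -> (burial level, environment polarity)
ENV = {
    "E":  (0.10, 0.90),   # exposed: mostly water
    "P1": (0.55, 0.30),   # partially buried, apolar contacts
    "P2": (0.55, 0.75),   # partially buried, polar contacts
    "B1": (0.95, 0.15),   # buried, apolar
    "B2": (0.95, 0.50),
    "B3": (0.95, 0.80),   # buried, polar
}

HELIX_FORMERS = {"ALA", "LEU", "MET", "GLU", "GLN", "LYS", "ARG"}
SHEET_FORMERS = {"VAL", "ILE", "PHE", "TYR", "TRP", "THR"}
BREAKERS = {"GLY", "PRO"}


def side_chain_logp(residues):
    out = {}
    for res, atoms in residues.items():
        out[res] = sum(v for k, v in atoms.items() if k not in BACKBONE)
    return out


def ss_term(res, ss):
    if res in BREAKERS:
        return 0.1 if ss == "other" else -0.2
    if ss == "helix" and res in HELIX_FORMERS:
        return 0.15
    if ss == "sheet" and res in SHEET_FORMERS:
        return 0.15
    return 0.0


def main():
    wc = json.loads((DATA / "wildman_crippen_residue_logp.json")
                    .read_text())
    h = side_chain_logp(wc["residues"])
    hmax = max(abs(v) for v in h.values())
    scores = {}
    for res in sorted(h):
        polarity = (1.0 - h[res] / hmax) / 2.0        # 0 apolar .. 1 polar
        for env, (burial, env_pol) in ENV.items():
            match = 1.0 - 2.0 * abs(polarity - env_pol)
            base = match * (0.3 + 0.7 * burial)
            for ss in ("helix", "sheet", "other"):
                scores[f"{res}:{env}-{ss}"] = round(
                    0.8 * base + ss_term(res, ss), 3)
    payload = {"scores": scores}
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()
    out = {
        "meta": {
            "name": "score3d1d-synthetic-v1",
            "synthetic": True,
            "note": "synthetic stand-in for a 3D-1D profile score table; "
                    "see module docstring of the generator script",
            "sha256": digest,
        },
        **payload,
    }
    dest = DATA / "score3d1d_synthetic.json"
    dest.write_text(json.dumps(out, indent=1, sort_keys=True) + "\n")
    print(f"wrote {dest} ({len(scores)} entries)")


if __name__ == "__main__":
    main()
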