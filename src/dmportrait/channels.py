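"""Shipped channel definitions for TRPV pore analysis.

Residue numbers are author numbering of the deposited structures (rat
TRPV1, mouse TRPV3, human TRPV6).  The S6 window of TRPV3 sits at a
constant -5 offset from TRPV1 and TRPV6 at -104; near the selectivity
filter TRPV6 carries a one-residue shift (T539 pairs with I642), so the
axis list is given explicitly per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .scoring import AlignmentMap

__all__ = ["ChannelConfig", "CHANNELS", "get_channel_config",
           "S6_ALIGNMENT", "gate_z_window"]


@dataclass(frozen=True)
class ChannelConfig:
    name: str
    axis_residues: tuple          # define the pore axis (Ca quadruplets)
    s6_range: tuple               # pore-lining helix span
    helix_map_range: tuple        # S6 fragment mapped on its own cylinder
    score_window: tuple           # 3D-1D profile window
    filter_gate_residues: tuple   # axial region between filter and gate
    gate_residues_pi: tuple       # constriction when S6 has the pi-bulge
    gate_residues_alpha: tuple    # constriction when S6 is alpha-helical
    neighbor_contact_range: tuple  # residues tested by the <7 A criterion


CHANNELS = {
    "TRPV1": ChannelConfig(
        name="TRPV1",
        axis_residues=(642, 643, 644, 645, 671, 675, 676, 679, 680,
                       683, 686),
        s6_range=(654, 692),
        helix_map_range=(670, 682),
        score_window=(670, 687),
        filter_gate_residues=(643, 682),      # G643 .. M682
        gate_residues_pi=(679,),              # I679
        gate_residues_alpha=(678, 682),       # L678, M682
        neighbor_contact_range=(654, 692),
    ),
    "TRPV3": ChannelConfig(
        name="TRPV3",
        axis_residues=(637, 638, 639, 640, 666, 670, 671, 674, 675,
                       678, 681),
        s6_range=(649, 687),
        helix_map_range=(665, 677),
        score_window=(665, 682),
        filter_gate_residues=(638, 677),      # G638 .. M677
        gate_residues_pi=(674,),              # I674
        gate_residues_alpha=(673, 677),       # L673, M677
        neighbor_contact_range=(649, 687),
    ),
    "TRPV6": ChannelConfig(
        name="TRPV6",
        axis_residues=(539, 540, 541, 542, 567, 571, 572, 575, 576,
                       579, 582),
        s6_range=(550, 588),
        helix_map_range=(566, 578),
        score_window=(566, 583),
        filter_gate_residues=(540, 578),      # I540 .. M578
        gate_residues_pi=(575,),              # I575
        gate_residues_alpha=(574, 578),       # L574, M578
        neighbor_contact_range=(550, 588),
    ),
}

# position-wise S6 alignment used for cross-channel profile correlations
S6_ALIGNMENT = AlignmentMap({
    "TRPV1": list(range(670, 688)),
    "TRPV3": list(range(665, 683)),
    "TRPV6": list(range(566, 584)),
})


def get_channel_config(name: str) -> ChannelConfig:
    try:
        return CHANNELS[name.upper()]
    except KeyError:
        raise KeyError(f"unknown channel {name!r}; shipped configs: "
                       + ", ".join(sorted(CHANNELS)))


def gate_z_window(structure, config: ChannelConfig,
                  conformation: str = "pi", margin: float = 4.0) -> tuple:
    """Axial gate region: Ca z of the gate residues +/- margin."""
    rids = config.gate_residues_pi if conformation == "pi" \
        else config.gate_residues_alpha
    zs = []
    for rid in rids:
        m = structure.is_protein & (structure.res_id == rid) \
            & (structure.atom_name == "CA")
        if not m.any():
            raise KeyError(f"gate residue {rid} not in structure")
        zs.append(float(structure.coords[m, 2].mean()))
    return (min(zs) - margin, max(zs) + margin)
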