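"""T4 lysozyme L99A cavity definitions and published CG-O₂ benchmark inputs.

T4 lysozyme L99A (PDB 181L) is the standard benchmark protein for
gas-cavity binding: the L99A mutation engineers hydrophobic cavities that
bind small apolar ligands.  Five probe regions are used here — two
hydrophilic cavities (1, 2), two hydrophobic cavities (3, 4) and a random
space inside the protein (5) — each defined by a residue list whose center
of geometry is the cavity center.

``REFERENCE_BINDING`` carries the published aggregate binding statistics
of a coarse-grained O₂ bead in this system (2 beads, 29 replicas, 2 μs
production each, 20 ps frames, 6 Å cutoff, 60 ps merge gap): total bound
time t (ns) and event count n per cavity.  These are *inputs* for the
arithmetic demos — everything derived from them (t̄, occupancy, ΔF_bind)
is recomputed by this package.
"""

from __future__ import annotations

from .binding import CavitySpec

__all__ = [
    "CAVITIES",
    "REFERENCE_BINDING",
    "REFERENCE_CONDITIONS",
    "RHO_WATER_KG_M3",
]

CAVITIES = (
    CavitySpec(
        name="cavity1",
        residues=((28, "GLY"), (29, "ILE"), (63, "ALA"), (70, "ASP")),
        klass="hydrophilic",
    ),
    CavitySpec(
        name="cavity2",
        residues=((101, "ASN"), (102, "MET"), (105, "GLN"), (138, "TRP"),
                  (149, "VAL")),
        klass="hydrophilic",
    ),
    CavitySpec(
        name="cavity3",
        residues=((126, "TRP"), (130, "ALA"), (153, "PHE"), (154, "ARG")),
        klass="hydrophobic",
    ),
    CavitySpec(
        name="cavity4",
        residues=((84, "LEU"), (87, "VAL"), (88, "TYR"), (91, "LEU"),
                  (99, "ALA"), (102, "MET"), (111, "VAL"), (118, "LEU")),
        klass="hydrophobic",
    ),
    CavitySpec(
        name="cavity5",
        residues=((50, "ILE"), (51, "GLY"), (52, "ARG"), (53, "ASN"),
                  (54, "THR"), (55, "ASN"), (56, "GLY"), (57, "VAL"),
                  (58, "ILE"), (59, "THR")),
        klass="random",
    ),
)

#: Published aggregate statistics: cavity -> (total bound time t in ns,
#: number of binding events n).
REFERENCE_BINDING = {
    "cavity1": (74.56, 283),
    "cavity2": (103.26, 830),
    "cavity3": (595.36, 1098),
    "cavity4": (1710.50, 2738),
    "cavity5": (67.44, 427),
}

#: Simulation conditions the reference statistics were collected under.
REFERENCE_CONDITIONS = {
    "n_beads": 2,
    "n_replicas": 29,
    "production_ns": 2000.0,
    "frame_interval_ps": 20.0,
    "cutoff": 6.0,
    "merge_gap_ps": 60.0,
    "temperature": 310.0,
}

#: Published O₂ mass density in the water phase of the benchmark box, kg/m³.
RHO_WATER_KG_M3 = 0.283


def cavity_class(name: str) -> str:
    for cav in CAVITIES:
        if cav.name == name:
            return cav.klass
    raise KeyError(name)
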