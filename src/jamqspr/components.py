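"""Reference jam components: SMILES and published descriptor values.

The five descriptor-bearing components of blueberry jam are water, citric
acid, glucose, sucrose and the anthocyanin chromophore.  The anthocyanin is
represented by the flavylium (2-phenylchromenylium) cation C15H11O+, the
aromatic core common to all anthocyanidins; its constitutional values (MW
207.26, 11 H, 15 C) match the published descriptor column.  A saturated
bicyclic SMILES sometimes printed for "anthocyanin" (kept here as
``NONCANONICAL_ANTHOCYANIN_SMILES``, a parse-only curiosity) encodes
C15H26O+ and is inconsistent with those values.
"""

from __future__ import annotations

import pandas as pd

from .descriptors import DESCRIPTOR_NAMES

__all__ = [
    "COMPONENT_SMILES",
    "COMPONENT_ORDER",
    "NONCANONICAL_ANTHOCYANIN_SMILES",
    "reference_descriptor_table",
]

#: Component order used throughout (mixture rule, reports).
COMPONENT_ORDER = ("water", "citric_acid", "glucose", "sucrose", "anthocyanin")

COMPONENT_SMILES = {
    "water": "O",
    "citric_acid": "OC(=O)CC(O)(CC(O)=O)C(O)=O",
    "glucose": "OC[C@@H](O)[C@@H](O)[C@H](O)[C@@H](O)C=O",
    "sucrose": "OC[C@H]1O[C@H](O[C@]2(CO)O[C@H](CO)[C@@H](O)[C@@H]2O)"
               "[C@H](O)[C@@H](O)[C@@H]1O",
    # flavylium cation, 2-phenylchromenylium
    "anthocyanin": "[o+]1c2ccccc2ccc1-c1ccccc1",
}

#: Saturated bicyclic cation (C15H26O+); parses, but does not describe an
#: anthocyanin chromophore.  Kept for parse-only tests.
NONCANONICAL_ANTHOCYANIN_SMILES = "C1CCC(CC1)C2CCC3CCCCC3[O+]2"

# Published descriptor values for the five components (report order rows).
_REFERENCE = {
    "MW":          (18.020, 192.140, 180.180, 342.340, 207.260),
    "AMW":         (6.007, 9.150, 7.507, 7.608, 7.676),
    "nH":          (2, 8, 12, 22, 11),
    "nC":          (0, 6, 6, 12, 15),
    "nStructures": (1, 1, 1, 1, 1),
    "Pol":         (0, 16, 16, 43, 23),
    "X1Av":        (0.0, 0.264, 0.302, 0.294, 0.297),
    "X1sol":       (0.000, 5.776, 5.540, 10.807, 7.933),
    "XMOD":        (0.000, 38.622, 36.964, 72.190, 48.412),
    "RDCHI":       (0.000, 2.190, 2.154, 3.143, 2.966),
    "P_VSA_p_1":   (0.000, 47.084, 82.398, 164.795, 129.482),
    "nHDon":       (2, 4, 5, 8, 0),
    "SAtot":       (58.196, 301.051, 332.384, 539.621, 259.272),
    "VvdwMG":      (14.767, 87.516, 89.375, 155.050, 114.516),
    "PDI":         (0.478, 0.682, 0.631, 0.686, 1.046),
}


def reference_descriptor_table() -> pd.DataFrame:
    """Published 5-component descriptor table (components x descriptors).

    These are the calibration anchors for the five calibrated descriptors
    and the golden values the exact descriptors are verified against.
    """
    data = {d: _REFERENCE[d] for d in DESCRIPTOR_NAMES}
    return pd.DataFrame(data, index=list(COMPONENT_ORDER))
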