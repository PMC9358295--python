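"""Physical constants and the species bookkeeping shared by all modules.

The model tracks seven solutes in every compartment, in a fixed order that is
used for all concentration vectors throughout the package.
"""
from __future__ import annotations

import enum

import numpy as np

#: Universal gas constant (J / mol / K).
R_GAS = 8.314462618

#: Faraday constant (C / mol).
FARADAY = 96485.33212


class Species(enum.IntEnum):
    """The seven tracked solutes, indexable into any concentration vector."""

    NA = 0
    K = 1
    CL = 2
    HCO3 = 3
    H = 4
    CO2 = 5
    H2CO3 = 6


#: Valence of each species, in ``Species`` order.
VALENCES = np.array([+1, +1, -1, -1, +1, 0, 0], dtype=float)

#: Number of tracked solutes.
N_SPECIES = len(Species)

#: Display names in ``Species`` order.
SPECIES_NAMES = ("Na+", "K+", "Cl-", "HCO3-", "H+", "CO2", "H2CO3")
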