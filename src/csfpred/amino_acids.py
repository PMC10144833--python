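"""Amino-acid constants: alphabet, masses, property scales and residue-distance matrices.

All scales are dictionaries over the 20 standard one-letter codes in the
alphabetical order ``ACDEFGHIKLMNPQRSTVWY``. Scales whose canonical literature
values are not reproducible here live in :mod:`csfpred.synthetic_scales`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils.ProtParamData import Flex as _VIHINEN_FLEX
from Bio.SeqUtils.ProtParamData import ja as _JANIN_ACC

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
NONSTANDARD = set("BJOUXZ")

# Average residue (monomer-in-chain) masses, Da.
RESIDUE_MASS = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155, "F": 147.1766,
    "G": 57.0519, "H": 137.1411, "I": 113.1594, "K": 128.1741, "L": 113.1594,
    "M": 131.1926, "N": 114.1038, "P": 97.1167, "Q": 128.1307, "R": 156.1875,
    "S": 87.0782, "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
WATER_MASS = 18.01524

# Kyte-Doolittle hydropathy.
HYDROPHOBICITY = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4, "H": -3.2,
    "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5,
    "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

# Hopp-Woods hydrophilicity.
HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0, "H": -0.5,
    "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2,
    "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}

# Side-chain mass = residue mass minus the glycine backbone contribution plus H.
SIDE_CHAIN_MASS = {a: RESIDUE_MASS[a] - RESIDUE_MASS["G"] + 1.008 for a in ALPHABET}

# Grantham (1974) amino-acid properties: composition c, polarity p, volume v.
GRANTHAM_COMPOSITION = {
    "A": 0.0, "C": 2.75, "D": 1.38, "E": 0.92, "F": 0.0, "G": 0.74, "H": 0.58,
    "I": 0.0, "K": 0.33, "L": 0.0, "M": 0.0, "N": 1.33, "P": 0.39, "Q": 0.89,
    "R": 0.65, "S": 1.42, "T": 0.71, "V": 0.0, "W": 0.13, "Y": 0.20,
}
POLARITY = {
    "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2, "G": 9.0, "H": 10.4,
    "I": 5.2, "K": 11.3, "L": 4.9, "M": 5.7, "N": 11.6, "P": 8.0, "Q": 10.5,
    "R": 10.5, "S": 9.2, "T": 8.6, "V": 5.9, "W": 5.4, "Y": 6.2,
}
GRANTHAM_VOLUME = {
    "A": 31.0, "C": 55.0, "D": 54.0, "E": 83.0, "F": 132.0, "G": 3.0, "H": 96.0,
    "I": 111.0, "K": 119.0, "L": 111.0, "M": 105.0, "N": 56.0, "P": 32.5,
    "Q": 85.0, "R": 124.0, "S": 32.0, "T": 61.0, "V": 84.0, "W": 170.0,
    "Y": 136.0,
}

# Charton-Charton polarizability.
POLARIZABILITY = {
    "A": 0.046, "C": 0.128, "D": 0.105, "E": 0.151, "F": 0.290, "G": 0.000,
    "H": 0.230, "I": 0.186, "K": 0.219, "L": 0.186, "M": 0.221, "N": 0.134,
    "P": 0.131, "Q": 0.180, "R": 0.291, "S": 0.062, "T": 0.108, "V": 0.140,
    "W": 0.409, "Y": 0.298,
}

# Normalized van der Waals volume (Fauchere et al.).
VDW_VOLUME = {
    "A": 1.00, "C": 2.43, "D": 2.78, "E": 3.78, "F": 5.89, "G": 0.00,
    "H": 4.66, "I": 4.00, "K": 4.77, "L": 4.00, "M": 4.43, "N": 2.95,
    "P": 2.72, "Q": 3.95, "R": 6.13, "S": 1.60, "T": 2.60, "V": 3.00,
    "W": 8.08, "Y": 6.47,
}

# Formal side-chain charge at physiological pH.
CHARGE = {a: 0.0 for a in ALPHABET}
CHARGE.update({"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0})

# Side-chain hydrogen-bond donor / acceptor counts (polar H's / lone-pair sites).
HBOND_DONORS = {a: 0.0 for a in ALPHABET}
HBOND_DONORS.update({"R": 5, "K": 3, "W": 1, "H": 1, "S": 1, "T": 1, "Y": 1,
                     "N": 2, "Q": 2, "C": 1})
HBOND_ACCEPTORS = {a: 0.0 for a in ALPHABET}
HBOND_ACCEPTORS.update({"D": 2, "E": 2, "N": 1, "Q": 1, "H": 1, "S": 1,
                        "T": 1, "Y": 1, "M": 1})

FLEXIBILITY = dict(_VIHINEN_FLEX)           # Vihinen normalized flexibility
SOLVENT_ACCESSIBILITY = dict(_JANIN_ACC)    # Janin interior-to-surface scale


@dataclass(frozen=True)
class PropertyScale:
    """A named map from the 20 standard amino acids to a real value."""

    name: str
    values: dict

    def __post_init__(self):
        if set(self.values) != set(ALPHABET):
            raise ValueError(f"scale {self.name!r} must cover exactly the 20 standard residues")

    def as_array(self) -> np.ndarray:
        """Values in ``ALPHABET`` order."""
        return np.array([float(self.values[a]) for a in ALPHABET])

    def normalized(self) -> "PropertyScale":
        """Zero-mean, unit-variance variant over the 20 values (idempotent)."""
        v = self.as_array()
        sd = v.std()
        z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        return PropertyScale(self.name, dict(zip(ALPHABET, z)))


def _grantham_matrix() -> np.ndarray:
    """Grantham chemical-distance matrix from his composition/polarity/volume
    properties, D = rho * sqrt(a*dc^2 + b*dp^2 + g*dv^2), scaled to mean 100
    over residue pairs (Leu-Ile comes out ~5, Ser-Arg ~110)."""
    c = np.array([GRANTHAM_COMPOSITION[a] for a in ALPHABET])
    p = np.array([POLARITY[a] for a in ALPHABET])
    v = np.array([GRANTHAM_VOLUME[a] for a in ALPHABET])
    d = np.sqrt(
        1.833 * (c[:, None] - c[None, :]) ** 2
        + 0.1018 * (p[:, None] - p[None, :]) ** 2
        + 0.000399 * (v[:, None] - v[None, :]) ** 2
    )
    off = d[np.triu_indices(20, k=1)]
    return d * (100.0 / off.mean())


def _physchem_distance_matrix() -> np.ndarray:
    """Physicochemical residue distance in the style of Schneider-Wrede.

    Stand-in for the published Schneider-Wrede matrix (not reproducible here):
    Euclidean distance over z-scored hydrophobicity, hydrophilicity and
    side-chain mass, normalized so the largest distance is 1. Diagonal is 0,
    so homopolymer sequence-order coupling terms vanish.
    """
    props = [PropertyScale(n, s).normalized().as_array()
             for n, s in [("h1", HYDROPHOBICITY), ("h2", HYDROPHILICITY),
                          ("m", SIDE_CHAIN_MASS)]]
    sq = sum((p[:, None] - p[None, :]) ** 2 for p in props)
    d = np.sqrt(sq / len(props))
    return d / d.max()


GRANTHAM_MATRIX = _grantham_matrix()
SW_LIKE_MATRIX = _physchem_distance_matrix()

DISTANCE_MATRICES = {"sw_like": SW_LIKE_MATRIX, "grantham": GRANTHAM_MATRIX}
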