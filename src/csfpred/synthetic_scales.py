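"""Synthetic stand-in property scales.

Several 21-dimension physicochemical profile blocks of the default feature
configuration are named after property scales (surface tension, water
solubility, CLogP, and a family of interface/binding-site propensity scales)
whose exact 20-value literature tables are not available here. For those
blocks this module provides SYNTHETIC stand-in scales: deterministic
pseudo-random values drawn once per scale name from a fixed generator. They
give the blocks well-defined, reproducible numerics with the correct layout;
they are NOT the published scales. Users with the real tables can supply them
via the external-feature ingestion path or a custom scale registry.
"""

from __future__ import annotations

import zlib

import numpy as np

from .amino_acids import ALPHABET, PropertyScale

SYNTHETIC_SCALE_NAMES = (
    "surface_tension",
    "water_solubility",
    "clogp",
    "ppi_hotspot_bogan",
    "ppi_propensity_ma",
    "dna_interface_schneider",
    "dna_interface_ahmad",
    "rna_interface_kim",
    "rna_interface_ellis",
    "rna_interface_phipps",
    "ligand_binding_khazanov",
    "ligand_valid_binding_khazanov",
    "ligand_polar_imai",
)


def synthetic_scale(name: str) -> PropertyScale:
    """Deterministic synthetic stand-in scale for ``name`` (seeded by a CRC of
    the name, so the values never change between runs or platforms)."""
    rng = np.random.default_rng(zlib.crc32(name.encode()) & 0x7FFFFFFF)
    values = np.round(rng.normal(size=20), 3)
    return PropertyScale(name, dict(zip(ALPHABET, values)))


SYNTHETIC_SCALES = {name: synthetic_scale(name) for name in SYNTHETIC_SCALE_NAMES}
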