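"""Sequence-derived protein descriptors.

Builds a fixed-length named feature vector per protein from four descriptor
groups: general sequence descriptors (composition, dipeptides, Moreau-Broto /
Moran / Geary autocorrelation, quasi-sequence-order, pseudo- and amphiphilic
pseudo-amino-acid composition, simple scalars), physicochemical property
profiles, and externally supplied domain/motif and structural descriptors.
The shipped default configuration comprises 52 named feature blocks totalling
1610 dimensions. Blocks that cannot be computed for a given sequence (e.g.
the sequence is shorter than a required lag) are flagged missing, never
silently zeroed; downstream preprocessing imputes them.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio.SeqUtils import molecular_weight
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

from .amino_acids import (
    ALPHABET,
    AA_INDEX,
    CHARGE,
    DISTANCE_MATRICES,
    FLEXIBILITY,
    HBOND_ACCEPTORS,
    HBOND_DONORS,
    HYDROPHILICITY,
    HYDROPHOBICITY,
    NONSTANDARD,
    POLARITY,
    POLARIZABILITY,
    RESIDUE_MASS,
    SIDE_CHAIN_MASS,
    SOLVENT_ACCESSIBILITY,
    VDW_VOLUME,
    WATER_MASS,
    PropertyScale,
)
from .synthetic_scales import SYNTHETIC_SCALES

logger = logging.getLogger(__name__)

#: Registry of per-residue property scales available to descriptor blocks.
SCALES: dict[str, PropertyScale] = {
    "hydrophobicity": PropertyScale("hydrophobicity", HYDROPHOBICITY),
    "hydrophilicity": PropertyScale("hydrophilicity", HYDROPHILICITY),
    "side_chain_mass": PropertyScale("side_chain_mass", SIDE_CHAIN_MASS),
    "polarity": PropertyScale("polarity", POLARITY),
    "polarizability": PropertyScale("polarizability", POLARIZABILITY),
    "vdw_volume": PropertyScale("vdw_volume", VDW_VOLUME),
    "charge": PropertyScale("charge", CHARGE),
    "molecular_weight": PropertyScale("molecular_weight", RESIDUE_MASS),
    "flexibility": PropertyScale("flexibility", FLEXIBILITY),
    "solvent_accessibility": PropertyScale("solvent_accessibility", SOLVENT_ACCESSIBILITY),
    "hbond_donors": PropertyScale("hbond_donors", HBOND_DONORS),
    "hbond_acceptors": PropertyScale("hbond_acceptors", HBOND_ACCEPTORS),
}
SCALES.update(SYNTHETIC_SCALES)

DIPEPTIDES = [a + b for a in ALPHABET for b in ALPHABET]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its (sanitized) amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non-standard letters {sorted(bad)}; sanitize first"
            )


def sanitize_sequence(raw: str, policy: str = "strip") -> str:
    """Uppercase ``raw`` and resolve non-standard letters.

    policy="strip" removes B/J/O/U/X/Z (and anything else outside the 20
    standard letters) with a logged warning; policy="reject" raises instead.
    """
    if not raw:
        raise ValueError("empty sequence")
    seq = raw.upper()
    bad = set(seq) - set(ALPHABET)
    if bad:
        if policy == "reject":
            raise ValueError(f"non-standard letters {sorted(bad)} under policy='reject'")
        if policy != "strip":
            raise ValueError(f"unknown policy {policy!r}")
        if not bad <= NONSTANDARD:
            unknown = bad - NONSTANDARD
            raise ValueError(f"letters {sorted(unknown)} are not amino-acid codes")
        logger.warning("stripping non-standard letters %s", sorted(bad))
        seq = "".join(c for c in seq if c in AA_INDEX)
        if not seq:
            raise ValueError("sequence empty after stripping non-standard letters")
    return seq


def encode(seq: str) -> np.ndarray:
    """Integer encoding of a sanitized sequence (positions in ALPHABET)."""
    return np.array([AA_INDEX[c] for c in seq], dtype=np.intp)


# ---------------------------------------------------------------------------
# descriptor primitives
# ---------------------------------------------------------------------------

def aac(seq: str) -> np.ndarray:
    """Amino-acid composition: 20 residue fractions (sums to 1)."""
    idx = encode(seq)
    return np.bincount(idx, minlength=20) / len(idx)


def dpc(seq: str) -> np.ndarray:
    """Dipeptide composition: 400 adjacent-pair fractions (sums to 1).

    Returns an all-NaN vector for single-residue sequences (no pairs).
    """
    if len(seq) < 2:
        return np.full(400, np.nan)
    idx = encode(seq)
    pair = idx[:-1] * 20 + idx[1:]
    return np.bincount(pair, minlength=400) / (len(idx) - 1)


def autocorrelation(seq: str, scales: list[PropertyScale], maxlag: int,
                    kind: str) -> np.ndarray:
    """Property autocorrelation descriptors, one value per (scale, lag).

    kind is one of ``moreau_broto_normalized``, ``moran``, ``geary``. Scales
    are z-scored over the 20 residues before use. Lags with no feasible
    residue pair (lag >= sequence length) are NaN; a property that is constant
    along the sequence yields 0 for Moran/Geary (zero-variance convention).
    """
    if kind not in ("moreau_broto_normalized", "moran", "geary"):
        raise ValueError(f"unknown autocorrelation kind {kind!r}")
    idx = encode(seq)
    n = len(idx)
    out = np.full(len(scales) * maxlag, np.nan)
    for s, scale in enumerate(scales):
        p = scale.normalized().as_array()[idx]
        pbar = p.mean()
        dev = p - pbar
        for d in range(1, maxlag + 1):
            if n - d < 1:
                continue
            k = s * maxlag + (d - 1)
            if kind == "moreau_broto_normalized":
                out[k] = float(p[:-d] @ p[d:]) / (n - d)
            elif kind == "moran":
                denom = float(dev @ dev) / n
                out[k] = 0.0 if denom == 0 else (float(dev[:-d] @ dev[d:]) / (n - d)) / denom
            else:  # geary
                denom = float(dev @ dev) / (n - 1) if n > 1 else 0.0
                num = float(((p[:-d] - p[d:]) ** 2).sum()) / (2 * (n - d))
                out[k] = 0.0 if denom == 0 else num / denom
    return out


def qso(seq: str, maxlag: int = 60, weight: float = 0.1,
        matrices: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Quasi-sequence-order descriptors.

    Per residue-distance matrix: 20 composition-derived terms followed by
    ``maxlag`` sequence-order-coupling terms tau_d = sum_i d(R_i, R_{i+d})^2,
    all sharing the denominator (1 + weight * sum tau). With the default two
    matrices and maxlag 60 the output has 2*(20+60) = 160 dimensions.
    Sequences of length <= maxlag yield an all-NaN block.
    """
    if matrices is None:
        matrices = DISTANCE_MATRICES
    total = sum(20 + maxlag for _ in matrices)
    if len(seq) <= maxlag:
        return np.full(total, np.nan)
    idx = encode(seq)
    f = np.bincount(idx, minlength=20) / len(idx)
    parts = []
    for mat in matrices.values():
        tau = np.array([
            float((mat[idx[:-d], idx[d:]] ** 2).sum()) for d in range(1, maxlag + 1)
        ])
        denom = 1.0 + weight * tau.sum()
        parts.append(np.concatenate([f / denom, weight * tau / denom]))
    return np.concatenate(parts)


def paac(seq: str, lam: int = 130, weight: float = 0.05,
         scales: list[PropertyScale] | None = None) -> np.ndarray:
    """Type-1 pseudo-amino-acid composition, 20 + lam dimensions.

    First 20 entries are composition terms, the last ``lam`` are tiered
    sequence-order factors theta_d averaging the squared property differences
    of residues ``d`` apart; everything shares the common denominator
    (1 + weight * sum theta) so the vector sums to 1. Sequences of length
    <= lam yield an all-NaN block.
    """
    if scales is None:
        scales = [SCALES["hydrophobicity"], SCALES["hydrophilicity"],
                  SCALES["side_chain_mass"]]
    n = len(seq)
    if n <= lam:
        return np.full(20 + lam, np.nan)
    idx = encode(seq)
    props = np.stack([s.normalized().as_array()[idx] for s in scales])
    theta = np.array([
        float(((props[:, d:] - props[:, :-d]) ** 2).mean(axis=0).sum()) / (n - d)
        for d in range(1, lam + 1)
    ])
    f = np.bincount(idx, minlength=20) / n
    denom = 1.0 + weight * theta.sum()
    return np.concatenate([f, weight * theta]) / denom


def apaac(seq: str, lam: int = 30, weight: float = 0.05,
          scales: list[PropertyScale] | None = None) -> np.ndarray:
    """Amphiphilic pseudo-amino-acid composition, 20 + 2*lam dimensions.

    The sequence-order factors are separate hydrophobicity and hydrophilicity
    correlation terms tau at each tier (interleaved h1, h2 per lag).
    """
    if scales is None:
        scales = [SCALES["hydrophobicity"], SCALES["hydrophilicity"]]
    if len(scales) != 2:
        raise ValueError("apaac requires exactly two scales")
    n = len(seq)
    if n <= lam:
        return np.full(20 + 2 * lam, np.nan)
    idx = encode(seq)
    h = np.stack([s.normalized().as_array()[idx] for s in scales])
    tau = np.empty(2 * lam)
    for d in range(1, lam + 1):
        prods = h[:, :-d] * h[:, d:]
        tau[2 * (d - 1)] = prods[0].sum() / (n - d)
        tau[2 * (d - 1) + 1] = prods[1].sum() / (n - d)
    f = np.bincount(idx, minlength=20) / n
    denom = 1.0 + weight * tau.sum()
    return np.concatenate([f, weight * tau]) / denom


def property_profile(seq: str, scale: PropertyScale) -> np.ndarray:
    """21-dimension physicochemical profile for one property scale.

    Entries 1..20 are the residue-type composition weighted by the raw scale
    value of that residue type; entry 21 is the mean scale value over the
    sequence.
    """
    comp = aac(seq)
    v = scale.as_array()
    weighted = comp * v
    return np.concatenate([weighted, [float(weighted.sum())]])


def sequence_mass(seq: str) -> float:
    """Average molecular mass in Da (residues + one water)."""
    return float(molecular_weight(seq, seq_type="protein", monoisotopic=False))


def isoelectric_point(seq: str) -> float:
    """Isoelectric point by bisection on the Henderson-Hasselbalch net charge."""
    return float(IsoelectricPoint(seq).pi())


def total_aa_property(seq: str, scales: list[PropertyScale] | None = None) -> np.ndarray:
    """Sequence sums of the configured property scales (default 3: raw
    hydrophobicity, charge, polarity)."""
    if scales is None:
        scales = [SCALES["hydrophobicity"], SCALES["charge"], SCALES["polarity"]]
    idx = encode(seq)
    return np.array([float(s.as_array()[idx].sum()) for s in scales])


# ---------------------------------------------------------------------------
# block configuration
# ---------------------------------------------------------------------------

GROUPS = ("general", "physicochemical", "domain_motif", "structural")


@dataclass(frozen=True)
class FeatureBlockSpec:
    """One named feature block: its group, dimensionality and parameters."""

    name: str
    group: str
    length: int
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"block {self.name!r}: unknown group {self.group!r}")
        implied = _implied_length(self.kind, self.params)
        if implied is not None and implied != self.length:
            raise ValueError(
                f"block {self.name!r}: declared length {self.length} != "
                f"length {implied} implied by params"
            )

    def columns(self) -> list[str]:
        if self.length == 1:
            return [self.name]
        return [f"{self.name}:{sub}" for sub in _subnames(self)]


def _implied_length(kind: str, params: dict) -> int | None:
    if kind == "aac":
        return 20
    if kind == "dpc":
        return 400
    if kind == "autocorrelation":
        return len(params["scales"]) * int(params["maxlag"])
    if kind == "qso":
        return len(params.get("matrices", list(DISTANCE_MATRICES))) * (20 + int(params["maxlag"]))
    if kind == "paac":
        return 20 + int(params["lam"])
    if kind == "apaac":
        return 20 + 2 * int(params["lam"])
    if kind == "property_profile":
        return 21
    if kind == "total_aa_property":
        return len(params["scales"])
    if kind in ("length", "mass", "isoelectric_point"):
        return 1
    return None  # external blocks: any declared length


def _subnames(spec: FeatureBlockSpec) -> list[str]:
    kind, params = spec.kind, spec.params
    if kind == "aac":
        return list(ALPHABET)
    if kind == "dpc":
        return DIPEPTIDES
    if kind == "autocorrelation":
        return [f"{s}.lag{d:02d}" for s in params["scales"]
                for d in range(1, int(params["maxlag"]) + 1)]
    if kind == "qso":
        names = []
        for m in params.get("matrices", list(DISTANCE_MATRICES)):
            names += [f"{m}.{a}" for a in ALPHABET]
            names += [f"{m}.tau{d:02d}" for d in range(1, int(params["maxlag"]) + 1)]
        return names
    if kind == "paac":
        return list(ALPHABET) + [f"theta{d:03d}" for d in range(1, int(params["lam"]) + 1)]
    if kind == "apaac":
        names = list(ALPHABET)
        for d in range(1, int(params["lam"]) + 1):
            names += [f"h1.lag{d:02d}", f"h2.lag{d:02d}"]
        return names
    if kind == "property_profile":
        return list(ALPHABET) + ["mean"]
    if kind == "total_aa_property":
        return list(params["scales"])
    return [str(i) for i in range(1, spec.length + 1)]


def _resolve_scales(names: list[str]) -> list[PropertyScale]:
    return [SCALES[n] for n in names]


def compute_block(spec: FeatureBlockSpec, seq: str) -> np.ndarray:
    """Compute one block for one sanitized sequence; NaN marks missing."""
    kind, params = spec.kind, spec.params
    if kind == "aac":
        return aac(seq)
    if kind == "dpc":
        return dpc(seq)
    if kind == "autocorrelation":
        return autocorrelation(seq, _resolve_scales(params["scales"]),
                               int(params["maxlag"]), params["variant"])
    if kind == "qso":
        mats = {m: DISTANCE_MATRICES[m] for m in params.get("matrices", list(DISTANCE_MATRICES))}
        return qso(seq, int(params["maxlag"]), float(params.get("weight", 0.1)), mats)
    if kind == "paac":
        return paac(seq, int(params["lam"]), float(params.get("weight", 0.05)))
    if kind == "apaac":
        return apaac(seq, int(params["lam"]), float(params.get("weight", 0.05)))
    if kind == "property_profile":
        return property_profile(seq, SCALES[params["scale"]])
    if kind == "total_aa_property":
        return total_aa_property(seq, _resolve_scales(params["scales"]))
    if kind == "length":
        return np.array([float(len(seq))])
    if kind == "mass":
        return np.array([sequence_mass(seq)])
    if kind == "isoelectric_point":
        return np.array([isoelectric_point(seq)])
    if kind == "external":
        return np.full(spec.length, np.nan)
    raise ValueError(f"unknown block kind {kind!r}")


def load_block_config(path=None) -> list[FeatureBlockSpec]:
    """Load a feature-block configuration from YAML (packaged default if no
    path is given)."""
    if path is None:
        ref = importlib.resources.files("csfpred").joinpath("data/default_blocks.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return [FeatureBlockSpec(name=b["name"], group=b["group"], length=int(b["length"]),
                             kind=b["kind"], params=b.get("params", {}) or {})
            for b in raw["blocks"]]


def default_block_config() -> list[FeatureBlockSpec]:
    """The shipped 52-block, 1610-dimension default configuration."""
    return load_block_config()


def total_length(config: list[FeatureBlockSpec]) -> int:
    return sum(b.length for b in config)


def config_columns(config: list[FeatureBlockSpec]) -> list[str]:
    cols = [c for b in config for c in b.columns()]
    if len(set(cols)) != len(cols):
        raise ValueError("duplicate column names in configuration")
    return cols


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Proteins x named feature dimensions, with a missing-value mask.

    ``values`` holds NaN exactly where ``missing_mask`` is True.
    """

    protein_ids: list[str]
    column_names: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, m = self.values.shape
        if len(self.protein_ids) != n or len(self.column_names) != m:
            raise ValueError("shape mismatch between ids/columns and values")
        if len(set(self.protein_ids)) != n:
            raise ValueError("duplicate protein ids")
        if self.missing_mask.shape != (n, m):
            raise ValueError("mask shape mismatch")

    @classmethod
    def from_values(cls, ids, columns, values) -> "FeatureMatrix":
        values = np.asarray(values, dtype=float)
        return cls(list(ids), list(columns), values, np.isnan(values))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.protein_ids, columns=self.column_names)
        df.index.name = "protein_id"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls.from_values(df.index.astype(str), df.columns.astype(str),
                               df.to_numpy(dtype=float))

    def subset_columns(self, columns: list[str]) -> "FeatureMatrix":
        pos = {c: i for i, c in enumerate(self.column_names)}
        missing = [c for c in columns if c not in pos]
        if missing:
            raise KeyError(f"unknown columns: {missing[:5]}")
        j = [pos[c] for c in columns]
        return FeatureMatrix(list(self.protein_ids), list(columns),
                             self.values[:, j], self.missing_mask[:, j])

    def subset_rows(self, ids: list[str]) -> "FeatureMatrix":
        pos = {p: i for i, p in enumerate(self.protein_ids)}
        i = [pos[p] for p in ids]
        return FeatureMatrix(list(ids), list(self.column_names),
                             self.values[i], self.missing_mask[i])


def ingest_external_features(table: pd.DataFrame, config: list[FeatureBlockSpec]) -> FeatureMatrix:
    """Copy predictor-derived feature columns into their configured blocks.

    ``table`` is indexed by protein id; its column names must match
    block-qualified column names of the configuration (for length-1 blocks the
    bare block name). Cells absent from the table stay missing.
    """
    cols = config_columns(config)
    known = set(cols)
    unmatched = [c for c in table.columns if c not in known]
    if unmatched:
        raise ValueError(f"unknown external feature columns: {unmatched}")
    if table.index.has_duplicates:
        raise ValueError("duplicate protein ids in external table")
    ids = [str(i) for i in table.index]
    values = np.full((len(ids), len(cols)), np.nan)
    pos = {c: j for j, c in enumerate(cols)}
    for c in table.columns:
        values[:, pos[c]] = pd.to_numeric(table[c], errors="coerce").to_numpy()
    return FeatureMatrix.from_values(ids, cols, values)


def build_feature_matrix(records: list[ProteinRecord],
                         config: list[FeatureBlockSpec] | None = None,
                         external: pd.DataFrame | None = None) -> FeatureMatrix:
    """Featurize ``records`` under ``config`` (default 52 blocks / 1610 dims).

    Internal blocks are computed from the sequences; blocks of kind
    ``external`` are filled from ``external`` (see
    :func:`ingest_external_features`) where provided, else flagged missing.
    """
    if config is None:
        config = default_block_config()
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in records")
    cols = config_columns(config)
    values = np.full((len(records), len(cols)), np.nan)
    offsets = np.cumsum([0] + [b.length for b in config])
    for i, rec in enumerate(records):
        for b, spec in enumerate(config):
            values[i, offsets[b]:offsets[b + 1]] = compute_block(spec, rec.sequence)
    fm = FeatureMatrix.from_values(ids, cols, values)
    if external is not None:
        ext = ingest_external_features(external, config)
        pos = {p: i for i, p in enumerate(ext.protein_ids)}
        colpos = {c: j for j, c in enumerate(cols)}
        for c in external.columns:
            j = colpos[c]
            for i, pid in enumerate(ids):
                if pid in pos:
                    v = ext.values[pos[pid], j]
                    if not np.isnan(v):
                        fm.values[i, j] = v
                        fm.missing_mask[i, j] = False
    n_missing = int(fm.missing_mask.sum())
    if n_missing:
        logger.info("feature matrix has %d missing cells (of %d)", n_missing, fm.values.size)
    return fm
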