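"""Synthetic fixtures with the statistical structure the method assumes.

Three generators, each a pure function of its configuration (seed included):

* protein sequences whose residue composition differs between a secreted
  (positive) and a background class, with a positive-unlabeled label
  structure — a configurable fraction of the unlabeled pool are hidden
  positives drawn from the positive distribution;
* tabular feature sets with mean-shifted informative columns and Gaussian
  noise columns, for exercising the selection pipeline directly;
* FPKM-like expression matrices with planted up-/down-regulated genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amino_acids import ALPHABET
from .sequence_features import FeatureMatrix, ProteinRecord

# Average amino-acid frequencies of the reviewed human/SwissProt proteome.
BACKGROUND_COMPOSITION = {
    "A": 0.0825, "C": 0.0137, "D": 0.0545, "E": 0.0675, "F": 0.0386,
    "G": 0.0707, "H": 0.0227, "I": 0.0596, "K": 0.0584, "L": 0.0966,
    "M": 0.0242, "N": 0.0406, "P": 0.0470, "Q": 0.0393, "R": 0.0553,
    "S": 0.0656, "T": 0.0534, "V": 0.0687, "W": 0.0108, "Y": 0.0292,
}

# Fixed +/-1 direction along which the two class compositions separate.
_CLASS_DIRECTION = np.array([1, -1] * 10, dtype=float)


@dataclass(frozen=True)
class SequenceGenConfig:
    n_pos: int = 300
    n_unlabeled: int = 600
    hidden_positive_fraction: float = 0.2
    length_range: tuple = (50, 300)
    composition_shift: float = 0.5
    seed: int = 0
    id_prefix: str = ""  # distinguishes e.g. train from held-out draws


@dataclass(frozen=True)
class ExprGenConfig:
    n_genes: int = 1000
    n_case: int = 40
    n_control: int = 40
    n_up: int = 50
    n_down: int = 50
    effect_fc: float = 4.0
    noise_sd: float = 0.5  # log-scale
    seed: int = 0


def class_compositions(shift: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean residue compositions of the positive and background classes,
    obtained by tilting the proteome background by exp(+/- shift/2) along a
    fixed direction."""
    base = np.array([BACKGROUND_COMPOSITION[a] for a in ALPHABET])
    pos = base * np.exp(0.5 * shift * _CLASS_DIRECTION)
    neg = base * np.exp(-0.5 * shift * _CLASS_DIRECTION)
    return pos / pos.sum(), neg / neg.sum()


def _draw_sequence(rng: np.random.Generator, comp: np.ndarray,
                   length_range: tuple, concentration: float = 200.0) -> str:
    """One sequence: per-protein composition ~ Dirichlet(concentration*comp),
    residues iid from it, length uniform over the range."""
    n = int(rng.integers(length_range[0], length_range[1] + 1))
    theta = rng.dirichlet(concentration * comp)
    idx = rng.choice(20, size=n, p=theta)
    return "".join(ALPHABET[i] for i in idx)


def gen_pu_sequences(config: SequenceGenConfig = SequenceGenConfig()):
    """Generate a positive-unlabeled sequence dataset.

    Returns (records, positive_ids, unlabeled_ids, hidden_truth) where
    ``hidden_truth`` maps each unlabeled id to its latent label (True for the
    hidden positives mixed into the unlabeled pool).
    """
    lo, hi = config.length_range
    if not (0 < lo <= hi) or config.n_pos <= 0 or config.n_unlabeled <= 0:
        raise ValueError("infeasible generator configuration")
    rng = np.random.default_rng(config.seed)
    pos_comp, neg_comp = class_compositions(config.composition_shift)
    records, positive_ids, unlabeled_ids = [], [], []
    hidden_truth = {}
    for i in range(config.n_pos):
        pid = f"{config.id_prefix}POS{i:05d}"
        records.append(ProteinRecord(pid, _draw_sequence(rng, pos_comp, config.length_range)))
        positive_ids.append(pid)
    n_hidden = int(round(config.hidden_positive_fraction * config.n_unlabeled))
    for i in range(config.n_unlabeled):
        pid = f"{config.id_prefix}UNL{i:05d}"
        is_hidden = i < n_hidden
        comp = pos_comp if is_hidden else neg_comp
        records.append(ProteinRecord(pid, _draw_sequence(rng, comp, config.length_range)))
        unlabeled_ids.append(pid)
        hidden_truth[pid] = bool(is_hidden)
    return records, positive_ids, unlabeled_ids, hidden_truth


def gen_feature_table(n_pos: int, n_neg: int, n_informative: int, n_noise: int,
                      effect_size: float, seed: int = 0):
    """Gaussian feature table: informative columns are shifted by
    ``effect_size`` in the positive class, noise columns are standard normal.

    Returns (FeatureMatrix, labels) with informative columns first
    (``inf000``...) then noise columns (``noise000``...).
    """
    if min(n_pos, n_neg) <= 0 or n_informative < 0 or n_noise < 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    x = rng.normal(size=(n, n_informative + n_noise))
    x[labels == 1, :n_informative] += effect_size
    cols = [f"inf{j:03d}" for j in range(n_informative)] + \
           [f"noise{j:03d}" for j in range(n_noise)]
    ids = [f"S{i:05d}" for i in range(n)]
    return FeatureMatrix.from_values(ids, cols, x), labels


def gen_expression(config: ExprGenConfig = ExprGenConfig()):
    """FPKM-like expression matrix with planted fold changes.

    Baseline per-gene level is log-normal; each sample value multiplies it by
    exp(N(0, noise_sd)). The first ``n_up`` genes are scaled by ``effect_fc``
    and the next ``n_down`` by 1/effect_fc in the case group. Returns
    (matrix DataFrame genes x samples, groups Series, truth dict gene->status,
    mapping DataFrame gene->protein).
    """
    if config.n_up + config.n_down > config.n_genes:
        raise ValueError("planted genes exceed total genes")
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    samples = [f"case{j:03d}" for j in range(config.n_case)] + \
              [f"ctrl{j:03d}" for j in range(config.n_control)]
    groups = pd.Series(["case"] * config.n_case + ["control"] * config.n_control,
                       index=samples, name="group")
    base = np.exp(rng.normal(2.0, 1.0, size=config.n_genes))
    noise = np.exp(rng.normal(0.0, config.noise_sd,
                              size=(config.n_genes, len(samples))))
    values = base[:, None] * noise
    effect = np.ones(config.n_genes)
    effect[:config.n_up] = config.effect_fc
    effect[config.n_up:config.n_up + config.n_down] = 1.0 / config.effect_fc
    values[:, :config.n_case] *= effect[:, None]
    truth = {g: ("up" if i < config.n_up else
                 "down" if i < config.n_up + config.n_down else "null")
             for i, g in enumerate(genes)}
    mapping = pd.DataFrame({"gene": genes,
                            "protein": [g.replace("G", "P", 1) for g in genes]})
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    return matrix, groups, truth, mapping
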