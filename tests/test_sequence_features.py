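"""Descriptor correctness against explicit-loop oracles and layout contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csfpred import sequence_features as sf
from csfpred.amino_acids import (
    ALPHABET,
    DISTANCE_MATRICES,
    GRANTHAM_MATRIX,
    RESIDUE_MASS,
    WATER_MASS,
    PropertyScale,
)

from conftest import random_sequence

seq_strategy = st.text(alphabet=ALPHABET, min_size=1, max_size=40)


# ---------------------------------------------------------------------- sanitize

@pytest.mark.parametrize("raw, policy, expected", [
    ("acdE", "strip", "ACDE"),
    ("ACXDE", "strip", "ACDE"),
    ("acde", "reject", "ACDE"),
])
def test_sanitize_normalizes_case_and_strips(raw, policy, expected):
    assert sf.sanitize_sequence(raw, policy) == expected


def test_sanitize_degenerate_and_reject():
    with pytest.raises(ValueError):
        sf.sanitize_sequence("XXX", "strip")  # empty after strip
    with pytest.raises(ValueError):
        sf.sanitize_sequence("ACXDE", "reject")
    with pytest.raises(ValueError):
        sf.sanitize_sequence("")


# ------------------------------------------------------------------ compositions

def test_aac_known_values():
    v = sf.aac("AAAA")
    assert v[ALPHABET.index("A")] == 1.0 and v.sum() == 1.0
    v = sf.aac("ACAC")
    assert v[ALPHABET.index("A")] == 0.5 and v[ALPHABET.index("C")] == 0.5


def test_dpc_enumerates_adjacent_pairs():
    v = sf.dpc("ACAC")  # pairs AC, CA, AC
    pairs = {p: x for p, x in zip(sf.DIPEPTIDES, v) if x > 0}
    assert pairs == {"AC": pytest.approx(2 / 3), "CA": pytest.approx(1 / 3)}
    assert sf.dpc("AA")[sf.DIPEPTIDES.index("AA")] == 1.0
    assert np.isnan(sf.dpc("A")).all()  # no pairs: missing block


@settings(max_examples=30, derandomize=True, deadline=None)
@given(seq_strategy)
def test_composition_blocks_sum_to_one(seq):
    assert sf.aac(seq).sum() == pytest.approx(1.0, abs=1e-12)
    if len(seq) >= 2:
        assert sf.dpc(seq).sum() == pytest.approx(1.0, abs=1e-12)
    lam = min(3, len(seq) - 1)
    if lam >= 1:
        assert sf.paac(seq, lam=lam).sum() == pytest.approx(1.0, abs=1e-9)
        assert sf.apaac(seq, lam=lam).sum() == pytest.approx(1.0, abs=1e-9)


# --------------------------------------------------------------- autocorrelation

def _z(scale):
    v = scale.as_array()
    return (v - v.mean()) / v.std()


def _oracle_autocorr(seq, scale, d, kind):
    """Independent direct-summation oracle over residue pairs at lag d."""
    p = [_z(scale)[ALPHABET.index(c)] for c in seq]
    n = len(p)
    pbar = sum(p) / n
    if kind == "moreau_broto_normalized":
        return sum(p[i] * p[i + d] for i in range(n - d)) / (n - d)
    if kind == "moran":
        denom = sum((x - pbar) ** 2 for x in p) / n
        num = sum((p[i] - pbar) * (p[i + d] - pbar) for i in range(n - d)) / (n - d)
        return 0.0 if denom == 0 else num / denom
    denom = sum((x - pbar) ** 2 for x in p) / (n - 1)
    num = sum((p[i] - p[i + d]) ** 2 for i in range(n - d)) / (2 * (n - d))
    return 0.0 if denom == 0 else num / denom


@pytest.mark.parametrize("kind", ["moreau_broto_normalized", "moran", "geary"])
def test_autocorrelation_matches_bruteforce(kind, rng):
    scale = sf.SCALES["hydrophobicity"]
    for seq in [ALPHABET, random_sequence(rng, 25), random_sequence(rng, 12)]:
        maxlag = 5
        got = sf.autocorrelation(seq, [scale], maxlag, kind)
        want = [_oracle_autocorr(seq, scale, d, kind) for d in range(1, maxlag + 1)]
        np.testing.assert_allclose(got, want, atol=1e-12)


def test_autocorrelation_degenerate_and_layout():
    # constant-property sequence: zero variance convention -> 0 for moran/geary
    assert (sf.autocorrelation("AAAAAA", [sf.SCALES["hydrophobicity"]], 3, "moran") == 0).all()
    assert (sf.autocorrelation("AAAAAA", [sf.SCALES["hydrophobicity"]], 3, "geary") == 0).all()
    # 3 scales x 30 lags = 90 dims
    scales = [sf.SCALES[s] for s in ("hydrophobicity", "polarity", "polarizability")]
    out = sf.autocorrelation(random_sequence(np.random.default_rng(0), 40), scales, 30, "moran")
    assert out.shape == (90,)
    # infeasible lags flagged missing
    short = sf.autocorrelation("ACDE", [scales[0]], 10, "moran")
    assert np.isnan(short[4:]).all() and not np.isnan(short[:3]).any()


# -------------------------------------------------------------------------- QSO

def _oracle_qso(seq, maxlag, weight, matrices):
    """Direct double-loop coupling sums."""
    out = []
    n = len(seq)
    f = [seq.count(a) / n for a in ALPHABET]
    for mat in matrices.values():
        tau = []
        for d in range(1, maxlag + 1):
            s = 0.0
            for i in range(n - d):
                s += mat[ALPHABET.index(seq[i]), ALPHABET.index(seq[i + d])] ** 2
            tau.append(s)
        denom = 1.0 + weight * sum(tau)
        out += [x / denom for x in f] + [weight * t / denom for t in tau]
    return np.array(out)


def test_qso_matches_bruteforce(rng):
    seq = random_sequence(rng, 15)
    got = sf.qso(seq, maxlag=2, weight=0.1)
    np.testing.assert_allclose(got, _oracle_qso(seq, 2, 0.1, DISTANCE_MATRICES), atol=1e-12)


def test_qso_layout_and_homopolymer():
    assert sf.qso(random_sequence(np.random.default_rng(1), 100)).shape == (160,)
    # self-distance 0 -> all coupling terms vanish on a homopolymer
    v = sf.qso("A" * 100, maxlag=10)
    per = 30  # 20 composition + 10 coupling per matrix
    for m in range(2):
        assert (v[m * per + 20: (m + 1) * per] == 0).all()
    assert np.isnan(sf.qso("ACDE", maxlag=60)).all()  # too short: missing


def test_grantham_matrix_spot_values():
    # classic published distances: Leu-Ile 5, Ser-Arg 110 (within rounding)
    i, j = ALPHABET.index("L"), ALPHABET.index("I")
    assert GRANTHAM_MATRIX[i, j] == pytest.approx(5, abs=1)
    i, j = ALPHABET.index("S"), ALPHABET.index("R")
    assert GRANTHAM_MATRIX[i, j] == pytest.approx(110, abs=2)
    assert np.allclose(np.diag(GRANTHAM_MATRIX), 0)


# ------------------------------------------------------------------ PAAC / APAAC

def _oracle_paac(seq, lam, weight, scales):
    n = len(seq)
    zs = [_z(s) for s in scales]
    theta = []
    for d in range(1, lam + 1):
        tot = 0.0
        for i in range(n - d):
            a, b = ALPHABET.index(seq[i]), ALPHABET.index(seq[i + d])
            tot += sum((z[b] - z[a]) ** 2 for z in zs) / len(zs)
        theta.append(tot / (n - d))
    f = [seq.count(a) / n for a in ALPHABET]
    denom = 1.0 + weight * sum(theta)
    return np.array([x / denom for x in f] + [weight * t / denom for t in theta])


def test_paac_matches_bruteforce(rng):
    seq = "ACDEFGHIKL"
    scales = [sf.SCALES[s] for s in ("hydrophobicity", "hydrophilicity", "side_chain_mass")]
    got = sf.paac(seq, lam=2, weight=0.05)
    np.testing.assert_allclose(got, _oracle_paac(seq, 2, 0.05, scales), atol=1e-12)


def test_paac_limits_and_layout():
    assert sf.paac("A" * 131).shape == (150,)
    assert np.isnan(sf.paac("A" * 130)).all()  # length <= lam: missing
    seq = "ACDEFGHIKL"
    v = sf.paac(seq, lam=2, weight=0.0)
    np.testing.assert_allclose(v[:20], sf.aac(seq), atol=1e-12)
    assert (v[20:] == 0).all()


def _oracle_apaac(seq, lam, weight):
    n = len(seq)
    h1 = _z(sf.SCALES["hydrophobicity"])
    h2 = _z(sf.SCALES["hydrophilicity"])
    tau = []
    for d in range(1, lam + 1):
        for z in (h1, h2):
            tau.append(sum(z[ALPHABET.index(seq[i])] * z[ALPHABET.index(seq[i + d])]
                           for i in range(n - d)) / (n - d))
    f = [seq.count(a) / n for a in ALPHABET]
    denom = 1.0 + weight * sum(tau)
    return np.array([x / denom for x in f] + [weight * t / denom for t in tau])


def test_apaac_matches_bruteforce_and_layout():
    seq = "ACDEF"
    np.testing.assert_allclose(sf.apaac(seq, lam=1, weight=0.05),
                               _oracle_apaac(seq, 1, 0.05), atol=1e-12)
    assert sf.apaac("A" * 31, lam=30).shape == (80,)
    v = sf.apaac(seq, lam=1, weight=0.0)
    np.testing.assert_allclose(v[:20], sf.aac(seq), atol=1e-12)


# ------------------------------------------------------------ profiles & scalars

def test_property_profile():
    scale = PropertyScale("toy", {a: (2.0 if a == "A" else 0.0) for a in ALPHABET})
    v = sf.property_profile("AAAA", scale)
    assert v[ALPHABET.index("A")] == 2.0 and v[-1] == 2.0
    assert (np.delete(v, ALPHABET.index("A"))[:-1] == 0).all()
    zero = PropertyScale("zero", {a: 0.0 for a in ALPHABET})
    assert (sf.property_profile("ACDE", zero) == 0).all()


def test_property_profile_mean_matches_direct_loop(rng):
    seq = random_sequence(rng, 50)
    scale = sf.SCALES["polarity"]
    direct = sum(scale.values[c] for c in seq) / len(seq)
    assert sf.property_profile(seq, scale)[-1] == pytest.approx(direct, rel=1e-12)


def test_simple_scalars():
    assert sf.sequence_mass("G") == pytest.approx(RESIDUE_MASS["G"] + WATER_MASS, abs=0.1)
    # independent table-lookup oracle
    want = sum(RESIDUE_MASS[c] for c in "ACDE") + WATER_MASS
    assert sf.sequence_mass("ACDE") == pytest.approx(want, rel=1e-3)
    assert sf.isoelectric_point("K" * 20) > sf.isoelectric_point("D" * 20)
    tot = sf.total_aa_property("ACDE")
    assert tot.shape == (3,)
    assert tot[1] == pytest.approx(-2.0)  # charge sum of A,C,D,E


def test_scale_normalization_idempotent():
    s = sf.SCALES["hydrophobicity"].normalized()
    v = s.as_array()
    assert v.mean() == pytest.approx(0, abs=1e-12) and v.std() == pytest.approx(1)
    np.testing.assert_allclose(s.normalized().as_array(), v, atol=1e-12)


# ------------------------------------------------------------------ build matrix

def test_default_config_reproduces_published_layout():
    config = sf.default_block_config()
    assert len(config) == 52
    assert sf.total_length(config) == 1610
    lengths = {b.name: b.length for b in config}
    assert lengths["aac"] == 20 and lengths["dpc"] == 400
    assert lengths["qso"] == 160 and lengths["paac"] == 150 and lengths["apaac"] == 80
    by_group = {}
    for b in config:
        by_group[b.group] = by_group.get(b.group, 0) + 1
    assert by_group == {"general": 11, "physicochemical": 24,
                        "domain_motif": 11, "structural": 6}


def test_build_feature_matrix_shapes_and_missingness(rng):
    recs = [sf.ProteinRecord(f"P{i}", random_sequence(rng, 200)) for i in range(3)]
    fm = sf.build_feature_matrix(recs)
    assert fm.values.shape == (3, 1610)
    # external blocks (15 + 26 dims) missing for every protein; internals computed
    assert fm.missing_mask.sum() == 3 * 41
    config = [b for b in sf.default_block_config() if b.name in ("aac", "dpc")]
    assert sf.build_feature_matrix(recs, config).values.shape == (3, 420)


def test_build_rejects_duplicate_ids():
    r = sf.ProteinRecord("P1", "ACDE")
    with pytest.raises(ValueError):
        sf.build_feature_matrix([r, r])


def test_featurization_deterministic_and_row_equivariant(rng):
    recs = [sf.ProteinRecord(f"P{i}", random_sequence(rng, 80)) for i in range(4)]
    config = [b for b in sf.default_block_config()
              if b.name in ("aac", "moran", "qso", "profile_hydrophobicity")]
    a = sf.build_feature_matrix(recs, config)
    b = sf.build_feature_matrix(recs, config)
    np.testing.assert_array_equal(a.values, b.values)  # bit-identical
    perm = [recs[2], recs[0], recs[3], recs[1]]
    c = sf.build_feature_matrix(perm, config)
    np.testing.assert_array_equal(c.values, a.subset_rows([r.id for r in perm]).values)


def test_ingest_external_features(rng):
    import pandas as pd
    config = sf.default_block_config()
    recs = [sf.ProteinRecord(f"P{i}", random_sequence(rng, 150)) for i in range(2)]
    table = pd.DataFrame({"signal_peptide": [1.0]}, index=["P0"])
    fm = sf.build_feature_matrix(recs, config, external=table)
    j = fm.column_names.index("signal_peptide")
    assert fm.values[0, j] == 1.0 and not fm.missing_mask[0, j]
    assert fm.missing_mask[1, j]
    with pytest.raises(ValueError, match="no_such"):
        sf.ingest_external_features(pd.DataFrame({"no_such": [1]}, index=["P0"]), config)


def test_external_table_round_trip(tmp_path, rng):
    import pandas as pd
    config = sf.default_block_config()
    ids = ["P0", "P1"]
    table = pd.DataFrame({"signal_peptide": [1.0, 0.0], "unfoldability": [0.3, 0.7]},
                         index=ids)
    fm = sf.ingest_external_features(table, config)
    path = tmp_path / "ext.tsv"
    sub = fm.to_frame()[["signal_peptide", "unfoldability"]]
    sub.to_csv(path, sep="\t")
    back = pd.read_csv(path, sep="\t", index_col=0)
    fm2 = sf.ingest_external_features(back, config)
    np.testing.assert_allclose(fm.values, fm2.values, atol=1e-12)
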