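"""Closed-form descriptor tests against hand computations and naive oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promdesign.features_numeric import (
    EIIP_TABLE,
    ZeroVarianceError,
    cgr_trajectory,
    cksnap,
    dinucleotide_moran,
    eiip_features,
    extract_kmers,
    gc_content,
    kmer_count_features,
    morans_i,
    pssm_from_cgr,
)

dna = st.text(alphabet="ACGT", min_size=10, max_size=60)


# ---------------------------------------------------------------------------
# naive double-loop oracles, independent of the implementation
# ---------------------------------------------------------------------------

def naive_cksnap(seq, K_max):
    from itertools import product
    pairs = ["".join(p) for p in product("ACGT", repeat=2)]
    out = []
    for gap in range(K_max):
        block = []
        total = len(seq) - gap - 1
        for pair in pairs:
            c = 0
            for i in range(len(seq)):
                j = i + gap + 1
                if j < len(seq) and seq[i] + seq[j] == pair:
                    c += 1
            block.append(c / total)
        out.extend(block)
    return np.array(out)


def naive_kmer_freqs(seq, k):
    from itertools import product
    out = []
    windows = len(seq) - k + 1
    for km in ("".join(p) for p in product("ACGT", repeat=k)):
        c = sum(1 for i in range(windows) if seq[i : i + k] == km)
        out.append(c / windows)
    return np.array(out)


def naive_eiip(seq, k):
    freqs = naive_kmer_freqs(seq, k)
    from itertools import product
    weights = np.array(
        [sum(EIIP_TABLE[ch] for ch in "".join(p)) for p in product("ACGT", repeat=k)]
    )
    return freqs * weights


def naive_moran(x, lag=1):
    x = np.asarray(x, dtype=float)
    n = len(x)
    xbar = x.mean()
    num = 0.0
    W = 0.0
    for i in range(n):
        for j in range(n):
            w = 1.0 if abs(i - j) == lag else 0.0
            W += w
            num += w * (x[i] - xbar) * (x[j] - xbar)
    return (n / W) * num / np.sum((x - xbar) ** 2)


# ---------------------------------------------------------------------------
# worked micro-examples
# ---------------------------------------------------------------------------

def test_gc_content_examples():
    assert gc_content("ATGC") == 50.0
    assert gc_content("AAAA") == 0.0
    assert gc_content("GCGCGC") == 100.0
    with pytest.raises(ValueError):
        gc_content("")


def test_cgr_hand_iterations():
    # one midpoint step from the center toward the A corner (0, 0)
    traj = cgr_trajectory("A")
    assert traj.shape == (1, 2)
    assert np.allclose(traj[0], (0.25, 0.25))
    # second step toward G = (1, 1): midpoint of (0.25, 0.25) and (1, 1)
    traj = cgr_trajectory("AG")
    assert np.allclose(traj, [(0.25, 0.25), (0.625, 0.625)])


def test_cgr_points_stay_in_unit_square(random_sequence):
    traj = cgr_trajectory(random_sequence(1000))
    assert traj.min() >= 0.0 and traj.max() <= 1.0


def test_cgr_contraction_in_first_base(random_sequence):
    """Trajectories differing only in base 1 converge at rate 2^-position."""
    tail = random_sequence(40)
    t1 = cgr_trajectory("A" + tail)
    t2 = cgr_trajectory("G" + tail)
    for pos in (1, 5, 10):
        dist = np.abs(t1[pos - 1] - t2[pos - 1]).max()
        # initial corner separation is 1; each midpoint step halves it
        assert dist == pytest.approx(2.0 ** -(pos - 1) * 0.5, rel=1e-12)


def test_pssm_binning_and_mass():
    grid = pssm_from_cgr(np.array([[0.25, 0.25]]))
    assert grid[5, 5] == 1.0 and grid.sum() == 1.0
    # the 1.0 coordinate folds into the final bin rather than overflowing
    grid = pssm_from_cgr(np.array([[1.0, 1.0]]))
    assert grid[19, 19] == 1.0
    with pytest.raises(ValueError):
        pssm_from_cgr(np.empty((0, 2)))


@given(dna)
@settings(max_examples=50, deadline=None)
def test_pssm_mass_conservation(seq):
    grid = pssm_from_cgr(cgr_trajectory(seq))
    assert grid.sum() == pytest.approx(1.0, abs=1e-12)
    assert (grid >= 0).all()


def test_extract_kmers():
    assert extract_kmers("ATGCA", 3) == ["ATG", "TGC", "GCA"]
    assert len(extract_kmers("A" * 50, 3)) == 48
    with pytest.raises(ValueError):
        extract_kmers("AT", 3)


def test_moran_alternating_series_is_minus_one():
    assert morans_i([1, 0, 1, 0]).I == pytest.approx(-1.0, abs=1e-15)


def test_moran_correlated_blocks_positive():
    assert morans_i([1, 1, 1, 0, 0, 0]).I > 0


def test_moran_matches_double_loop_oracle():
    assert morans_i([1, 1, 0, 0]).I == pytest.approx(naive_moran([1, 1, 0, 0]), abs=1e-12)


def test_moran_zero_variance_error():
    with pytest.raises(ZeroVarianceError):
        morans_i([3.0, 3.0, 3.0, 3.0])


def test_dinucleotide_moran_oracle_and_errors():
    # ATATAT: dinucleotide series alternates between freq(AT) and freq(TA)
    series = [3 / 5, 2 / 5, 3 / 5, 2 / 5, 3 / 5]
    assert dinucleotide_moran("ATATAT").I == pytest.approx(naive_moran(series), abs=1e-12)
    with pytest.raises(ZeroVarianceError):
        dinucleotide_moran("AAAA")


def test_cksnap_worked_example():
    v = cksnap("AATT", K_max=2)
    # gap 0: adjacent pairs AA, AT, TT each once over 3 windows
    assert v["cksnap_g0_AA"] == pytest.approx(1 / 3)
    assert v["cksnap_g0_AT"] == pytest.approx(1 / 3)
    assert v["cksnap_g0_TT"] == pytest.approx(1 / 3)
    assert v[[f"cksnap_g0_{p}" for p in ("AC", "CA", "GG", "TA")]].sum() == 0
    # gap 1: pairs (s1,s3) = AT and (s2,s4) = AT
    assert v["cksnap_g1_AT"] == pytest.approx(1.0)


def test_eiip_worked_examples():
    v = eiip_features("AAA", (3,))
    assert v["eiip_k3_AAA"] == pytest.approx(3 * EIIP_TABLE["A"], abs=1e-12)
    assert v["eiip_k3_AAA"] == pytest.approx(0.3780, abs=1e-12)
    assert v["eiip_k3_GGG"] == 0.0
    # doubling the homopolymer leaves the frequency (and the feature) at 1.0
    assert eiip_features("AAAAAA", (3,))["eiip_k3_AAA"] == pytest.approx(0.3780)


def test_kmer_count_worked_example():
    v = kmer_count_features("ACAC", (2,))
    assert v["kmer2_AC"] == pytest.approx(2 / 3)
    assert v["kmer2_CA"] == pytest.approx(1 / 3)


def test_kmer_feature_names_stable(random_sequence):
    a = kmer_count_features(random_sequence(30), (2, 3))
    b = kmer_count_features(random_sequence(30), (2, 3))
    assert list(a.index) == list(b.index)


# ---------------------------------------------------------------------------
# oracle equivalence on random sequences
# ---------------------------------------------------------------------------

def test_oracle_equivalence_on_random_sequences():
    gen = np.random.default_rng(42)
    for _ in range(200):
        length = int(gen.integers(10, 61))
        seq = "".join(gen.choice(list("ACGT"), size=length))
        np.testing.assert_allclose(
            cksnap(seq, 5).to_numpy(), naive_cksnap(seq, 5), atol=1e-12)
        np.testing.assert_allclose(
            eiip_features(seq, (3,)).to_numpy(), naive_eiip(seq, 3), atol=1e-12)
        np.testing.assert_allclose(
            kmer_count_features(seq, (2, 3)).to_numpy(),
            np.concatenate([naive_kmer_freqs(seq, 2), naive_kmer_freqs(seq, 3)]),
            atol=1e-12)
        series = gen.normal(size=int(gen.integers(4, 12)))
        np.testing.assert_allclose(morans_i(series).I, naive_moran(series), atol=1e-12)


@given(dna)
@settings(max_examples=50, deadline=None)
def test_cksnap_blocks_sum_to_one(seq):
    v = cksnap(seq, 5).to_numpy()
    for gap in range(5):
        assert v[16 * gap : 16 * (gap + 1)].sum() == pytest.approx(1.0, abs=1e-12)


@given(dna)
@settings(max_examples=50, deadline=None)
def test_kmer_blocks_sum_to_one(seq):
    v = kmer_count_features(seq, (2, 3)).to_numpy()
    assert v[:16].sum() == pytest.approx(1.0, abs=1e-12)
    assert v[16:].sum() == pytest.approx(1.0, abs=1e-12)
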