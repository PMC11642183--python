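"""Adversarial generator contracts: output validity, determinism, screening."""

import numpy as np
import pytest

from promdesign import nn
from promdesign.gan import (
    Discriminator,
    GeneratorConfig,
    ScreeningCriteria,
    corpus_screening_targets,
    sample_sequences,
    screen_sequences,
    train_gan,
)
from promdesign.sequence_io import PromoterRecord, one_hot_encode
from promdesign.synthetic_data import PlantedMotif, SyntheticSpec, generate_corpus


@pytest.fixture(scope="module")
def tiny_corpus():
    spec = SyntheticSpec(
        n=60, length=20, seed=8,
        motifs=(PlantedMotif("TATAAT", (5, 12), 1.0, 0.5),),
    )
    return generate_corpus(spec)


@pytest.fixture(scope="module")
def tiny_config():
    return GeneratorConfig(length=20, noise_dim=8, hidden=16, epochs=2,
                           batch_size=16, seed=8)


@pytest.fixture(scope="module")
def trained(tiny_corpus, tiny_config):
    return train_gan(tiny_corpus, tiny_config)


def test_training_log_covers_every_epoch(trained, tiny_config):
    assert list(trained.training_log["epoch"]) == list(range(tiny_config.epochs))
    assert np.isfinite(trained.training_log[["gen_loss", "disc_loss"]]).all().all()


def test_sampled_sequences_are_valid(trained):
    seqs = sample_sequences(trained, 10, seed=1)
    assert len(seqs) == 10
    assert all(len(s) == 20 for s in seqs)
    assert set("".join(seqs)) <= set("ACGT")


def test_sampling_deterministic_under_seed(trained):
    assert sample_sequences(trained, 5, seed=3) == sample_sequences(trained, 5, seed=3)
    with pytest.raises(ValueError):
        sample_sequences(trained, 0)


def test_generator_rows_are_probability_vectors(trained, rng):
    probs = trained.probabilities(rng.normal(size=(4, 8)))
    assert probs.shape == (4, 20, 4)
    assert (probs >= 0).all()
    np.testing.assert_allclose(probs.sum(axis=2), 1.0, atol=1e-6)


def test_first_epoch_losses_reproducible(tiny_corpus, tiny_config):
    a = train_gan(tiny_corpus, tiny_config).training_log.iloc[0]
    b = train_gan(tiny_corpus, tiny_config).training_log.iloc[0]
    assert a["gen_loss"] == b["gen_loss"]
    assert a["disc_loss"] == b["disc_loss"]


def test_mixed_length_corpus_rejected(tiny_config):
    bad = [PromoterRecord("a", "ACGT" * 5), PromoterRecord("b", "ACGT" * 6)]
    with pytest.raises(ValueError, match="length"):
        train_gan(bad, tiny_config)


def test_sampling_consistency_with_output_distribution(trained):
    """Temperature-1 sampling frequencies track the generator's mean
    per-position output distribution (within 5 percentage points)."""
    rng = np.random.default_rng(0)
    mean_probs = np.zeros((20, 4))
    n_ref = 2000
    for s in range(0, n_ref, 256):
        nb = min(256, n_ref - s)
        mean_probs += trained.probabilities(rng.normal(size=(nb, 8))).sum(axis=0)
    mean_probs /= n_ref
    seqs = sample_sequences(trained, 10_000, seed=5, method="sample")
    freq = np.zeros((20, 4))
    lut = {b: i for i, b in enumerate("ACGT")}
    for s in seqs:
        for pos, ch in enumerate(s):
            freq[pos, lut[ch]] += 1
    freq /= len(seqs)
    assert np.abs(freq - mean_probs).max() < 0.05


def test_discriminator_separates_toy_classes(rng):
    """Trained alone on patterned-real vs uniform-random sequences the
    discriminator must reach held-out accuracy > 0.9."""
    config = GeneratorConfig(length=16, noise_dim=8, hidden=16, seed=0)
    real = np.stack([one_hot_encode("ACGT" * 4) for _ in range(64)])
    fake_seqs = ["".join(rng.choice(list("ACGT"), size=16)) for _ in range(64)]
    fake = np.stack([one_hot_encode(s) for s in fake_seqs])
    disc = Discriminator(config, np.random.default_rng(0))
    opt = nn.Adam(list(disc.params.values()), lr=3e-3)
    x = np.concatenate([real[:48], fake[:48]])
    y = np.concatenate([np.ones((48, 1)), np.zeros((48, 1))])
    for _ in range(60):
        loss = nn.bce_loss(disc.forward(x), y)
        opt.zero_grad()
        loss.backward()
        opt.step()
    held = np.concatenate([real[48:], fake[48:]])
    held_y = np.concatenate([np.ones(16), np.zeros(16)])
    acc = ((disc.forward(held).data[:, 0] > 0.5) == held_y).mean()
    assert acc > 0.9


class TestScreening:
    def test_accept_within_both_windows(self):
        crit = ScreeningCriteria(target_gc=0.5, target_moran=0.0,
                                 gc_tolerance=0.5, moran_tolerance=2.0)
        accepted, report = screen_sequences(["ACGTACGT"], crit)
        assert accepted == ["ACGTACGT"]
        assert report.loc[0, "accepted"]

    def test_reject_gc_with_reason(self):
        crit = ScreeningCriteria(target_gc=0.5, target_moran=0.0,
                                 gc_tolerance=0.05, moran_tolerance=10.0)
        accepted, report = screen_sequences(["GGGGGGAT"], crit)  # GC = 0.75
        assert accepted == []
        assert report.loc[0, "reason"] == "gc"

    def test_undefined_moran_rejected_with_reason(self):
        crit = ScreeningCriteria(target_gc=0.0, target_moran=0.0,
                                 gc_tolerance=1.0, moran_tolerance=10.0)
        _, report = screen_sequences(["AAAAAA"], crit)
        assert report.loc[0, "reason"] == "moran_undefined"

    def test_acceptance_count_matches_recount_oracle(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(200)]
        crit = ScreeningCriteria(target_gc=0.5, target_moran=-0.02,
                                 gc_tolerance=0.08, moran_tolerance=0.05)
        accepted, report = screen_sequences(seqs, crit)
        recount = report[
            ~report["moran"].isna()
            & ((report["gc"] - crit.target_gc).abs() <= crit.gc_tolerance)
            & ((report["moran"] - crit.target_moran).abs() <= crit.moran_tolerance)
        ]
        assert len(accepted) == len(recount)
        assert report["accepted"].sum() == len(recount)

    def test_corpus_targets_are_means(self, tiny_corpus):
        gc, moran = corpus_screening_targets(tiny_corpus)
        assert 0.0 <= gc <= 1.0
        assert -1.5 <= moran <= 1.5
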