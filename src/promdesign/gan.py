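"""Adversarial generation of fixed-length promoter-like sequences.

A recurrent generator maps a noise vector to an L x 4 matrix of
per-position base probabilities; a recurrent discriminator scores a
(one-hot or probability-row) sequence as real vs generated.  The
generator minimizes the negative log probability that the discriminator
calls its output real; the discriminator minimizes binary cross-entropy
with real -> 1, generated -> 0.  Updates alternate one-for-one.

During training the discriminator sees the generator's continuous
probability rows (a continuous relaxation that keeps the generator
differentiable); emission discretizes each position by argmax, or by
temperature sampling behind a flag.

Generated candidates are screened post hoc against target GC content
(fraction) and target dinucleotide Moran's I, each within a tolerance
window; the screen is what ties the generator's output back to the
summary statistics of the training corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .features_numeric import ZeroVarianceError, dinucleotide_moran, gc_content
from .sequence_io import BASES, PromoterRecord, one_hot_encode

__all__ = ["GeneratorConfig", "ScreeningCriteria", "Generator", "Discriminator",
           "TrainedGenerator", "train_gan", "sample_sequences", "screen_sequences",
           "corpus_screening_targets", "generate_and_screen"]


@dataclass(frozen=True)
class GeneratorConfig:
    length: int = 50
    noise_dim: int = 64
    hidden: int = 128
    lr_generator: float = 1e-3
    lr_discriminator: float = 1e-3
    batch_size: int = 32
    epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("length", "noise_dim", "hidden", "batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if min(self.lr_generator, self.lr_discriminator) <= 0:
            raise ValueError("learning rates must be positive")


@dataclass(frozen=True)
class ScreeningCriteria:
    """Accept a candidate iff |GC - target_gc| <= gc_tolerance and
    |I - target_moran| <= moran_tolerance (GC as a fraction in [0, 1])."""

    target_gc: float
    target_moran: float
    gc_tolerance: float = 0.05
    moran_tolerance: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_gc <= 1.0:
            raise ValueError("target_gc must be a fraction in [0, 1]")
        if self.gc_tolerance < 0 or self.moran_tolerance < 0:
            raise ValueError("tolerances must be >= 0")


class Generator:
    """Noise (B, noise_dim) -> per-position base probabilities (B, L, 4)."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        self.config = config
        self.lstm = nn.LSTM(config.noise_dim, config.hidden, rng, name="gen.lstm")
        self.head = nn.Dense(config.hidden, 4, rng, name="gen.head")
        self.params = {**self.lstm.params,
                       **{f"head_{k}": v for k, v in self.head.params.items()}}

    def forward(self, noise: np.ndarray) -> nn.Tensor:
        B = noise.shape[0]
        # the noise vector is fed as the input at every timestep
        x = nn.Tensor(np.repeat(noise[:, None, :], self.config.length, axis=1))
        hs = self.lstm(x, return_sequence=True)
        logits = [self.head(h).reshape(B, 1, 4) for h in hs]
        return nn.concat(logits, axis=1).softmax(axis=2)


class Discriminator:
    """Sequence rows (B, L, 4) -> probability of being a real promoter (B, 1)."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        self.lstm = nn.LSTM(4, config.hidden, rng, name="disc.lstm")
        self.head = nn.Dense(config.hidden, 1, rng, name="disc.head")
        self.params = {**self.lstm.params,
                       **{f"head_{k}": v for k, v in self.head.params.items()}}

    def forward(self, x: np.ndarray | nn.Tensor) -> nn.Tensor:
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(x)
        return self.head(self.lstm(x)).sigmoid()


@dataclass
class TrainedGenerator:
    generator: Generator
    config: GeneratorConfig
    training_log: pd.DataFrame = field(repr=False)  # epoch, gen_loss, disc_loss

    def probabilities(self, noise: np.ndarray) -> np.ndarray:
        probs = self.generator.forward(noise).data
        return probs


def train_gan(corpus: list[PromoterRecord], config: GeneratorConfig) -> TrainedGenerator:
    """Alternating adversarial training on a uniform-length corpus.

    Returns the trained generator with a per-epoch log of the mean
    generator and discriminator losses.  Deterministic under the config
    seed.  Aborts on non-finite losses.
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    lengths = {len(r) for r in corpus}
    if lengths != {config.length}:
        raise ValueError(f"corpus lengths {sorted(lengths)} != config length {config.length}")
    rng = np.random.default_rng(config.seed)
    gen = Generator(config, rng)
    disc = Discriminator(config, rng)
    opt_g = nn.Adam(list(gen.params.values()), lr=config.lr_generator)
    opt_d = nn.Adam(list(disc.params.values()), lr=config.lr_discriminator)

    real = np.stack([one_hot_encode(r.sequence) for r in corpus])
    N, B = len(corpus), config.batch_size
    log_rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(N)
        d_losses, g_losses = [], []
        for s in range(0, N, B):
            batch = real[order[s : s + B]]
            nb = len(batch)
            # discriminator step (generated rows detached from the G tape)
            noise = rng.normal(size=(nb, config.noise_dim))
            fake = gen.forward(noise).data
            p_real = disc.forward(batch)
            p_fake = disc.forward(fake)
            d_loss = nn.bce_loss(p_real, np.ones((nb, 1))) + nn.bce_loss(
                p_fake, np.zeros((nb, 1))
            )
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()
            # generator step: maximize log D(G(z))
            noise = rng.normal(size=(nb, config.noise_dim))
            probs = gen.forward(noise)
            p = disc.forward(probs)
            g_loss = -((p * (1.0 - 2e-7) + 1e-7).log()).mean()
            opt_g.zero_grad()
            g_loss.backward()
            opt_g.step()
            d_losses.append(float(d_loss.data))
            g_losses.append(float(g_loss.data))
        gl, dl = float(np.mean(g_losses)), float(np.mean(d_losses))
        if not (np.isfinite(gl) and np.isfinite(dl)):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: gen={gl}, disc={dl}; "
                "lower the learning rates or reduce the batch size"
            )
        log_rows.append({"epoch": epoch, "gen_loss": gl, "disc_loss": dl})
    return TrainedGenerator(generator=gen, config=config,
                            training_log=pd.DataFrame(log_rows))


def sample_sequences(
    trained: TrainedGenerator, n: int, seed: int = 0, method: str = "argmax",
    temperature: float = 1.0,
) -> list[str]:
    """Draw n discrete sequences from the generator.

    ``argmax`` (default) takes the most probable base per position;
    ``sample`` draws from the (temperature-scaled) probability rows.
    Identical seeds give identical output lists.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    batch = 256
    for s in range(0, n, batch):
        nb = min(batch, n - s)
        noise = rng.normal(size=(nb, trained.config.noise_dim))
        probs = trained.probabilities(noise)
        if method == "argmax":
            idx = probs.argmax(axis=2)
        elif method == "sample":
            logits = np.log(probs + 1e-12) / temperature
            p = np.exp(logits - logits.max(axis=2, keepdims=True))
            p /= p.sum(axis=2, keepdims=True)
            u = rng.random(p.shape[:2])[..., None]
            idx = (p.cumsum(axis=2) < u).sum(axis=2)
        else:
            raise ValueError(f"unknown emission method {method!r}")
        out.extend("".join(BASES[j] for j in row) for row in idx)
    return out


def corpus_screening_targets(corpus: list[PromoterRecord]) -> tuple[float, float]:
    """Default screening targets: corpus means of GC fraction and Moran's I.

    Sequences whose Moran series is constant are skipped for the Moran mean.
    """
    gcs, morans = [], []
    for rec in corpus:
        gcs.append(gc_content(rec.sequence) / 100.0)
        try:
            morans.append(dinucleotide_moran(rec.sequence).I)
        except ZeroVarianceError:
            pass
    if not morans:
        raise ValueError("Moran's I undefined for every corpus sequence")
    return float(np.mean(gcs)), float(np.mean(morans))


def screen_sequences(
    candidates: list[str], criteria: ScreeningCriteria
) -> tuple[list[str], pd.DataFrame]:
    """Filter candidates by the GC and Moran tolerance windows.

    Returns the accepted sequences (input order) and a per-candidate
    report with measured values, acceptance flag and rejection reason
    (``gc``, ``moran``, ``moran_undefined``, or ``""``).  Rejection is a
    reported outcome, never an error.
    """
    rows, accepted = [], []
    for i, seq in enumerate(candidates):
        gc = gc_content(seq) / 100.0
        reason = ""
        moran: float | None
        try:
            moran = dinucleotide_moran(seq).I
        except ZeroVarianceError:
            moran = None
            reason = "moran_undefined"
        if reason == "":
            if abs(gc - criteria.target_gc) > criteria.gc_tolerance:
                reason = "gc"
            elif abs(moran - criteria.target_moran) > criteria.moran_tolerance:
                reason = "moran"
        ok = reason == ""
        if ok:
            accepted.append(seq)
        rows.append({"index": i, "sequence": seq, "gc": gc,
                     "moran": np.nan if moran is None else moran,
                     "accepted": ok, "reason": reason})
    return accepted, pd.DataFrame(rows)


def generate_and_screen(
    trained: TrainedGenerator, n: int, criteria: ScreeningCriteria, seed: int = 0,
    max_batches: int = 100, batch: int = 200, method: str = "argmax",
) -> tuple[list[str], pd.DataFrame]:
    """Sample batches and screen until n accepted sequences (or give up).

    Every emitted sequence satisfies both tolerance windows by
    construction; raises if the acceptance rate is too low to reach n
    within ``max_batches`` batches.
    """
    accepted: list[str] = []
    reports = []
    for b in range(max_batches):
        cands = sample_sequences(trained, batch, seed=seed + b, method=method)
        acc, rep = screen_sequences(cands, criteria)
        rep.insert(0, "batch", b)
        reports.append(rep)
        accepted.extend(acc)
        if len(accepted) >= n:
            return accepted[:n], pd.concat(reports, ignore_index=True)
    raise RuntimeError(
        f"only {len(accepted)}/{n} candidates passed screening after "
        f"{max_batches} batches; widen the tolerances or retrain"
    )
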