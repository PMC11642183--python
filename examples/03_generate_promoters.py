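"""Design promoter-like sequences adversarially and screen them.

A recurrent generator/discriminator pair trains on a synthetic corpus;
candidates sampled from the generator are kept only if their GC content
and dinucleotide Moran's I fall within tolerance windows around the
corpus means — the screen that keeps generated sequences biologically
plausible.
"""

from promdesign.gan import (
    GeneratorConfig,
    ScreeningCriteria,
    corpus_screening_targets,
    generate_and_screen,
    train_gan,
)
from promdesign.synthetic_data import SyntheticSpec, generate_corpus

corpus = generate_corpus(SyntheticSpec(n=200, seed=0))
config = GeneratorConfig(length=50, epochs=5, seed=0)
trained = train_gan(corpus, config)
print(trained.training_log.to_string(index=False))

gc_t, moran_t = corpus_screening_targets(corpus)
criteria = ScreeningCriteria(target_gc=gc_t, target_moran=moran_t,
                             gc_tolerance=0.05, moran_tolerance=0.1)
accepted, report = generate_and_screen(trained, 20, criteria, seed=1, method="sample")
print(f"\nscreen targets: GC={gc_t:.3f} +/- 0.05, Moran={moran_t:+.3f} +/- 0.1")
print(f"acceptance rate: {report['accepted'].mean():.1%} of {len(report)} candidates")
print("first three accepted sequences:")
for seq in accepted[:3]:
    print(" ", seq)
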