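"""Mechanistic interpretation from repeated probe runs.

Runs five independent optimizations (identical but for the seed) on one
split and classifies every active token by the stability of its weight
sign: uniformly positive -> promoter of activity (class 1), uniformly
negative -> promoter of inactivity (class 2), mixed -> unclear.
"""

from semicorr import (
    MonteCarloConfig,
    classify_features,
    generate,
    make_split,
    planted_demo_config,
    probe_runs,
    roles_frame,
)
from semicorr.tokenizer import count_frequencies, tokenize

corpus = generate(planted_demo_config(2000, seed=5))
split = make_split(corpus, seed=6, split_id=1)
tables = probe_runs(split, MonteCarloConfig(T=1, N=15, seed=7, target="tf1"), 5)
freqs = {
    label: count_frequencies((tokenize(r.smiles) for r in split.subsets[label]), label)
    for label in ("active_training", "passive_training", "calibration")
}
df = roles_frame(classify_features(tables, freqs))

print(df.round(3).to_string(index=False))
print()
print("Br (the planted promoter) keeps a positive weight in all five probes,")
print("n (the planted suppressor) a negative one; tokens whose sign flips")
print("between probes are left 'unclear' — no mechanistic claim is made.")
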