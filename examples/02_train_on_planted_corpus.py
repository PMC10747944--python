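"""Monte Carlo training on a synthetic corpus with a known planted signal.

Generates 2000 molecules in which bromine (Br) raises and aromatic nitrogen
(n) lowers a noise-free latent activity score, splits them into the four
subsets, optimizes correlation weights against TF1 (the IIC-augmented
target), and evaluates on the untouched validation set.
"""

from semicorr import (
    MonteCarloConfig,
    evaluate_on,
    generate,
    make_split,
    optimize,
    planted_demo_config,
)

corpus = generate(planted_demo_config(2000, seed=11))
split = make_split(corpus, seed=21, split_id=1)
model, trace = optimize(split, MonteCarloConfig(T=1, N=15, seed=31, target="tf1"))

print("epoch   TF1     rAT     rPT     IIC   accepted")
for rec in trace.records:
    print(f"{rec.epoch:5d} {rec.tf:7.4f} {rec.r_at:7.4f} {rec.r_pt:7.4f} "
          f"{rec.iic:7.4f} {rec.accepted:6d}")

print()
print(f"weight of planted promoter  Br : {model.weights.cw['Br']:+.4f}")
print(f"weight of planted suppressor n : {model.weights.cw['n']:+.4f}")
block = evaluate_on(model, split.validation)
print(f"validation: sens={block.sens:.4f} spec={block.spec:.4f} "
      f"acc={block.acc:.4f} MCC={block.mcc:.4f}")
print()
print("The accepted target value rises monotonically; the planted tokens get")
print("weights of the planted signs and the held-out MCC approaches 1.")
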