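"""How many normal samples does the panel of normals need?

Sweeps the PoN size on a simulated dilution-series truth set and prints
the expected fraction of true variants the Fisher filter removes at each
size.  The curve drops steeply at first and plateaus around 8 samples —
beyond that, extra normals barely change the outcome.
"""

from chpipe.evaluate import pon_sweep_experiment

sweep = pon_sweep_experiment(seed=0, sizes=(1, 2, 4, 8, 12, 16, 20, 27))
print(sweep[["size", "proportion_removed", "n_subsets"]].round(4).to_string(index=False))
r = dict(zip(sweep["size"], sweep.proportion_removed))
print(f"\nrelative change 8 -> 27: {abs(r[8] - r[27]) / r[27]:.1%}")
print(f"relative change 1 -> 27: {abs(r[1] - r[27]) / r[27]:.1%}")
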