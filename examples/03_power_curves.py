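"""Reduced-scale versions of the two power sweeps.

Set 1 sweeps the treatment effect size on the 8-blastocyst design; Set 2
sweeps the number of blastocysts at a fixed effect size of 2 (d = 0.2).
The full study scale is 100 batches x 100 genes per setting (run it via
the CLI: `simulate-power set1 --out results/set1`); here we use 5 x 20 to
finish in about a minute.
"""

import blastopower as bp

set1 = bp.run_set1(effect_sizes=[1, 4, 7, 10], n_batches=5, batch_size=20, seed=1)
print("Set 1: power vs unstandardized effect size (8 blastocysts)")
print(set1.summary_frame().round(3).to_string(index=False))

set2 = bp.run_set2(blastocyst_counts=[8, 48, 96], n_batches=5, batch_size=20, seed=1)
print("\nSet 2: power vs blastocyst count (effect size 2, d = 0.2)")
print(set2.summary_frame().round(3).to_string(index=False))

# Reading: at the real study's size (8 blastocysts), only unusually strong
# effects (d near 1) are detectable; at a realistic d = 0.2 you need
# hundreds of blastocysts before power approaches conventional levels.
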