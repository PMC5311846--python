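"""Build and inspect the experimental designs all simulations share.

The balanced reference design has 8 blastocysts (2 per treatment), each
contributing one cell of each of the four blastocyst lineages.
"""

import numpy as np

import blastopower as bp

design = bp.build_balanced_design(8)
diag = bp.validate_design(design)
print(design.head(8).to_string(index=False))
print(f"\n{diag.n_samples} samples, {diag.n_blastocysts} blastocysts, "
      f"violations: {diag.violations or 'none'}")
print("samples per treatment:", diag.samples_per_treatment)

# An unbalanced design like the real study: 10 blastocysts, 1-11 cells each.
unb = bp.hyslop_like_unbalanced_design(np.random.default_rng(0))
sizes = unb.groupby("blastocyst_id", observed=True).size()
print("\nunbalanced preset cells/blastocyst:", sizes.tolist())
# Treatment is constant within blastocyst in every design - the blastocyst,
# not the cell, is the unit of replication.
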