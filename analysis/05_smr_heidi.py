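#!/usr/bin/env python
"""Summary-data Mendelian randomization with the top cis eQTL as instrument,
plus the HEIDI linkage test; SMR support = P_FDR < 0.05 and P_HEIDI > 0.05."""

from common import parse_args
from stratwas.pipeline import stage_smr

args = parse_args(__doc__)
out = stage_smr(args.workdir, seed=args.seed)
supported = int(out.support.sum()) if len(out) else 0
print(f"{supported}/{len(out)} pairs with SMR support")
for _, r in out.iterrows():
    heidi = "missing" if not (r.p_heidi == r.p_heidi) else f"{r.p_heidi:.3f}"
    print(f"  {r.gene} ({r.cell_type}, {r.stratum}): b_xy = {r.b_xy:+.3f}, "
          f"p_SMR(FDR) = {r.p_smr_fdr:.2e}, p_HEIDI = {heidi} -> "
          f"{'support' if r.support else 'no support'}")
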