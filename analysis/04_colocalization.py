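#!/usr/bin/env python
"""ABF colocalization of each retained pair's stratum GWAS against its
cell-type eQTL signal, under default and adjusted priors; best PP4 tiering
at 0.4 (suggestive) / 0.7 (strong)."""

from common import parse_args
from stratwas.pipeline import stage_coloc

args = parse_args(__doc__)
out = stage_coloc(args.workdir)
print(f"{len(out)} pairs colocalized")
for tier in ("strong", "suggestive", "none"):
    sub = out[out.tier == tier]
    print(f"  {tier}: {len(sub)}")
for _, r in out.iterrows():
    print(f"  {r.gene} ({r.cell_type}, {r.stratum}): best PP4 = {r.pp4_best:.3f} "
          f"[{r.tier}], top variant {r.top_variant}")
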