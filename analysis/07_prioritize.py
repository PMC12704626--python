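#!/usr/bin/env python
"""Gene prioritization: cross-ancestry consistency, LD-proxy peak overlap,
then assembly of the six evidence layers into support tiers (>=3 of 6 at
least half, >=4 more than half), druggable intersection and network
expansion per stratum."""

from common import parse_args
from stratwas.pipeline import stage_cross_ancestry, stage_overlap, stage_prioritize

args = parse_args(__doc__)
xanc = stage_cross_ancestry(args.workdir)
print(f"{int(xanc.consistent.sum())}/{len(xanc)} pairs cross-ancestry consistent")
ov = stage_overlap(args.workdir)
print(f"{int(ov.overlap.sum())}/{len(ov)} pairs with matching-cell-type peak overlap")
prof = stage_prioritize(args.workdir)
layers = ["cross_ancestry", "coloc", "smr", "atac", "deg_nonstratified", "deg_stratified"]
print(f"{(prof.tier != 'none').sum()}/{len(prof)} pairs supported by >= half the layers")
for _, r in prof.iterrows():
    hit = ",".join(l for l in layers if r[l])
    print(f"  {r.gene} ({r.cell_type}, {r.stratum}): {r.support_count}/6 [{r.tier}] ({hit})")
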