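#!/usr/bin/env python
"""Stratified cell-type TWAS: combine the expression weights with each
stratum's GWAS z-scores under the reference LD. Writes results/run/ctwas.tsv."""

from common import parse_args
from stratwas.pipeline import stage_ctwas

args = parse_args(__doc__)
table = stage_ctwas(args.workdir)
print(f"{len(table)} (gene, cell type) pairs tested in both strata")
for s in ("carrier", "non-carrier"):
    top = table.sort_values(f"p_{s}").head(3)
    print(f"top {s} associations:")
    for _, r in top.iterrows():
        print(f"  {r.gene} ({r.cell_type}): z = {r[f'z_{s}']:+.2f}, p = {r[f'p_{s}']:.2e}")
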