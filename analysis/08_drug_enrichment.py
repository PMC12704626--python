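#!/usr/bin/env python
"""Compound/drug gene-set enrichment of the expanded prioritized gene lists
per stratum (hypergeometric, BH FDR < 0.05, >=2 prioritized target genes)."""

import pandas as pd

from common import parse_args
from stratwas import io as sio

args = parse_args(__doc__)
for tag in ("carrier", "noncarrier"):
    seeds = sio.read_gene_list(args.workdir / f"prioritized_{tag}.txt")
    tier1 = sio.read_gene_list(args.workdir / f"druggable_tier1_{tag}.txt")
    enr = pd.read_csv(args.workdir / f"enrichment_{tag}.tsv", sep="\t")
    sig = enr[enr.significant]
    print(f"{tag}: {len(seeds)} prioritized genes, {len(tier1)} tier-1 druggable, "
          f"{len(sig)} enriched compounds")
    for _, r in sig.iterrows():
        print(f"  {r.compound}: {r.k}/{r.K} targets in query (q = {r.q:.2e}), "
              f"genes: {r.overlap}")
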