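#!/usr/bin/env python
"""TMM-normalized pseudobulk differential expression against AD status and
global pathology, in non-stratified and APOE*4-stratified scopes."""

import pandas as pd

from common import parse_args
from stratwas.pipeline import stage_deg

args = parse_args(__doc__)
out = stage_deg(args.workdir)
print(f"{len(out)} gene-level fits "
      f"({out.cell_type.nunique()} cell types x {out.scope.nunique()} scopes "
      f"x {out.phenotype.nunique()} phenotypes)")
for scope in ("nonstratified", "carrier", "non-carrier"):
    sub = out[out.scope == scope]
    print(f"  {scope}: {(sub.p < 0.05).sum()} fits at p < 0.05 of {len(sub)}")
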