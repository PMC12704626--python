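"""Evidence integration, druggable-gene intersection, network expansion and
compound gene-set enrichment.

Six evidence layers per (cell type, gene) pair — cross-ancestry consistency,
colocalization (tier >= suggestive), SMR support, open-chromatin overlap,
non-stratified DEG, stratified DEG — feed a support count with tiers
"at_least_half" (>=3 of 6) and "more_than_half" (>=4 of 6). Prioritized
genes are intersected with the druggable genome, expanded one hop through a
gene-gene interaction network (keeping druggable neighbours), and tested
for compound-set over-representation with a one-sided hypergeometric test,
BH correction, and the >=2-prioritized-genes robustness filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stratum_filter import bh_fdr

log = logging.getLogger(__name__)

LAYERS = ("cross_ancestry", "coloc", "smr", "atac", "deg_nonstratified", "deg_stratified")
TIER_HALF = 3
TIER_MORE_THAN_HALF = 4


@dataclass
class EvidenceProfile:
    gene: str
    cell_type: str
    stratum: str
    flags: dict = field(default_factory=dict)
    coloc_strong: bool = False

    def __post_init__(self):
        unknown = set(self.flags) - set(LAYERS)
        if unknown:
            raise ValueError(f"unknown evidence layers: {sorted(unknown)}")
        self.flags = {k: bool(self.flags.get(k, False)) for k in LAYERS}

    @property
    def support_count(self) -> int:
        return sum(self.flags.values())

    @property
    def tier(self) -> str:
        c = self.support_count
        if c >= TIER_MORE_THAN_HALF:
            return "more_than_half"
        if c >= TIER_HALF:
            return "at_least_half"
        return "none"


def evidence_profile(gene: str, cell_type: str, stratum: str, *,
                     cross_ancestry: bool = False, coloc_tier: str = "none",
                     smr: bool = False, atac: bool = False,
                     deg_nonstratified: bool = False,
                     deg_stratified: bool = False) -> EvidenceProfile:
    """Assemble the six-layer profile; a layer not attempted counts false."""
    return EvidenceProfile(
        gene=gene, cell_type=cell_type, stratum=stratum,
        flags={
            "cross_ancestry": cross_ancestry,
            "coloc": coloc_tier in ("suggestive", "strong"),
            "smr": smr,
            "atac": atac,
            "deg_nonstratified": deg_nonstratified,
            "deg_stratified": deg_stratified,
        },
        coloc_strong=coloc_tier == "strong",
    )


def profiles_to_frame(profiles: list[EvidenceProfile]) -> pd.DataFrame:
    rows = []
    for pr in profiles:
        row = {"gene": pr.gene, "cell_type": pr.cell_type, "stratum": pr.stratum}
        row.update(pr.flags)
        row["coloc_strong"] = pr.coloc_strong
        row["support_count"] = pr.support_count
        row["tier"] = pr.tier
        rows.append(row)
    return pd.DataFrame(rows)


def druggable_intersect(genes: list[str], druggable: list[str]) -> list[str]:
    """Case-insensitive intersection with the druggable-gene list."""
    if not druggable:
        raise ValueError("druggable list is empty")
    dset = {g.upper() for g in druggable}
    return [g for g in genes if g.upper() in dset]


def network_expand(seeds: list[str], edges: pd.DataFrame, druggable: list[str]) -> list[str]:
    """Seeds plus their druggable first-degree interaction neighbours.

    Seeds are retained regardless of druggability; a seed absent from the
    network contributes no neighbours (logged).
    """
    dset = {g.upper() for g in druggable}
    adjacency: dict[str, set[str]] = {}
    for _, e in edges.iterrows():
        adjacency.setdefault(e.gene_a.upper(), set()).add(e.gene_b)
        adjacency.setdefault(e.gene_b.upper(), set()).add(e.gene_a)
    out = list(dict.fromkeys(seeds))
    seen = {g.upper() for g in out}
    for s in seeds:
        nbrs = adjacency.get(s.upper())
        if nbrs is None:
            log.info("seed %s absent from network (zero neighbours)", s)
            continue
        for n in sorted(nbrs):
            if n.upper() in dset and n.upper() not in seen:
                out.append(n)
                seen.add(n.upper())
    return out


def drug_enrichment(query: list[str], gene_sets: dict[str, list[str]],
                    universe: list[str], *, min_overlap: int = 2,
                    prioritized: list[str] | None = None,
                    fdr_level: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of the query in each compound set.

    Each set is intersected with the universe; p = P(X >= k) for overlap k,
    set size K, query size n, universe size N. BH across all tested sets;
    the ``significant`` column marks q < 0.05 AND overlap with the
    ``prioritized`` genes (default: the query itself) >= min_overlap. The
    full unfiltered table is returned.
    """
    uni = {g.upper() for g in universe}
    qset = {g.upper() for g in query} & uni
    if not qset:
        log.warning("empty query after universe intersection")
        return pd.DataFrame(columns=["compound", "k", "K", "n", "N", "p", "q",
                                     "overlap", "k_prioritized", "significant"])
    pset = {g.upper() for g in (prioritized if prioritized is not None else query)} & uni
    N, n = len(uni), len(qset)
    rows = []
    for name, members in gene_sets.items():
        mset = {g.upper() for g in members} & uni
        K = len(mset)
        overlap = sorted(mset & qset)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"compound": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0),
                     "overlap": ",".join(overlap),
                     "k_prioritized": len(mset & pset)})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = (out.q < fdr_level) & (out.k_prioritized >= min_overlap)
    return out.sort_values("p").reset_index(drop=True)
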