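"""LD-proxy expansion of top colocalizing variants and overlap with
cell-type open-chromatin peaks.

Peaks follow BED convention (0-based half-open intervals, column 4 = cell
type label); variant positions are 1-based, so a variant at position p hits
a peak [start, end) iff start < p <= end.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

R2_PROXY = 0.8


def ld_proxies(index_variant: str, ld: pd.DataFrame, r2_min: float = R2_PROXY) -> list[str]:
    """Variants whose r^2 with the index exceeds ``r2_min`` (index included).

    ``ld`` is a correlation matrix indexed by variant id (as computed from
    genotype Pearson correlations in a reference panel).
    """
    if index_variant not in ld.index:
        raise KeyError(f"index variant {index_variant} absent from LD panel")
    r = ld.loc[index_variant]
    if not np.isfinite(r[index_variant]) or r[index_variant] == 0:
        raise ValueError(f"index variant {index_variant} monomorphic in panel")
    r2 = r ** 2
    proxies = list(r2.index[(r2 > r2_min) | (r2.index == index_variant)])
    if index_variant not in proxies:
        proxies.append(index_variant)
    return proxies


def ld_proxies_from_panel(index_variant: str, genotypes: np.ndarray,
                          variant_ids: list[str], r2_min: float = R2_PROXY) -> list[str]:
    """Proxy set computed directly from a genotype reference panel."""
    G = np.asarray(genotypes, dtype=float)
    idx = variant_ids.index(index_variant)
    if G[:, idx].std() < 1e-12:
        raise ValueError(f"index variant {index_variant} monomorphic in panel")
    sd = G.std(axis=0)
    ok = sd > 1e-12
    r = np.zeros(G.shape[1])
    Gc = G - G.mean(axis=0)
    r[ok] = (Gc[:, ok].T @ Gc[:, idx]) / (len(G) * sd[ok] * sd[idx])
    r2 = r ** 2
    return [v for j, v in enumerate(variant_ids) if r2[j] > r2_min or j == idx]


def peak_overlap(variants: pd.DataFrame, peaks: pd.DataFrame,
                 cell_type: str) -> tuple[bool, pd.DataFrame]:
    """Whether any variant falls inside a peak of the matching cell type.

    ``variants``: frame with chrom and pos (1-based); ``peaks``: BED-like
    frame with chrom, start, end (0-based half-open) and name = cell-type
    label. Returns (hit, frame of variant/peak hit pairs).
    """
    empty = pd.DataFrame(columns=["variant", "chrom", "pos", "start", "end"])
    if len(variants) == 0:
        return False, empty
    sub = peaks[peaks.name == cell_type]
    if sub.empty:
        log.warning("no peaks labelled %r", cell_type)
        return False, empty
    hits = []
    for _, v in variants.iterrows():
        p0 = v.pos - 1  # convert to 0-based
        m = sub[(sub.chrom == v.chrom) & (sub.start <= p0) & (p0 < sub.end)]
        for _, pk in m.iterrows():
            hits.append((v.get("variant", f"{v.chrom}:{v.pos}"), v.chrom, v.pos,
                         pk.start, pk.end))
    out = pd.DataFrame(hits, columns=empty.columns)
    return len(out) > 0, out
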