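"""Multiple-testing correction, the APOE*4 heterogeneity criteria, locus
clustering with the locus-level exclusion rule, and the cross-ancestry
consistency check.

A (cell type, gene) pair is "biased" to a stratum when it reaches FDR < 0.05
there while the other stratum is either non-significant with the same effect
direction or shows an opposite effect direction. Loci are single-linkage
clusters of significant genes' TSS at 1 Mb reach; if a locus's most
significant gene is not biased to a stratum, every gene at the locus is
excluded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .assoc import meta_stouffer
from .simulate import STRATA

log = logging.getLogger(__name__)

FDR_LEVEL = 0.05
OTHER_P = 0.05
LOCUS_REACH = 1_000_000  # bp, TSS-to-TSS single linkage


def bh_fdr(p: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs propagate)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _other(stratum: str) -> str:
    return STRATA[1] if stratum == STRATA[0] else STRATA[0]


def heterogeneity_flag(q_s: float, z_s: float, p_other: float, z_other: float,
                       fdr_level: float = FDR_LEVEL, other_p: float = OTHER_P) -> bool:
    """Stratum-bias criterion for one pair in stratum s.

    True iff q_s < 0.05 and either the other stratum is non-significant
    (p > 0.05) with the same effect direction, or the other stratum's effect
    direction is opposite. z_other == 0 counts as same-direction.
    """
    if not np.isfinite(q_s) or not np.isfinite(z_s):
        return False
    if not np.isfinite(p_other) or not np.isfinite(z_other):
        log.info("missing other-stratum result: heterogeneity flag set false")
        return False
    if q_s >= fdr_level:
        return False
    same_sign = bool(np.sign(z_s) == np.sign(z_other)) or z_other == 0
    return bool((p_other > other_p and same_sign) or not same_sign)


def annotate_heterogeneity(pairs: pd.DataFrame, fdr_level: float = FDR_LEVEL) -> pd.DataFrame:
    """Add q-values (pooled across all pairs, per stratum) and per-stratum
    heterogeneity flags; ``heterogeneity_stratum`` is the biased stratum or
    'none'."""
    out = pairs.copy()
    for s in STRATA:
        out[f"q_{s}"] = bh_fdr(out[f"p_{s}"].to_numpy())
    flags = {s: [] for s in STRATA}
    for _, row in out.iterrows():
        for s in STRATA:
            o = _other(s)
            flags[s].append(heterogeneity_flag(row[f"q_{s}"], row[f"z_{s}"],
                                               row[f"p_{o}"], row[f"z_{o}"],
                                               fdr_level=fdr_level))
    for s in STRATA:
        out[f"flag_{s}"] = flags[s]
    out["heterogeneity_stratum"] = np.select(
        [out[f"flag_{STRATA[0]}"], out[f"flag_{STRATA[1]}"]], list(STRATA), default="none")
    return out


def cluster_loci(pairs: pd.DataFrame, reach: int = LOCUS_REACH) -> pd.Series:
    """Single-linkage locus ids from TSS positions (per chromosome).

    On a line, single linkage at ``reach`` is chaining: sorted TSS join one
    cluster while consecutive gaps are <= reach. Returns a locus_id Series
    aligned to ``pairs``.
    """
    locus_id = pd.Series(index=pairs.index, dtype=object)
    counter = 0
    for chrom, sub in pairs.groupby("chrom"):
        order = sub.sort_values("tss")
        current = None
        last_tss = None
        for idx, row in order.iterrows():
            if current is None or row.tss - last_tss > reach:
                current = f"locus_{counter:03d}"
                counter += 1
            locus_id.loc[idx] = current
            last_tss = row.tss
    return locus_id


def locus_exclusion(pairs: pd.DataFrame) -> pd.DataFrame:
    """Apply the locus-level exclusion rule to heterogeneity-annotated pairs.

    Input must carry p_/q_/flag_ columns (from :func:`annotate_heterogeneity`)
    and a ``locus_id``. Only pairs significant (q < 0.05) in some stratum are
    considered. Per locus: the top pair is the one with smallest p over both
    strata (ties by smaller q, then gene id); if the top pair is not flagged
    in its best-p stratum, all members are dropped; otherwise members that
    individually carry a flag are retained.
    """
    sig = pairs[(pairs[[f"q_{s}" for s in STRATA]] < FDR_LEVEL).any(axis=1)].copy()
    if sig.empty:
        return sig
    p_cols = [f"p_{s}" for s in STRATA]
    sig["_pmin"] = sig[p_cols].min(axis=1)
    sig["_best_stratum"] = sig[p_cols].idxmin(axis=1).str.replace("p_", "", regex=False)
    sig["_qmin"] = sig[[f"q_{s}" for s in STRATA]].min(axis=1)
    kept = []
    for locus, grp in sig.groupby("locus_id"):
        order = grp.sort_values(["_pmin", "_qmin", "gene"])
        if len(order) > 1 and np.isclose(order._pmin.iloc[0], order._pmin.iloc[1]):
            log.info("locus %s: top-p tie broken by q then gene id", locus)
        top = order.iloc[0]
        if not top[f"flag_{top._best_stratum}"]:
            log.info("locus %s: top gene %s unflagged, excluding all %d members",
                     locus, top.gene, len(grp))
            continue
        kept.append(grp[grp.heterogeneity_stratum != "none"])
    if not kept:
        return sig.iloc[0:0].drop(columns=["_pmin", "_best_stratum", "_qmin"])
    out = pd.concat(kept).drop(columns=["_pmin", "_best_stratum", "_qmin"])
    return out.sort_index()


def cross_ancestry_consistent(z_primary: dict[str, float], p_primary: dict[str, float],
                              z_secondary: dict[str, float], n_eff: dict[str, dict[str, float]],
                              stratum: str) -> bool:
    """Cross-ancestry consistency for a pair biased to ``stratum``.

    Stouffer-combines primary and secondary z per stratum with effective
    sample sizes; True iff the meta p in the respective stratum is strictly
    smaller than the primary p while the opposite stratum's meta p stays
    above 0.05. Missing secondary results give False.
    """
    other = _other(stratum)
    for s in (stratum, other):
        if s not in z_secondary or not np.isfinite(z_secondary[s]):
            log.info("missing secondary-ancestry result for %s: inconsistent", s)
            return False
    meta = {}
    for s in (stratum, other):
        Z, p = meta_stouffer([z_primary[s], z_secondary[s]],
                             [n_eff[s]["primary"], n_eff[s]["secondary"]])
        meta[s] = p
    return meta[stratum] < p_primary[stratum] and meta[other] > OTHER_P
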