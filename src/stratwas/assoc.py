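"""Per-stratum association testing, variant filtering and meta-analysis.

The GWAS kernel is a batched Newton (IRLS) logistic maximum-likelihood
solver: every variant shares the covariate block, so all per-variant models
are iterated simultaneously with stacked (k x k) normal equations. Wald z
and two-sided normal p-values are reported; monomorphic or non-converged
variants are flagged and their p set missing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


# ---------------------------------------------------------------------------
# logistic GWAS

def _batched_logistic(y: np.ndarray, G: np.ndarray, C: np.ndarray,
                      max_iter: int = 30, tol: float = 1e-8):
    """Fit logit(y) ~ g_v + C for every column g_v of G at once.

    Returns (beta, se, converged) for the genotype coefficient of each
    variant. C must already contain an intercept column.
    """
    n, V = G.shape
    k = C.shape[1] + 1
    # design per variant: [g_v, C]; parameters theta[v] of length k
    theta = np.zeros((V, k))
    converged = np.zeros(V, dtype=bool)
    active = np.ones(V, dtype=bool)
    XtX = np.empty((V, k, k))
    Xty = np.empty((V, k))
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Ga = G[:, idx]
        eta = Ga * theta[idx, 0] + C @ theta[idx, 1:].T  # n x |idx|
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        resid = y[:, None] - mu
        # score
        Xty[idx, 0] = np.einsum("nv,nv->v", Ga, resid)
        Xty[idx, 1:] = (C.T @ resid).T
        # information
        XtX[idx, 0, 0] = np.einsum("nv,nv->v", Ga * w, Ga)
        gc = (Ga * w).T @ C  # |idx| x (k-1)
        XtX[idx, 0, 1:] = gc
        XtX[idx, 1:, 0] = gc
        XtX[idx, 1:, 1:] = np.einsum("nv,ni,nj->vij", w, C, C)
        try:
            step = np.linalg.solve(XtX[idx], Xty[idx][..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.array([np.linalg.lstsq(XtX[i], Xty[i], rcond=None)[0] for i in idx])
        theta[idx] += step
        done = np.abs(step).max(axis=1) < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    se = np.full(V, np.nan)
    ok = np.flatnonzero(converged)
    if ok.size:
        try:
            inv = np.linalg.inv(XtX[ok])
            se[ok] = np.sqrt(inv[:, 0, 0])
        except np.linalg.LinAlgError:
            for i in ok:
                se[i] = np.sqrt(np.linalg.pinv(XtX[i])[0, 0])
    return theta[:, 0], se, converged


def run_stratified_gwas(genotypes: np.ndarray, labels: np.ndarray,
                        covariates: pd.DataFrame | np.ndarray,
                        variants: pd.DataFrame, *, n_cases: int | None = None,
                        n_controls: int | None = None,
                        is_proxy: bool = False) -> pd.DataFrame:
    """Per-variant logistic regression of disease on dosage + covariates.

    Returns a summary-statistics frame (one stratum) with columns
    variant, chrom, pos, a1, a2, freq, beta, se, z, p, n_cases, n_controls,
    genotyping_rate, is_proxy. Monomorphic variants are excluded up front;
    non-converged fits keep their row with missing beta/se/p.
    """
    y = np.asarray(labels, dtype=float)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 cases and 2 controls per stratum")
    G = np.asarray(genotypes, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        C = covariates.to_numpy(dtype=float)
    else:
        C = np.asarray(covariates, dtype=float)
    # drop constant covariate columns, add intercept
    keep = C.std(axis=0) > 1e-12
    C = np.column_stack([np.ones(len(y)), C[:, keep]])

    sd = G.std(axis=0)
    poly = sd > 1e-12
    n_mono = int((~poly).sum())
    if n_mono:
        log.info("excluding %d monomorphic variants", n_mono)
    beta = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    conv = np.zeros(G.shape[1], dtype=bool)
    if poly.any():
        b, s, c = _batched_logistic(y, G[:, poly], C)
        bad = c & ~np.isfinite(s)
        c &= np.isfinite(s)
        if bad.any():
            log.warning("%d variants with singular information dropped", int(bad.sum()))
        beta[poly], se[poly], conv[poly] = b, s, c
    z = np.where(conv, beta / se, np.nan)
    p = np.where(conv, 2.0 * stats.norm.sf(np.abs(z)), np.nan)
    out = variants[["variant", "chrom", "pos", "a1", "a2"]].copy()
    out["freq"] = G.mean(axis=0) / 2.0
    out["beta"], out["se"], out["z"], out["p"] = beta, se, z, p
    out["n_cases"] = n_cases if n_cases is not None else int((y == 1).sum())
    out["n_controls"] = n_controls if n_controls is not None else int((y == 0).sum())
    out["genotyping_rate"] = 1.0 - np.isnan(np.asarray(genotypes, dtype=float)).mean(axis=0)
    out["is_proxy"] = is_proxy
    out["monomorphic"] = ~poly
    return out[~out.monomorphic].drop(columns="monomorphic").reset_index(drop=True)


# ---------------------------------------------------------------------------
# effective sample size

def effective_n(n_cases: float, n_controls: float, is_proxy: bool = False) -> float:
    """Effective sample size 4·N·v·(1−v), v = cases/(cases+controls).

    Proxy-phenotype cohorts (family-history GWAS) are down-weighted by a
    further factor of 4. Maximised (N_eff = N) at a balanced design.
    """
    total = n_cases + n_controls
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("n_cases and n_controls must be positive")
    v = n_cases / total
    neff = 4.0 * total * v * (1.0 - v)
    return neff / 4.0 if is_proxy else neff


# ---------------------------------------------------------------------------
# harmonization + filtering

def harmonize(stats_df: pd.DataFrame, anchor: pd.DataFrame) -> pd.DataFrame:
    """Align allele orientation of ``stats_df`` to the anchor table.

    Matching on (a1, a2) keeps the row; matching on swapped alleles flips
    beta/z sign and freq; strand-ambiguous A/T, C/G palindromes and
    irreconcilable allele pairs are dropped (counted in the log). Duplicate
    variant keys keep the first occurrence.
    """
    a = anchor.drop_duplicates("variant").set_index("variant")
    df = stats_df.drop_duplicates("variant", keep="first").copy()
    dup = len(stats_df) - len(df)
    if dup:
        log.warning("%d duplicate variant keys, kept first occurrence", dup)
    keep, flip = [], []
    dropped = 0
    for _, row in df.iterrows():
        if row.variant not in a.index:
            keep.append(False); flip.append(False)
            continue
        if (row.a1, row.a2) in PALINDROMIC:
            dropped += 1
            keep.append(False); flip.append(False)
            continue
        ref = a.loc[row.variant]
        if (row.a1, row.a2) == (ref.a1, ref.a2):
            keep.append(True); flip.append(False)
        elif (row.a2, row.a1) == (ref.a1, ref.a2):
            keep.append(True); flip.append(True)
        else:
            dropped += 1
            keep.append(False); flip.append(False)
    if dropped:
        log.warning("%d variants dropped during harmonization", dropped)
    df = df[np.array(keep, dtype=bool)].copy()
    fl = np.array(flip, dtype=bool)[np.array(keep, dtype=bool)]
    for col in ("beta", "z"):
        if col in df:
            df.loc[fl, col] = -df.loc[fl, col]
    if "freq" in df:
        df.loc[fl, "freq"] = 1.0 - df.loc[fl, "freq"]
    if fl.any():
        sw = df.loc[fl, "a1"].copy()
        df.loc[fl, "a1"] = df.loc[fl, "a2"]
        df.loc[fl, "a2"] = sw
    return df.reset_index(drop=True)


def filter_variants(cohort_stats: list[pd.DataFrame], anchor_variants: set[str],
                    min_rate: float = 0.9) -> list[str]:
    """Variants present in the anchor set with genotyping rate >= min_rate
    in every cohort."""
    retained: set[str] | None = None
    for df in cohort_stats:
        ok = set(df.loc[df.genotyping_rate >= min_rate, "variant"])
        retained = ok if retained is None else (retained & ok)
    retained = (retained or set()) & set(anchor_variants)
    return sorted(retained)


# ---------------------------------------------------------------------------
# meta-analysis

def meta_fixed_effects(betas, ses):
    """Inverse-variance-weighted fixed-effects pooling.

    Returns (beta, se, z, p); cohorts with missing se are ignored; all
    missing -> all-NaN result.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    ok = np.isfinite(b) & np.isfinite(s) & (s > 0)
    if not ok.any():
        return np.nan, np.nan, np.nan, np.nan
    w = 1.0 / s[ok] ** 2
    beta = float(np.sum(w * b[ok]) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    return beta, se, z, float(2.0 * stats.norm.sf(abs(z)))


def meta_stouffer(zs, n_effs):
    """Sample-size-weighted z combination: Z = sum(sqrt(n_i) z_i)/sqrt(sum n_i)."""
    z = np.asarray(zs, dtype=float)
    n = np.asarray(n_effs, dtype=float)
    ok = np.isfinite(z) & np.isfinite(n) & (n > 0)
    if not ok.any() or n[ok].sum() <= 0:
        raise ValueError("meta_stouffer needs at least one cohort with positive n_eff")
    Z = float(np.sum(np.sqrt(n[ok]) * z[ok]) / np.sqrt(np.sum(n[ok])))
    return Z, float(2.0 * stats.norm.sf(abs(Z)))
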