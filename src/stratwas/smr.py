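"""Summary-data Mendelian randomization of expression on disease, the HEIDI
linkage test, and the SMR support rule.

SMR uses the top cis eQTL as an instrument: b_xy = b_GWAS / b_eQTL with the
chi-square(1) statistic T = z_GWAS^2 z_eQTL^2 / (z_GWAS^2 + z_eQTL^2). HEIDI
asks whether b_xy is homogeneous across nearby eQTL SNPs in intermediate LD
with the instrument — heterogeneity indicates the GWAS and eQTL hits are
distinct variants in linkage rather than one shared variant. The HEIDI
p-value is obtained by seeded Monte Carlo from the multivariate normal
implied by the delta-method covariance of the b_xy differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

#: eligibility defaults following the cited SMR tool's conventions
EQTL_P_MAX = 1.57e-3   # |z_eqtl| > 3.16
R2_LO = 0.05
R2_HI = 0.9
MAX_SNPS = 20
MC_DRAWS = 10_000


@dataclass
class SmrResult:
    top_variant: str
    b_xy: float
    t_smr: float
    p_smr: float
    p_heidi: float | None = None
    n_heidi_snps: int = 0
    p_smr_fdr: float = np.nan


def smr_test(z_gwas: float, z_eqtl: float, b_gwas: float, b_eqtl: float,
             top_variant: str = "") -> SmrResult | None:
    """Single-instrument SMR statistic and ratio estimate."""
    if z_gwas == 0 and z_eqtl == 0:
        return None
    if z_eqtl == 0 or b_eqtl == 0:
        raise ValueError("top eQTL must have nonzero effect")
    denom = z_gwas ** 2 + z_eqtl ** 2
    if denom == 0:  # squares can underflow to zero for denormal z
        return None
    t = (z_gwas ** 2 * z_eqtl ** 2) / denom
    p = float(stats.chi2.sf(t, df=1))
    return SmrResult(top_variant=top_variant, b_xy=b_gwas / b_eqtl,
                     t_smr=float(t), p_smr=p)


def heidi_test(b_gwas: np.ndarray, se_gwas: np.ndarray, b_eqtl: np.ndarray,
               se_eqtl: np.ndarray, R: np.ndarray, top: int, *,
               r2_lo: float = R2_LO, r2_hi: float = R2_HI, max_snps: int = MAX_SNPS,
               eqtl_p_max: float = EQTL_P_MAX, n_draws: int = MC_DRAWS,
               rng: np.random.Generator | None = None) -> tuple[float | None, int]:
    """HEIDI heterogeneity p-value for the instrument at index ``top``.

    Eligible SNPs have eQTL p < eqtl_p_max and r^2 with the top SNP inside
    [r2_lo, r2_hi]; the ``max_snps`` strongest eQTL signals are kept. With
    fewer than 3 eligible SNPs the p-value is missing (None). The statistic
    is the sum of squared standardized differences d_i = b_xy(i) - b_xy(top);
    its null distribution is simulated from MVN(0, corr(d)).
    """
    rng = rng or np.random.default_rng(0)
    b_g = np.asarray(b_gwas, float)
    s_g = np.asarray(se_gwas, float)
    b_e = np.asarray(b_eqtl, float)
    s_e = np.asarray(se_eqtl, float)
    R = np.asarray(R, float)
    m = b_g.size
    z_e = b_e / s_e
    p_e = 2 * stats.norm.sf(np.abs(z_e))
    r2 = R[top] ** 2
    eligible = np.flatnonzero((p_e < eqtl_p_max) & (r2 >= r2_lo) & (r2 <= r2_hi)
                              & (np.arange(m) != top))
    if eligible.size > max_snps:
        eligible = eligible[np.argsort(-np.abs(z_e[eligible]))[:max_snps]]
    if eligible.size < 3:
        log.info("HEIDI: only %d eligible SNPs (<3), p missing", eligible.size)
        return None, int(eligible.size)

    sel = np.concatenate([[top], eligible])
    bg, sg, be, se_ = b_g[sel], s_g[sel], b_e[sel], s_e[sel]
    Rs = R[np.ix_(sel, sel)]
    # delta-method covariance of b_xy across SNPs; GWAS and eQTL samples
    # independent, so the two trait terms add
    inv_be = 1.0 / be
    cov_xy = (np.outer(inv_be, inv_be) * Rs * np.outer(sg, sg)
              + np.outer(bg * inv_be ** 2, bg * inv_be ** 2) * Rs * np.outer(se_, se_))
    k = eligible.size
    # d_i = b_xy(i) - b_xy(top), i = 1..k
    A = np.zeros((k, k + 1))
    A[:, 0] = -1.0
    A[np.arange(k), np.arange(1, k + 1)] = 1.0
    cov_d = A @ cov_xy @ A.T
    sd_d = np.sqrt(np.diag(cov_d))
    d = (bg[1:] / be[1:]) - (bg[0] / be[0])
    z_d = d / sd_d
    T_obs = float(np.sum(z_d ** 2))
    corr = cov_d / np.outer(sd_d, sd_d)
    # guard against numerically singular correlation
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        log.warning("HEIDI: singular covariance, ridge-regularizing diagonal")
        L = np.linalg.cholesky(corr + 1e-8 * np.eye(k))
    draws = rng.standard_normal((n_draws, k)) @ L.T
    T_null = np.sum(draws ** 2, axis=1)
    p = float((1 + np.sum(T_null >= T_obs)) / (n_draws + 1))
    return p, int(k)


def smr_support(p_smr_fdr: float, p_heidi: float | None,
                allow_missing_heidi: bool = False) -> bool:
    """Support rule: P_FDR < 0.05 and P_HEIDI > 0.05 (missing HEIDI counts
    as support only under the configurable waiver, default off)."""
    if not np.isfinite(p_smr_fdr) or p_smr_fdr >= 0.05:
        return False
    if p_heidi is None or not np.isfinite(p_heidi):
        return bool(allow_missing_heidi)
    return p_heidi > 0.05
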