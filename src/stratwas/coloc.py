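"""Approximate-Bayes-factor colocalization between a stratum GWAS and a
cell-type eQTL signal.

Per-variant evidence is the Wakefield log approximate Bayes factor; the five
hypothesis posteriors (no association / trait-1 only / trait-2 only /
distinct causal variants / one shared causal variant) are accumulated in log
space. Two prior schemes are evaluated — the standard (p1=p2=1e-4, p12=1e-5)
and an adjusted scheme with elevated p12 reflecting that tested pairs are
pre-selected TWAS discoveries — and the best PP4 across schemes is tiered at
0.4 (suggestive) and 0.7 (strong).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

#: prior effect SD on the log-odds scale for a case-control trait
W_GWAS = 0.2
#: prior effect SD for a quantitative eQTL trait
W_EQTL = 0.15

PRIOR_SCHEMES = {
    "default": dict(p1=1e-4, p2=1e-4, p12=1e-5),
    "adjusted": dict(p1=1e-4, p2=1e-4, p12=1e-4),
}

TIER_SUGGESTIVE = 0.4
TIER_STRONG = 0.7


@dataclass
class ColocResult:
    pp: np.ndarray              # pp0..pp4, sums to 1
    priors: tuple[float, float, float]
    scheme_tag: str
    n_variants: int
    top_variant_index: int      # argmax of the per-variant H4 share

    def __post_init__(self):
        self.pp = np.asarray(self.pp, dtype=float)
        if not np.isclose(self.pp.sum(), 1.0, atol=1e-9):
            raise ValueError("posteriors must sum to 1")

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


def wakefield_labf(beta, se, prior_sd: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor.

    With V = se^2, W = prior_sd^2, z = beta/se:
    lABF = 0.5*log(V/(V+W)) + (z^2/2)*(W/(V+W)).
    """
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    V = se ** 2
    W = prior_sd ** 2
    r = W / (V + W)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * z ** 2 * r


def coloc_abf(labf1: np.ndarray, labf2: np.ndarray, p1: float = 1e-4, p2: float = 1e-4,
              p12: float = 1e-5, scheme_tag: str = "default") -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    All sums run in log space: with s1 = logsumexp(labf1),
    s2 = logsumexp(labf2) and s12 = logsumexp(labf1 + labf2),
    H0 ~ 1, H1 ~ p1 e^s1, H2 ~ p2 e^s2, H3 ~ p1 p2 (e^{s1+s2} - e^s12),
    H4 ~ p12 e^s12.
    """
    l1 = np.asarray(labf1, dtype=float)
    l2 = np.asarray(labf2, dtype=float)
    if l1.shape != l2.shape or l1.ndim != 1:
        raise ValueError("labf vectors must be equal-length 1-d arrays")
    n = l1.size
    if n < 2:
        import warnings
        warnings.warn("fewer than 2 variants: H3 is degenerate", stacklevel=2)
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    log_h = np.empty(5)
    log_h[0] = 0.0
    log_h[1] = np.log(p1) + s1
    log_h[2] = np.log(p2) + s2
    # e^{s1+s2} - e^{s12}, guarded against cancellation to exactly zero
    diff = logsumexp([s1 + s2, s12], b=[1.0, -1.0], return_sign=True)
    log_h[3] = (np.log(p1) + np.log(p2) + diff[0]) if diff[1] > 0 else -np.inf
    log_h[4] = np.log(p12) + s12
    pp = np.exp(log_h - logsumexp(log_h))
    pp /= pp.sum()
    top = int(np.argmax(l1 + l2))
    return ColocResult(pp=pp, priors=(p1, p2, p12), scheme_tag=scheme_tag,
                       n_variants=n, top_variant_index=top)


def run_schemes(beta1, se1, beta2, se2, w1: float = W_GWAS, w2: float = W_EQTL,
                schemes: dict | None = None) -> list[ColocResult]:
    """Evaluate every prior scheme on one (GWAS, eQTL) variant slice."""
    schemes = schemes or PRIOR_SCHEMES
    l1 = wakefield_labf(beta1, se1, w1)
    l2 = wakefield_labf(beta2, se2, w2)
    return [coloc_abf(l1, l2, scheme_tag=tag, **pri) for tag, pri in schemes.items()]


def best_pp4(results: list[ColocResult]) -> tuple[float, str, int]:
    """Best PP4 across schemes, its tier, and the top colocalizing variant
    index (largest per-variant H4 share in the winning scheme)."""
    if not results:
        raise ValueError("best_pp4 requires at least one ColocResult")
    best = max(results, key=lambda r: r.pp4)
    if best.pp4 >= TIER_STRONG:
        tier = "strong"
    elif best.pp4 >= TIER_SUGGESTIVE:
        tier = "suggestive"
    else:
        tier = "none"
    return best.pp4, tier, best.top_variant_index
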