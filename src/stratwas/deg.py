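"""TMM normalization and pseudobulk differential expression versus AD
phenotypes, with the non-stratified and stratified support rules.

Counts are per-cell-type gene x sample pseudobulk matrices. Normalization is
the trimmed mean of M-values; expression is log2 CPM with a 0.5 pseudocount
over TMM-scaled library sizes; per-gene inference is ordinary least squares
of log-CPM on phenotype plus covariates (sex, post-mortem interval,
age-at-death, APOE2/APOE4 dosage, batch), with a t-test on the phenotype
coefficient.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: trim fractions per tail, matching the usual TMM convention
M_TRIM = 0.30
A_TRIM = 0.05
FC_RATIO = 1.5  # stratified support: |logFC| must be >= 1.5x the other stratum


# ---------------------------------------------------------------------------
# TMM

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float) -> float:
    """Weighted trimmed mean of M values of one library against the reference."""
    both = (obs > 0) & (ref > 0)
    if not both.any():
        return 0.0
    y_k, y_r = obs[both], ref[both]
    p_k, p_r = y_k / n_obs, y_r / n_ref
    M = np.log2(p_k / p_r)
    A = 0.5 * np.log2(p_k * p_r)
    if np.allclose(M, M[0]):
        return float(M[0])
    lo_m, hi_m = np.quantile(M, [M_TRIM, 1 - M_TRIM])
    lo_a, hi_a = np.quantile(A, [A_TRIM, 1 - A_TRIM])
    keep = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
    if not keep.any():
        return 0.0
    # inverse asymptotic binomial variance of M
    var = (n_obs - y_k[keep]) / (n_obs * y_k[keep]) + (n_ref - y_r[keep]) / (n_ref * y_r[keep])
    w = 1.0 / var
    return float(np.sum(w * M[keep]) / np.sum(w))


def tmm_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Per-sample TMM normalization factors (geometric mean 1).

    Reference sample: library whose upper quartile of nonzero CPM is closest
    to the mean of those upper quartiles.
    """
    Y = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("need a genes x samples matrix with >=2 samples")
    lib = Y.sum(axis=0)
    if np.any(lib <= 0):
        bad = np.flatnonzero(lib <= 0)
        names = (list(counts.columns[bad]) if isinstance(counts, pd.DataFrame) else bad.tolist())
        raise ValueError(f"samples with all-zero counts: {names}")
    uq = np.array([np.quantile(Y[Y[:, j] > 0, j] / lib[j] * 1e6, 0.75)
                   for j in range(Y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    logf = np.array([_tmm_pair(Y[:, j], Y[:, ref], lib[j], lib[ref])
                     for j in range(Y.shape[1])])
    f = 2.0 ** logf
    return f / np.exp(np.mean(np.log(f)))


def log_cpm(counts: pd.DataFrame, factors: np.ndarray | None = None) -> pd.DataFrame:
    """log2 counts-per-million with 0.5 pseudocount over TMM-scaled libraries."""
    if factors is None:
        factors = tmm_factors(counts)
    lib = counts.sum(axis=0).to_numpy(dtype=float) * np.asarray(factors, float)
    return np.log2((counts + 0.5) / (lib + 1.0) * 1e6)


# ---------------------------------------------------------------------------
# differential expression

def fit_de(logcpm: pd.DataFrame, phenotype: np.ndarray,
           covariates: pd.DataFrame, *, phenotype_name: str = "status",
           scope: str = "nonstratified") -> pd.DataFrame:
    """Per-gene OLS of log2-CPM on phenotype + covariates.

    Returns a frame with gene, logFC (phenotype coefficient, log2 per unit),
    p, t, n_samples, scope and phenotype columns. Constant covariates in a
    stratified scope (APOE4 dosage within a stratum) are dropped with a log
    message; any other rank deficiency raises, naming collinear columns.
    """
    y = np.asarray(phenotype, dtype=float)
    C = covariates.copy()
    const = [c for c in C.columns if C[c].std() < 1e-12]
    if const:
        if scope in ("carrier", "non-carrier") and "apoe4_dosage" in const:
            log.info("dropping constant covariate(s) %s in %s scope", const, scope)
        C = C.drop(columns=const)
    X = np.column_stack([np.ones(len(y)), y, C.to_numpy(dtype=float)])
    names = ["intercept", phenotype_name] + list(C.columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        collinear = [names[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    Y = logcpm.to_numpy(dtype=float).T  # samples x genes
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y               # coefs x genes
    resid = Y - X @ B
    dof = X.shape[0] - X.shape[1]
    if dof < 2:
        raise ValueError("not enough samples for the design (dof < 2)")
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    t = np.divide(B[1], se, out=np.zeros_like(se), where=se > 0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"gene": logcpm.index, "logFC": B[1], "t": t, "p": p,
                         "n_samples": len(y), "scope": scope,
                         "phenotype": phenotype_name})


def deg_support_nonstratified(p: float) -> bool:
    """Non-stratified rule: P < 0.05 for the pair's gene and cell type."""
    return bool(np.isfinite(p) and p < 0.05)


def deg_support_stratified(p_s: float, logfc_s: float, logfc_other: float) -> bool:
    """Stratified rule: P < 0.05 in the respective stratum AND (opposite
    effect direction OR |logFC| at least 1.5x the opposite stratum's)."""
    if not (np.isfinite(p_s) and np.isfinite(logfc_s) and np.isfinite(logfc_other)):
        if not np.isfinite(logfc_other):
            log.info("missing other-stratum logFC: stratified DEG support false")
        return False
    if p_s >= 0.05:
        return False
    opposite = np.sign(logfc_s) != np.sign(logfc_other) and logfc_other != 0
    return opposite or abs(logfc_s) >= FC_RATIO * abs(logfc_other)


def deg_support(results: pd.DataFrame, gene: str, cell_type: str, scope: str,
                require_all_phenotypes: bool = False) -> bool:
    """Evaluate the support rule over every fitted phenotype for one pair.

    ``results`` holds fit_de outputs for one cell type across scopes and
    phenotypes, with a ``cell_type`` column. Default combines phenotypes
    with 'any'.
    """
    sub = results[(results.gene == gene) & (results.cell_type == cell_type)]
    verdicts = []
    for pheno, grp in sub.groupby("phenotype"):
        by_scope = {s: r for s, r in zip(grp.scope, grp.itertuples())}
        if scope == "nonstratified":
            row = by_scope.get("nonstratified")
            verdicts.append(deg_support_nonstratified(row.p) if row else False)
        else:
            other = "non-carrier" if scope == "carrier" else "carrier"
            row, row_o = by_scope.get(scope), by_scope.get(other)
            if row is None or row_o is None:
                verdicts.append(False)
            else:
                verdicts.append(deg_support_stratified(row.p, row.logFC, row_o.logFC))
    if not verdicts:
        return False
    return all(verdicts) if require_all_phenotypes else any(verdicts)
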