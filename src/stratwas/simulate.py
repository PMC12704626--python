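"""Synthetic genotype / expression / phenotype generator.

Emulates the statistical structure the stratified cell-type TWAS pipeline
assumes: LD-blocked genotypes (Gaussian-copula AR(1) per haplotype),
cell-type cis-eQTL architecture, stratum-specific liability effects of
genetically regulated expression on a binary disease label, negative-binomial
pseudobulk counts, open-chromatin peaks centred on regulatory variants, and
compound gene sets seeded with causal genes.

Every draw is governed by ``SimulationConfig.seed`` through
``numpy.random.SeedSequence`` spawn keys, so a fixed config reproduces a
bit-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CELL_TYPES = ("Ast", "Exc", "Inh", "Mic", "Oli", "Opc", "End")
STRATA = ("carrier", "non-carrier")
#: primary (large) and secondary (small, different allele frequencies) ancestries
ANCESTRIES = ("EUR", "AFR")

_SALT = {"maf": 11, "truth": 13, "cohort": 17, "expr": 19, "pheno": 23, "bundle": 29}


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic bundle.

    Defaults are the desk-scale conditions the pipeline is validated under:
    20,000 subjects per APOE*4 stratum in the primary ancestry, 12 independent
    loci of 30 variants, 60 genes of which 10 are stratum-specific causal
    genes, cis-heritability 0.2 and a liability log-odds effect of 0.2 per
    unit of latent expression (≈1% of liability variance).
    """

    n_per_stratum: int = 20_000
    n_ref: int = 400                    # eQTL / pseudobulk reference cohort
    secondary_fraction: float = 0.25    # secondary-ancestry n as a fraction
    n_variants: int = 30                # variants per locus
    n_loci: int = 12
    ld_rho: float = 0.8                 # AR(1) adjacent-variant latent correlation
    maf_range: tuple[float, float] = (0.10, 0.50)
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    n_genes: int = 5                    # genes per locus (one cell type each)
    n_causal: int = 10                  # causal genes, one per leading locus
    h2_cis: float = 0.2
    beta_liability: float = 0.2
    stratum_specificity: float = 1.0
    prevalence_logit_intercept: float = -1.1
    nb_dispersion: float = 0.3
    peak_width: int = 500               # bp, centred on eQTL variants
    seed: int = 1

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigurationError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if not (0.0 <= self.h2_cis <= 1.0):
            raise ConfigurationError(f"h2_cis must be in [0, 1], got {self.h2_cis}")
        if not (0.0 <= self.stratum_specificity <= 1.0):
            raise ConfigurationError("stratum_specificity must be in [0, 1]")
        for name in ("n_per_stratum", "n_ref", "n_variants", "n_loci", "n_genes", "peak_width"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_causal > self.n_loci:
            raise ConfigurationError("n_causal cannot exceed n_loci (one causal gene per locus)")
        if self.n_causal > 0 and self.h2_cis == 0.0:
            raise ConfigurationError("h2_cis=0 with causal genes present: signal undetectable")

    def rng(self, *keys: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=tuple(keys)))


# ---------------------------------------------------------------------------
# variants and allele frequencies

_BASES = np.array(["A", "C", "G", "T"])


def variant_table(config: SimulationConfig, ancestry: str = "EUR") -> pd.DataFrame:
    """Variant map shared by all strata of one ancestry.

    Each locus occupies its own chromosome; positions are strictly increasing,
    1-based, spaced 1.5 kb apart. Ancestries share positions and alleles but
    draw independent allele frequencies from ``maf_range``.
    """
    lo, hi = config.maf_range
    m, L = config.n_variants, config.n_loci
    rng = config.rng(_SALT["maf"], ANCESTRIES.index(ancestry))
    maf = rng.uniform(lo, hi, size=L * m)
    allele_rng = config.rng(_SALT["maf"], 99)  # alleles identical across ancestries
    # avoid strand-ambiguous A/T and C/G pairs (harmonization would drop them)
    pairs = np.array([(0, 1), (0, 2), (1, 3), (2, 3)])  # AC, AG, CT, GT
    chosen = pairs[allele_rng.integers(0, len(pairs), size=L * m)]
    swap = allele_rng.random(L * m) < 0.5
    a1_idx = np.where(swap, chosen[:, 1], chosen[:, 0])
    a2_idx = np.where(swap, chosen[:, 0], chosen[:, 1])
    rows = []
    k = 0
    for locus in range(L):
        chrom = locus + 1
        for j in range(m):
            pos = 1_000_000 + j * 1_500
            rows.append((f"{chrom}:{pos}", chrom, pos, _BASES[a1_idx[k]], _BASES[a2_idx[k]],
                         locus, maf[k]))
            k += 1
    return pd.DataFrame(rows, columns=["variant", "chrom", "pos", "a1", "a2", "locus", "maf"])


# ---------------------------------------------------------------------------
# truth table

@dataclass
class TruthTable:
    """Ground truth: which (gene, cell type) pairs are causal, where and how."""

    table: pd.DataFrame  # gene, cell_type, locus, chrom, tss, causal_stratum, beta_liability
    weights: dict[str, list[tuple[str, float]]]  # gene -> [(variant, weight)]

    def causal_genes(self, stratum: str | None = None) -> list[str]:
        t = self.table
        if stratum is None:
            mask = t.causal_stratum != "none"
        else:
            mask = t.causal_stratum.isin([stratum, "both"])
        return list(t.loc[mask, "gene"])

    def validate(self) -> None:
        for _, row in self.table.iterrows():
            if row.causal_stratum == "none" and row.beta_liability != 0.0:
                raise ValueError(f"{row.gene}: null gene with nonzero liability effect")
            if not self.weights.get(row.gene):
                raise ValueError(f"{row.gene}: gene without eQTL variants")


def make_truth(config: SimulationConfig) -> TruthTable:
    """Assign genes to loci/cell types and choose causal strata and weights.

    Gene ``k`` at a locus regulates two adjacent variants starting at index
    ``k * floor(m / n_genes)``, keeping the eQTL signals of co-locus genes in
    weak LD. Raw weights (1.0, 0.5) are normalised so that the standardized
    genetic score has unit variance (Monte-Carlo normalisation under the same
    genotype copula), which makes ``h2_cis`` the latent variance fraction.
    Causal genes occupy the leading ``n_causal`` loci, alternating strata;
    a fraction ``1 - stratum_specificity`` of them is causal in both strata.
    """
    variants = variant_table(config, "EUR")
    rng = config.rng(_SALT["truth"])
    m = config.n_variants
    stride = max(1, m // config.n_genes)
    # small reference draw used only to normalise genetic-score variance
    norm_geno = {}
    rows, weights = [], {}
    gene_idx = 0
    n_both = round(config.n_causal * (1.0 - config.stratum_specificity))
    for locus in range(config.n_loci):
        vloc = variants[variants.locus == locus].reset_index(drop=True)
        X = _genotypes_one_locus(vloc.maf.to_numpy(), config.ld_rho, 2000,
                                 config.rng(_SALT["truth"], 7, locus))
        Xs = standardize_genotypes(X)
        for k in range(config.n_genes):
            gene = f"G{locus + 1:02d}{chr(ord('A') + k)}"
            cell_type = config.cell_types[gene_idx % len(config.cell_types)]
            # keep eQTL variants off the LD-block edges so the instrument has
            # flanking proxies on both sides, as real cis variants do
            i0 = min(2 + k * stride, m - 2) if m > 3 else 0
            idx = [i0, (i0 + 1) % m]
            raw = np.array([1.0, 0.5])
            score = Xs[:, idx] @ raw
            w = raw / max(score.std(), 1e-12)
            if locus < config.n_causal and k == 0:
                if gene_idx // config.n_genes < n_both:
                    stratum = "both"
                else:
                    stratum = STRATA[locus % 2]
                beta = config.beta_liability * (1.0 if locus % 4 < 2 else -1.0)
            else:
                stratum, beta = "none", 0.0
            tss = int(vloc.pos.iloc[idx[0]])
            rows.append((gene, cell_type, locus, int(vloc.chrom.iloc[0]), tss, stratum, beta))
            weights[gene] = list(zip(vloc.variant.iloc[idx], w))
            gene_idx += 1
    table = pd.DataFrame(rows, columns=["gene", "cell_type", "locus", "chrom", "tss",
                                        "causal_stratum", "beta_liability"])
    truth = TruthTable(table=table, weights=weights)
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# genotypes

def _genotypes_one_locus(maf: np.ndarray, rho: float, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Diploid genotypes for one locus via a latent AR(1) Gaussian copula.

    Two haplotypes per subject; each haplotype carries the minor allele where
    its latent Gaussian falls below Phi^-1(maf).
    """
    m = maf.size
    thr = stats.norm.ppf(maf)
    geno = np.zeros((n, m), dtype=np.int8)
    for _hap in range(2):
        z = np.empty((n, m))
        z[:, 0] = rng.standard_normal(n)
        if m > 1:
            eps = rng.standard_normal((n, m - 1))
            c = np.sqrt(1.0 - rho * rho)
            for j in range(1, m):
                z[:, j] = rho * z[:, j - 1] + c * eps[:, j - 1]
        geno += (z < thr).astype(np.int8)
    return geno


def simulate_genotypes(config: SimulationConfig, stratum: str, ancestry: str = "EUR",
                       n: int | None = None) -> tuple[np.ndarray, pd.DataFrame]:
    """Genotype matrix (subjects x variants, dosage 0/1/2) and its variant table."""
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
    variants = variant_table(config, ancestry)
    if n is None:
        n = config.n_per_stratum
        if ancestry != "EUR":
            n = max(50, int(round(n * config.secondary_fraction)))
    cols = []
    for locus in range(config.n_loci):
        maf = variants.loc[variants.locus == locus, "maf"].to_numpy()
        rng = config.rng(_SALT["cohort"], STRATA.index(stratum),
                         ANCESTRIES.index(ancestry), locus)
        cols.append(_genotypes_one_locus(maf, config.ld_rho, n, rng))
    return np.concatenate(cols, axis=1), variants


def standardize_genotypes(X: np.ndarray) -> np.ndarray:
    """Mean-impute NaNs, centre, scale to unit variance (monomorphic -> 0)."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean, X)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (X - mu) / sd


# ---------------------------------------------------------------------------
# expression + phenotype

@dataclass
class Cohort:
    """One simulated cohort: genotypes plus everything derived from them."""

    stratum: str
    ancestry: str
    genotypes: np.ndarray
    variants: pd.DataFrame
    latent: pd.DataFrame          # subjects x genes latent expression
    status: np.ndarray            # binary AD label
    pathology: np.ndarray         # quantitative global pathology score
    covariates: pd.DataFrame
    counts: dict[str, pd.DataFrame] = field(default_factory=dict)  # cell type -> genes x samples


def simulate_expression_and_phenotype(genotypes: np.ndarray, variants: pd.DataFrame,
                                      truth: TruthTable, config: SimulationConfig,
                                      stratum: str, *, rng_keys: tuple[int, ...] = (0,),
                                      with_counts: bool = False,
                                      libsize_log_offset: float = 0.0):
    """Latent expression, disease labels, covariates (and optional counts).

    latent_g = sqrt(h2_cis) * (standardized genotypes @ truth weights)
               + sqrt(1 - h2_cis) * N(0,1);
    logit P(case) = intercept + sum over genes causal in this stratum of
    beta_liability_g * latent_g. Pathology is the same genetic burden plus
    unit Gaussian noise. Covariates are independent of genotype by design.
    """
    if config.h2_cis == 0.0 and truth.causal_genes():
        raise ConfigurationError("h2_cis=0 with causal genes: undetectable signal")
    n = genotypes.shape[0]
    rng = config.rng(_SALT["expr"], *rng_keys)
    vindex = {v: i for i, v in enumerate(variants.variant)}
    Xs = standardize_genotypes(genotypes)
    lat = {}
    for gene, wlist in truth.weights.items():
        idx = [vindex[v] for v, _ in wlist]
        w = np.array([w for _, w in wlist])
        genetic = Xs[:, idx] @ w
        noise = rng.standard_normal(n)
        lat[gene] = np.sqrt(config.h2_cis) * genetic + np.sqrt(1.0 - config.h2_cis) * noise
    latent = pd.DataFrame(lat)

    prng = config.rng(_SALT["pheno"], *rng_keys)
    logit = np.full(n, config.prevalence_logit_intercept)
    burden = np.zeros(n)
    for _, row in truth.table.iterrows():
        if row.causal_stratum in (stratum, "both"):
            contrib = row.beta_liability * latent[row.gene].to_numpy()
            logit += contrib
            burden += contrib
    status = (prng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(np.int8)
    pathology = burden + prng.standard_normal(n)

    covariates = pd.DataFrame({
        "sex": prng.integers(0, 2, n),
        "age": prng.normal(75.0, 8.0, n),
        "pmi": np.clip(prng.normal(7.0, 2.0, n), 1.0, None),
        "batch": prng.integers(0, 3, n),
        "apoe2_dosage": prng.binomial(2, 0.07, n),
        "apoe4_dosage": np.full(n, 1 if stratum == "carrier" else 0, dtype=int),
    })

    counts = {}
    if with_counts:
        crng = config.rng(_SALT["expr"], 101, *rng_keys)
        offsets = libsize_log_offset + crng.normal(np.log(100.0), 0.2, n)
        r = 1.0 / config.nb_dispersion
        genes = list(truth.table.gene)
        for ct in config.cell_types:
            own = set(truth.table.loc[truth.table.cell_type == ct, "gene"])
            mat = np.empty((len(genes), n))
            for gi, gene in enumerate(genes):
                sig = latent[gene].to_numpy() if gene in own else crng.standard_normal(n)
                mu = np.exp(offsets + sig)
                mat[gi] = crng.negative_binomial(r, r / (r + mu))
            counts[ct] = pd.DataFrame(mat.astype(int), index=genes,
                                      columns=[f"S{i:04d}" for i in range(n)])
    return latent, status, pathology, covariates, counts


def simulate_cohort(config: SimulationConfig, truth: TruthTable, stratum: str,
                    ancestry: str = "EUR", n: int | None = None, *,
                    with_counts: bool = False) -> Cohort:
    geno, variants = simulate_genotypes(config, stratum, ancestry, n)
    keys = (STRATA.index(stratum), ANCESTRIES.index(ancestry), 1 if with_counts else 0)
    latent, status, pathology, cov, counts = simulate_expression_and_phenotype(
        geno, variants, truth, config, stratum, rng_keys=keys, with_counts=with_counts)
    return Cohort(stratum=stratum, ancestry=ancestry, genotypes=geno, variants=variants,
                  latent=latent, status=status, pathology=pathology, covariates=cov,
                  counts=counts)


def simulate_reference(config: SimulationConfig, truth: TruthTable) -> Cohort:
    """Mixed-stratum reference cohort (paired genotypes + pseudobulk counts).

    Emulates a snRNA-seq cohort with WGS: both strata present (assigned at
    random), counts generated for every cell type, used for eQTL weights,
    LD matrices and the pseudobulk differential-expression stage.
    """
    n = config.n_ref
    rng = config.rng(_SALT["cohort"], 77)
    assign = rng.random(n) < 0.45  # carrier fraction
    halves = []
    for stratum, mask in (("carrier", assign), ("non-carrier", ~assign)):
        nh = int(mask.sum())
        geno, variants = simulate_genotypes(config, stratum, "EUR", nh)
        keys = (STRATA.index(stratum), 5, 1)
        latent, status, path, cov, counts = simulate_expression_and_phenotype(
            geno, variants, truth, config, stratum, rng_keys=keys, with_counts=True)
        halves.append((mask, geno, latent, status, path, cov, counts))
    variants = variant_table(config, "EUR")
    geno = np.empty((n, halves[0][1].shape[1]), dtype=np.int8)
    latent = pd.DataFrame(index=range(n), columns=halves[0][2].columns, dtype=float)
    status = np.empty(n, dtype=np.int8)
    path = np.empty(n)
    cov = pd.DataFrame(index=range(n), columns=halves[0][5].columns, dtype=float)
    counts = {ct: pd.DataFrame(0, index=halves[0][6][ct].index,
                               columns=[f"S{i:04d}" for i in range(n)])
              for ct in config.cell_types}
    for mask, g, l, s, p, c, cnt in halves:
        where = np.flatnonzero(mask)
        geno[where] = g
        latent.iloc[where] = l.to_numpy()
        status[where] = s
        path[where] = p
        cov.iloc[where] = c.to_numpy()
        for ct in counts:
            counts[ct].iloc[:, where] = cnt[ct].to_numpy()
    cov["apoe4_dosage"] = assign.astype(int)
    cov["batch"] = cov["batch"].astype(int)
    cov["sex"] = cov["sex"].astype(int)
    stratum_label = np.where(assign, "carrier", "non-carrier")
    cov["stratum"] = stratum_label
    return Cohort(stratum="mixed", ancestry="EUR", genotypes=geno, variants=variants,
                  latent=latent, status=status, pathology=path, covariates=cov,
                  counts=counts)


# ---------------------------------------------------------------------------
# auxiliary bundle pieces

def make_peaks(config: SimulationConfig, truth: TruthTable,
               variants: pd.DataFrame) -> pd.DataFrame:
    """BED peaks (0-based half-open) centred on each gene's eQTL variants,
    labelled with the gene's cell type, plus decoy peaks away from variants."""
    vpos = variants.set_index("variant")[["chrom", "pos"]]
    half = config.peak_width // 2
    rows = []
    for _, row in truth.table.iterrows():
        for v, _w in truth.weights[row.gene]:
            chrom, pos = vpos.loc[v]
            start = max(0, int(pos) - 1 - half)
            rows.append((int(chrom), start, start + config.peak_width, row.cell_type))
    rng = config.rng(_SALT["bundle"], 3)
    for _ in range(config.n_loci):
        chrom = int(rng.integers(1, config.n_loci + 1))
        start = int(rng.integers(10_000, 500_000))
        ct = config.cell_types[int(rng.integers(0, len(config.cell_types)))]
        rows.append((chrom, start, start + config.peak_width, ct))
    bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return bed.sort_values(["chrom", "start"]).reset_index(drop=True)


def make_gene_sets(config: SimulationConfig, truth: TruthTable,
                   n_decoy: int = 8, seeded_per_stratum: int = 2) -> dict[str, list[str]]:
    """Synthetic compound gene sets (GMT content).

    Drug-signature databases list the targets of a compound, which for a
    disease-focused signature cover a gene network rather than isolated
    genes. Per stratum, ``seeded_per_stratum`` compound sets therefore each
    contain three of that stratum's causal genes together with those genes'
    druggable interaction partners, plus one random null gene; decoy
    compounds draw five random null genes. Every set has >=2 genes.
    """
    rng = config.rng(_SALT["bundle"], 5)
    null_genes = list(truth.table.loc[truth.table.causal_stratum == "none", "gene"])
    sets: dict[str, list[str]] = {}
    for stratum in STRATA:
        causal = truth.causal_genes(stratum)
        tag = "CAR" if stratum == "carrier" else "NON"
        for i in range(seeded_per_stratum):
            picked = list(rng.choice(causal, size=min(3, len(causal)), replace=False))
            picked += [f"{g}_P1" for g in picked]
            picked += list(rng.choice(null_genes, size=1, replace=False))
            sets[f"CMPD_{tag}{i + 1}"] = picked
    for i in range(n_decoy):
        sets[f"CMPD_DECOY{i + 1}"] = list(rng.choice(null_genes, size=5, replace=False))
    return sets


def make_network(config: SimulationConfig, truth: TruthTable) -> pd.DataFrame:
    """Interaction edge list: each causal gene linked to two partner genes."""
    rows = []
    for gene in truth.causal_genes():
        rows.append((gene, f"{gene}_P1", "synthetic"))
        rows.append((gene, f"{gene}_P2", "synthetic"))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "source"])


def make_druggable(config: SimulationConfig, truth: TruthTable) -> list[str]:
    """Druggable-gene list: all causal genes, half of null genes, P1 partners."""
    rng = config.rng(_SALT["bundle"], 9)
    null_genes = sorted(truth.table.loc[truth.table.causal_stratum == "none", "gene"])
    keep = list(rng.choice(null_genes, size=len(null_genes) // 2, replace=False))
    drugs = sorted(set(truth.causal_genes()) | set(keep)
                   | {f"{g}_P1" for g in truth.causal_genes()})
    return drugs


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["maf_range"] = list(d["maf_range"])
    d["cell_types"] = list(d["cell_types"])
    return d
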