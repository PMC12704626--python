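"""Pipeline driver: chains simulation, stratified GWAS, cell-type TWAS,
heterogeneity filtering, colocalization, SMR/HEIDI, pseudobulk DEG,
open-chromatin overlap, evidence integration and compound enrichment.

Each ``stage_*`` function reads its inputs from and writes its outputs to a
working directory, so the stages can be run one at a time (the analysis
drivers and the CLI do exactly that) or end-to-end via :func:`run_pipeline`,
which also writes a manifest with the seed, a config hash and every
threshold applied.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .assoc import effective_n, filter_variants, harmonize, run_stratified_gwas
from .coloc import best_pp4, run_schemes
from .deg import deg_support, fit_de, log_cpm, tmm_factors
from .epigenome import ld_proxies, peak_overlap
from .prioritize import drug_enrichment, druggable_intersect, evidence_profile, \
    network_expand, profiles_to_frame
from .simulate import STRATA, SimulationConfig, TruthTable, config_to_dict, \
    make_druggable, make_gene_sets, make_network, make_peaks, make_truth, \
    simulate_cohort, simulate_reference, standardize_genotypes
from .smr import heidi_test, smr_support, smr_test
from .stratum_filter import annotate_heterogeneity, bh_fdr, cluster_loci, \
    cross_ancestry_consistent, locus_exclusion
from .twas import WeightSet, fit_weights, run_ctwas, screen_heritability

log = logging.getLogger(__name__)

GWAS_COVARIATES = ["sex", "age", "apoe2_dosage"]
DEG_COVARIATES = ["sex", "pmi", "age", "apoe2_dosage", "apoe4_dosage", "batch"]
THRESHOLDS = {
    "fdr_level": 0.05, "other_stratum_p": 0.05, "locus_reach_bp": 1_000_000,
    "heritability_p": 0.05, "pp4_suggestive": 0.4, "pp4_strong": 0.7,
    "proxy_r2": 0.8, "deg_fc_ratio": 1.5, "min_compound_overlap": 2,
    "min_genotyping_rate": 0.9,
}


def _bundle(outdir) -> Path:
    return Path(outdir) / "bundle"


# ---------------------------------------------------------------------------
# stage 1: synthetic bundle

def stage_bundle(config: SimulationConfig, outdir) -> Path:
    """Simulate everything and emit the fixture bundle (stage 1).

    Writes per-stratum EUR and secondary-ancestry GWAS summary statistics,
    fitted expression-weight files, per-chromosome LD matrices, eQTL marginal
    statistics, pseudobulk counts and sample covariates, cell-type peaks,
    compound gene sets, the interaction edge list, the druggable-gene list
    and the ground-truth table.
    """
    bdir = _bundle(outdir)
    bdir.mkdir(parents=True, exist_ok=True)
    truth = make_truth(config)
    sio.write_truth(truth, bdir / "truth.tsv")

    ref = simulate_reference(config, truth)
    ref.variants.to_csv(bdir / "variants.tsv", sep="\t", index=False)

    # LD per chromosome from the reference panel
    for chrom, sub in ref.variants.groupby("chrom"):
        idx = sub.index.to_numpy()
        Xs = standardize_genotypes(ref.genotypes[:, idx])
        R = np.corrcoef(Xs, rowvar=False)
        R = np.nan_to_num(R, nan=0.0)
        np.fill_diagonal(R, 1.0)
        sio.write_ld(pd.DataFrame(R, index=sub.variant, columns=sub.variant),
                     bdir / f"ld_chr{chrom}.tsv")

    # pseudobulk counts + sample sheet
    for ct in config.cell_types:
        sio.write_counts(ref.counts[ct], bdir / f"counts_{ct}.tsv")
    samples = ref.covariates.copy()
    samples.insert(0, "status", ref.status)
    samples.insert(1, "pathology", ref.pathology)
    samples.index = [f"S{i:04d}" for i in range(len(samples))]
    sio.write_covariates(samples, bdir / "samples.tsv")

    # eQTL marginal statistics and expression weights per (gene, cell type)
    eqtl_rows = []
    weight_sets: list[WeightSet] = []
    screen_rng = config.rng(43)
    n = ref.genotypes.shape[0]
    for _, g in truth.table.iterrows():
        expr = log_cpm(ref.counts[g.cell_type]).loc[g.gene].to_numpy()
        cis = ref.variants[ref.variants.chrom == g.chrom]
        X = ref.genotypes[:, cis.index.to_numpy()].astype(float)
        # marginal per-variant OLS on dosage
        xm = X - X.mean(axis=0)
        ym = expr - expr.mean()
        sxx = (xm ** 2).sum(axis=0)
        sxx = np.where(sxx < 1e-12, np.nan, sxx)
        beta = xm.T @ ym / sxx
        rss = (ym ** 2).sum() - beta ** 2 * sxx
        se = np.sqrt(np.maximum(rss, 1e-300) / (n - 2) / sxx)
        from scipy import stats as sps
        pvals = 2 * sps.t.sf(np.abs(beta / se), n - 2)
        for v, b, s, p in zip(cis.variant, beta, se, pvals):
            eqtl_rows.append((g.gene, g.cell_type, v, b, s, p, n))
        h2_p = screen_heritability(expr, X, n_perm=500, rng=screen_rng)
        if h2_p < THRESHOLDS["heritability_p"]:
            ws = fit_weights(expr, X, list(cis.variant), g.gene, g.cell_type,
                             int(g.chrom), int(g.tss), h2_p=h2_p, seed=config.seed)
            if ws is not None:
                weight_sets.append(ws)
    sio.write_eqtl_stats(pd.DataFrame(eqtl_rows, columns=["gene", "cell_type", "variant",
                                                          "beta", "se", "p", "n"]),
                         bdir / "eqtl_stats.tsv")
    sio.write_weights(weight_sets, bdir / "weights.tsv", variants=ref.variants)

    # GWAS cohorts
    for ancestry in ("EUR", "AFR"):
        for stratum in STRATA:
            cohort = simulate_cohort(config, truth, stratum, ancestry)
            stats = run_stratified_gwas(cohort.genotypes, cohort.status,
                                        cohort.covariates[GWAS_COVARIATES],
                                        cohort.variants)
            sio.write_sumstats(stats, bdir / f"gwas_{ancestry}_{stratum}.tsv")

    sio.write_bed(make_peaks(config, truth, ref.variants), bdir / "peaks.bed")
    sio.write_gmt(make_gene_sets(config, truth), bdir / "compounds.gmt")
    sio.write_edges(make_network(config, truth), bdir / "edges.tsv")
    sio.write_gene_list(make_druggable(config, truth), bdir / "druggable.txt")
    (bdir / "config.json").write_text(json.dumps(config_to_dict(config), indent=2))
    return bdir


def _load_ld(outdir) -> dict[int, pd.DataFrame]:
    bdir = _bundle(outdir)
    out = {}
    for f in sorted(bdir.glob("ld_chr*.tsv")):
        chrom = int(f.stem.removeprefix("ld_chr"))
        out[chrom] = sio.read_ld(f)
    return out


def _load_gwas(outdir, ancestry: str) -> dict[str, pd.DataFrame]:
    bdir = _bundle(outdir)
    anchor = pd.read_csv(bdir / "variants.tsv", sep="\t")
    out = {}
    for stratum in STRATA:
        df = sio.read_sumstats(bdir / f"gwas_{ancestry}_{stratum}.tsv")
        df = harmonize(df, anchor)
        keep = filter_variants([df], set(anchor.variant),
                               THRESHOLDS["min_genotyping_rate"])
        out[stratum] = df[df.variant.isin(keep)].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# stage 2+3: TWAS and the heterogeneity filter

def stage_ctwas(outdir) -> pd.DataFrame:
    weights = sio.read_weights(_bundle(outdir) / "weights.tsv")
    gwas = _load_gwas(outdir, "EUR")
    table = run_ctwas(weights, gwas, _load_ld(outdir))
    table.to_csv(Path(outdir) / "ctwas.tsv", sep="\t", index=False)
    return table


def stage_filter(outdir) -> pd.DataFrame:
    table = pd.read_csv(Path(outdir) / "ctwas.tsv", sep="\t")
    ann = annotate_heterogeneity(table)
    ann["locus_id"] = cluster_loci(ann)
    ann.to_csv(Path(outdir) / "pairs_annotated.tsv", sep="\t", index=False)
    retained = locus_exclusion(ann)
    retained.to_csv(Path(outdir) / "pairs_retained.tsv", sep="\t", index=False)
    log.info("%d of %d pairs retained after heterogeneity + locus exclusion",
             len(retained), len(table))
    return retained


# ---------------------------------------------------------------------------
# stage 4: cross-ancestry consistency

def stage_cross_ancestry(outdir) -> pd.DataFrame:
    outdir = Path(outdir)
    retained = pd.read_csv(outdir / "pairs_retained.tsv", sep="\t")
    weights = {(w.gene, w.cell_type): w
               for w in sio.read_weights(_bundle(outdir) / "weights.tsv")}
    gwas_sec = _load_gwas(outdir, "AFR")
    gwas_pri = _load_gwas(outdir, "EUR")
    ld = _load_ld(outdir)
    sec_table = run_ctwas(list(weights.values()), gwas_sec, ld)
    sec = sec_table.set_index(["gene", "cell_type"])
    neff = {}
    for s in STRATA:
        neff[s] = {
            "primary": effective_n(int(gwas_pri[s].n_cases.iloc[0]),
                                   int(gwas_pri[s].n_controls.iloc[0])),
            "secondary": effective_n(int(gwas_sec[s].n_cases.iloc[0]),
                                     int(gwas_sec[s].n_controls.iloc[0])),
        }
    rows = []
    for _, r in retained.iterrows():
        stratum = r.heterogeneity_stratum
        key = (r.gene, r.cell_type)
        if key in sec.index:
            zsec = {s: float(sec.loc[key, f"z_{s}"]) for s in STRATA}
        else:
            zsec = {}
        ok = cross_ancestry_consistent(
            {s: r[f"z_{s}"] for s in STRATA}, {s: r[f"p_{s}"] for s in STRATA},
            zsec, neff, stratum)
        rows.append({"gene": r.gene, "cell_type": r.cell_type, "stratum": stratum,
                     "consistent": ok})
    out = pd.DataFrame(rows, columns=["gene", "cell_type", "stratum", "consistent"])
    out.to_csv(outdir / "cross_ancestry.tsv", sep="\t", index=False)
    return out


# ---------------------------------------------------------------------------
# stage 5: colocalization

def stage_coloc(outdir) -> pd.DataFrame:
    outdir = Path(outdir)
    retained = pd.read_csv(outdir / "pairs_retained.tsv", sep="\t")
    gwas = _load_gwas(outdir, "EUR")
    eqtl = sio.read_eqtl_stats(_bundle(outdir) / "eqtl_stats.tsv")
    rows = []
    for _, r in retained.iterrows():
        stratum = r.heterogeneity_stratum
        e = eqtl[(eqtl.gene == r.gene) & (eqtl.cell_type == r.cell_type)]
        g = gwas[stratum].set_index("variant").reindex(e.variant)
        ok = g.beta.notna() & e.set_index("variant").beta.notna().to_numpy()
        e2 = e[ok.to_numpy()]
        g2 = g[ok.to_numpy()]
        results = run_schemes(g2.beta.to_numpy(), g2.se.to_numpy(),
                              e2.beta.to_numpy(), e2.se.to_numpy())
        pp4, tier, top_idx = best_pp4(results)
        rows.append({"gene": r.gene, "cell_type": r.cell_type, "stratum": stratum,
                     "pp4_best": pp4, "tier": tier,
                     "top_variant": e2.variant.iloc[top_idx],
                     "n_variants": len(e2)})
    out = pd.DataFrame(rows, columns=["gene", "cell_type", "stratum", "pp4_best",
                                      "tier", "top_variant", "n_variants"])
    out.to_csv(outdir / "coloc.tsv", sep="\t", index=False)
    return out


# ---------------------------------------------------------------------------
# stage 6: SMR + HEIDI

def stage_smr(outdir, seed: int = 0) -> pd.DataFrame:
    outdir = Path(outdir)
    retained = pd.read_csv(outdir / "pairs_retained.tsv", sep="\t")
    gwas = _load_gwas(outdir, "EUR")
    eqtl = sio.read_eqtl_stats(_bundle(outdir) / "eqtl_stats.tsv")
    ld = _load_ld(outdir)
    rng = np.random.default_rng(seed)
    rows = []
    for _, r in retained.iterrows():
        stratum = r.heterogeneity_stratum
        e = eqtl[(eqtl.gene == r.gene) & (eqtl.cell_type == r.cell_type)].reset_index(drop=True)
        g = gwas[stratum].set_index("variant").reindex(e.variant).reset_index()
        ok = g.beta.notna() & e.beta.notna()
        e, g = e[ok].reset_index(drop=True), g[ok].reset_index(drop=True)
        z_e = (e.beta / e.se).to_numpy()
        top = int(np.argmax(np.abs(z_e)))
        res = smr_test(float(g.beta[top] / g.se[top]), float(z_e[top]),
                       float(g.beta[top]), float(e.beta[top]),
                       top_variant=e.variant[top])
        if res is None:
            continue
        R = ld[int(r.chrom)].loc[e.variant, e.variant].to_numpy()
        p_heidi, n_snps = heidi_test(g.beta.to_numpy(), g.se.to_numpy(),
                                     e.beta.to_numpy(), e.se.to_numpy(), R, top,
                                     rng=rng)
        rows.append({"gene": r.gene, "cell_type": r.cell_type, "stratum": stratum,
                     "top_variant": res.top_variant, "b_xy": res.b_xy,
                     "t_smr": res.t_smr, "p_smr": res.p_smr,
                     "p_heidi": np.nan if p_heidi is None else p_heidi,
                     "n_heidi_snps": n_snps})
    out = pd.DataFrame(rows, columns=["gene", "cell_type", "stratum", "top_variant",
                                      "b_xy", "t_smr", "p_smr", "p_heidi",
                                      "n_heidi_snps"])
    if not len(out):
        out["p_smr_fdr"] = pd.Series(dtype=float)
        out["support"] = pd.Series(dtype=bool)
    if len(out):
        out["p_smr_fdr"] = bh_fdr(out.p_smr.to_numpy())
        out["support"] = [smr_support(q, None if not np.isfinite(ph) else ph)
                          for q, ph in zip(out.p_smr_fdr, out.p_heidi)]
    out.to_csv(outdir / "smr.tsv", sep="\t", index=False)
    return out


# ---------------------------------------------------------------------------
# stage 7: pseudobulk DEG

def stage_deg(outdir) -> pd.DataFrame:
    outdir = Path(outdir)
    bdir = _bundle(outdir)
    samples = sio.read_covariates(bdir / "samples.tsv")
    cell_types = sorted(f.stem.removeprefix("counts_") for f in bdir.glob("counts_*.tsv"))
    cov = pd.get_dummies(samples[DEG_COVARIATES], columns=["batch"], drop_first=True,
                         dtype=float)
    results = []
    for ct in cell_types:
        counts = sio.read_counts(bdir / f"counts_{ct}.tsv")
        lcpm = log_cpm(counts, tmm_factors(counts))
        for scope, mask in (("nonstratified", np.ones(len(samples), bool)),
                            ("carrier", (samples.stratum == "carrier").to_numpy()),
                            ("non-carrier", (samples.stratum == "non-carrier").to_numpy())):
            for pheno in ("status", "pathology"):
                res = fit_de(lcpm.loc[:, mask], samples.loc[mask, pheno].to_numpy(),
                             cov.loc[mask], phenotype_name=pheno, scope=scope)
                res["cell_type"] = ct
                results.append(res)
    out = pd.concat(results, ignore_index=True)
    out.to_csv(outdir / "deg.tsv", sep="\t", index=False)
    return out


# ---------------------------------------------------------------------------
# stage 8: open-chromatin overlap

def stage_overlap(outdir) -> pd.DataFrame:
    outdir = Path(outdir)
    coloc = pd.read_csv(outdir / "coloc.tsv", sep="\t")
    peaks = sio.read_bed(_bundle(outdir) / "peaks.bed")
    variants = pd.read_csv(_bundle(outdir) / "variants.tsv", sep="\t")
    ld = _load_ld(outdir)
    vmap = variants.set_index("variant")
    rows = []
    for _, r in coloc.iterrows():
        if r.tier not in ("suggestive", "strong"):
            rows.append({"gene": r.gene, "cell_type": r.cell_type, "stratum": r.stratum,
                         "overlap": False, "n_proxies": 0})
            continue
        chrom = int(vmap.loc[r.top_variant, "chrom"])
        proxies = ld_proxies(r.top_variant, ld[chrom], THRESHOLDS["proxy_r2"])
        vsub = vmap.loc[proxies].reset_index()
        hit, _hits = peak_overlap(vsub, peaks, r.cell_type)
        rows.append({"gene": r.gene, "cell_type": r.cell_type, "stratum": r.stratum,
                     "overlap": hit, "n_proxies": len(proxies)})
    out = pd.DataFrame(rows, columns=["gene", "cell_type", "stratum", "overlap",
                                      "n_proxies"])
    out.to_csv(outdir / "overlap.tsv", sep="\t", index=False)
    return out


# ---------------------------------------------------------------------------
# stage 9: evidence profiles + drug enrichment

def stage_prioritize(outdir, drug_tier: str = "more_than_half") -> pd.DataFrame:
    outdir = Path(outdir)
    retained = pd.read_csv(outdir / "pairs_retained.tsv", sep="\t")
    xanc = pd.read_csv(outdir / "cross_ancestry.tsv", sep="\t")
    coloc = pd.read_csv(outdir / "coloc.tsv", sep="\t")
    smr = pd.read_csv(outdir / "smr.tsv", sep="\t")
    deg = pd.read_csv(outdir / "deg.tsv", sep="\t")
    overlap = pd.read_csv(outdir / "overlap.tsv", sep="\t")

    def lookup(df, gene, ct, col, default=False):
        sub = df[(df.gene == gene) & (df.cell_type == ct)]
        return sub[col].iloc[0] if len(sub) else default

    profiles = []
    for _, r in retained.iterrows():
        stratum = r.heterogeneity_stratum
        profiles.append(evidence_profile(
            r.gene, r.cell_type, stratum,
            cross_ancestry=bool(lookup(xanc, r.gene, r.cell_type, "consistent")),
            coloc_tier=str(lookup(coloc, r.gene, r.cell_type, "tier", "none")),
            smr=bool(lookup(smr, r.gene, r.cell_type, "support")),
            atac=bool(lookup(overlap, r.gene, r.cell_type, "overlap")),
            deg_nonstratified=deg_support(deg, r.gene, r.cell_type, "nonstratified"),
            deg_stratified=deg_support(deg, r.gene, r.cell_type, stratum),
        ))
    prof = profiles_to_frame(profiles)
    prof.to_csv(outdir / "profiles.tsv", sep="\t", index=False)

    bdir = _bundle(outdir)
    gmt = sio.read_gmt(bdir / "compounds.gmt")
    edges = sio.read_edges(bdir / "edges.tsv")
    druggable = sio.read_gene_list(bdir / "druggable.txt")
    truth = sio.read_truth(bdir / "truth.tsv")
    universe = sorted({g for gs in gmt.values() for g in gs}
                      | set(truth.table.gene) | set(druggable))
    rank = {"none": 0, "at_least_half": 1, "more_than_half": 2}
    for stratum in STRATA:
        tag = stratum.replace("-", "")
        sub = prof[(prof.stratum == stratum)
                   & (prof.tier.map(rank) >= rank[drug_tier])] if len(prof) else prof
        seeds = sorted(set(sub.gene)) if len(prof) else []
        tier1 = druggable_intersect(seeds, druggable) if seeds else []
        expanded = network_expand(seeds, edges, druggable) if seeds else []
        sio.write_gene_list(seeds or [""], outdir / f"prioritized_{tag}.txt")
        sio.write_gene_list(tier1 or [""], outdir / f"druggable_tier1_{tag}.txt")
        enr = drug_enrichment(expanded, gmt, universe, prioritized=seeds) if expanded \
            else pd.DataFrame(columns=["compound", "k", "K", "n", "N", "p", "q",
                                       "overlap", "k_prioritized", "significant"])
        enr.to_csv(outdir / f"enrichment_{tag}.tsv", sep="\t", index=False)
    return prof


# ---------------------------------------------------------------------------
# end-to-end

def run_pipeline(config: SimulationConfig, outdir, drug_tier: str = "more_than_half") -> dict:
    """Run every stage in order; returns a manifest dict (also written to
    manifest.json). Deterministic given ``config.seed``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_bundle(config, outdir)
    stage_ctwas(outdir)
    retained = stage_filter(outdir)
    stage_cross_ancestry(outdir)
    stage_coloc(outdir)
    stage_smr(outdir, seed=config.seed)
    stage_deg(outdir)
    stage_overlap(outdir)
    prof = stage_prioritize(outdir, drug_tier=drug_tier)
    cfg = config_to_dict(config)
    manifest = {
        "seed": config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "thresholds": THRESHOLDS,
        "drug_tier": drug_tier,
        "n_pairs_tested": int(pd.read_csv(outdir / "ctwas.tsv", sep="\t").shape[0]),
        "n_pairs_retained": int(len(retained)),
        "n_pairs_prioritized": int((prof.tier != "none").sum()) if len(prof) else 0,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
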