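"""Generator tests: LD control of the genotype copula, MAF bounds,
phenotype model, pseudobulk count structure, determinism, and the auxiliary
bundle pieces (peaks, gene sets)."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from stratwas.simulate import (ConfigurationError, SimulationConfig, make_gene_sets,
                               make_peaks, make_truth, simulate_expression_and_phenotype,
                               simulate_genotypes, variant_table)


@pytest.mark.parametrize("kwargs", [
    {"maf_range": (0.0, 0.5)},
    {"maf_range": (0.1, 0.6)},
    {"ld_rho": 1.0},
    {"ld_rho": -0.1},
    {"h2_cis": 1.5},
    {"n_variants": 0},
])
def test_config_invariants_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        SimulationConfig(**kwargs)


def test_h2_zero_with_causal_genes_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(h2_cis=0.0, n_causal=2)


def test_adjacent_correlation_near_zero_without_ld():
    cfg = SimulationConfig(ld_rho=0.0, n_loci=1, n_variants=10, n_causal=0, seed=5)
    G, _ = simulate_genotypes(cfg, "carrier", n=5000)
    r = np.corrcoef(G, rowvar=False)
    adj = np.diag(r, k=1)
    assert np.all(np.abs(adj) < 0.05)


def test_adjacent_genotype_correlation_matches_mc_oracle():
    """Latent rho=0.9 at MAF 0.3 gives genotype correlation ~0.703
    (frozen Monte-Carlo oracle, 10^6 draws under the same copula)."""
    cfg = SimulationConfig(ld_rho=0.9, n_loci=1, n_variants=2, maf_range=(0.3, 0.3),
                           n_causal=0, seed=5)
    G, _ = simulate_genotypes(cfg, "carrier", n=5000)
    r = np.corrcoef(G[:, 0], G[:, 1])[0, 1]
    assert abs(r - 0.703) < 0.1


def test_same_seed_bit_identical():
    cfg = SimulationConfig(n_loci=2, n_variants=8, n_causal=1, seed=11)
    G1, v1 = simulate_genotypes(cfg, "carrier", n=200)
    G2, v2 = simulate_genotypes(cfg, "carrier", n=200)
    assert np.array_equal(G1, G2)
    pd.testing.assert_frame_equal(v1, v2)


def test_strata_and_ancestries_differ():
    cfg = SimulationConfig(n_loci=2, n_variants=8, n_causal=1, seed=11)
    G1, _ = simulate_genotypes(cfg, "carrier", n=200)
    G2, _ = simulate_genotypes(cfg, "non-carrier", n=200)
    assert not np.array_equal(G1, G2)
    vA = variant_table(cfg, "EUR")
    vB = variant_table(cfg, "AFR")
    assert not np.allclose(vA.maf, vB.maf)
    assert (vA.a1 == vB.a1).all()  # alleles shared across ancestries


def test_positions_strictly_increasing_and_mafs_in_range():
    cfg = SimulationConfig(n_loci=3, n_variants=20, maf_range=(0.15, 0.4), n_causal=0,
                           seed=2)
    G, v = simulate_genotypes(cfg, "carrier", n=4000)
    for _, sub in v.groupby("chrom"):
        assert sub.pos.is_monotonic_increasing and sub.pos.nunique() == len(sub)
    emp_maf = G.mean(axis=0) / 2
    # fold to minor allele; allow binomial sampling error at n=4000
    emp_maf = np.minimum(emp_maf, 1 - emp_maf)
    tol = 3 * np.sqrt(0.4 * 0.6 / (2 * 4000))
    assert emp_maf.min() > 0.15 - tol and emp_maf.max() < 0.4 + tol


def test_null_case_proportion_matches_intercept():
    """With no liability effects the case rate is logit^-1(intercept)."""
    cfg = SimulationConfig(n_loci=2, n_variants=8, n_causal=0,
                           prevalence_logit_intercept=-1.1, seed=3)
    truth = make_truth(cfg)
    G, v = simulate_genotypes(cfg, "carrier", n=10_000)
    _, status, _, _, _ = simulate_expression_and_phenotype(G, v, truth, cfg, "carrier")
    expected = special.expit(-1.1)
    ci = 3 * np.sqrt(expected * (1 - expected) / 10_000)
    assert abs(status.mean() - expected) < ci


def test_h2_one_latent_equals_genetic_score():
    cfg = SimulationConfig(n_loci=2, n_variants=8, n_causal=1, h2_cis=1.0, seed=3)
    truth = make_truth(cfg)
    G, v = simulate_genotypes(cfg, "carrier", n=300)
    latent, *_ = simulate_expression_and_phenotype(G, v, truth, cfg, "carrier")
    from stratwas.simulate import standardize_genotypes
    Xs = standardize_genotypes(G)
    vidx = {vid: i for i, vid in enumerate(v.variant)}
    gene = truth.table.gene.iloc[0]
    idx = [vidx[vv] for vv, _ in truth.weights[gene]]
    w = np.array([wt for _, wt in truth.weights[gene]])
    np.testing.assert_allclose(latent[gene].to_numpy(), Xs[:, idx] @ w, atol=1e-12)


def test_library_offset_doubles_total_counts():
    cfg = SimulationConfig(n_loci=1, n_variants=8, n_genes=4, n_causal=0,
                           cell_types=("Ast",), nb_dispersion=0.2, seed=9)
    truth = make_truth(cfg)
    G, v = simulate_genotypes(cfg, "carrier", n=400)
    totals = []
    for off in (0.0, np.log(2.0)):
        *_, counts = simulate_expression_and_phenotype(
            G, v, truth, cfg, "carrier", with_counts=True, libsize_log_offset=off)
        totals.append(counts["Ast"].to_numpy().sum(axis=0).mean())
    assert abs(np.log(totals[1] / totals[0]) - np.log(2.0)) < 0.1


def test_truth_table_consistency(small_truth):
    t = small_truth.table
    assert (t.loc[t.causal_stratum == "none", "beta_liability"] == 0).all()
    assert (t.loc[t.causal_stratum != "none", "beta_liability"] != 0).all()
    assert all(len(small_truth.weights[g]) >= 1 for g in t.gene)


def test_peaks_cover_causal_eqtl_variants(small_config, small_truth):
    variants = variant_table(small_config, "EUR")
    peaks = make_peaks(small_config, small_truth, variants)
    vpos = variants.set_index("variant")
    for _, row in small_truth.table.iterrows():
        for vid, _ in small_truth.weights[row.gene]:
            chrom, pos = vpos.loc[vid, "chrom"], vpos.loc[vid, "pos"]
            hit = peaks[(peaks.name == row.cell_type) & (peaks.chrom == chrom)
                        & (peaks.start <= pos - 1) & (pos - 1 < peaks.end)]
            assert len(hit) >= 1, f"{vid} not covered by a {row.cell_type} peak"


def test_gene_sets_have_at_least_two_genes(small_config, small_truth):
    sets = make_gene_sets(small_config, small_truth)
    assert all(len(g) >= 2 for g in sets.values())
    # seeded sets contain causal genes of the right stratum
    carrier = set(small_truth.causal_genes("carrier"))
    assert all(len(carrier & set(g)) >= 1 for name, g in sets.items()
               if name.startswith("CMPD_CAR"))
    # at the default study conditions each seeded set holds >=2 causal genes
    default_truth = make_truth(SimulationConfig())
    car = set(default_truth.causal_genes("carrier"))
    default_sets = make_gene_sets(SimulationConfig(), default_truth)
    assert all(len(car & set(g)) >= 2 for name, g in default_sets.items()
               if name.startswith("CMPD_CAR"))
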