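"""TWAS tests: heritability screen, weight fitting model selection, the
association kernel's algebraic identities, and assembly bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from stratwas.simulate import SimulationConfig, make_truth, simulate_cohort
from stratwas.twas import WeightSet, fit_weights, run_ctwas, screen_heritability, \
    twas_associate


def _geno(rng, n, m, maf=0.3):
    return rng.binomial(2, maf, size=(n, m)).astype(float)


class TestHeritabilityScreen:
    def test_perfect_signal_reaches_floor(self, rng):
        X = _geno(rng, 100, 10)
        p = screen_heritability(X[:, 3].copy(), X, n_perm=999, rng=rng)
        assert p == pytest.approx(1 / 1000)

    def test_constant_expression_is_null(self, rng):
        X = _geno(rng, 60, 5)
        assert screen_heritability(np.ones(60), X, rng=rng) == 1.0

    def test_zero_variants_rejected(self, rng):
        with pytest.raises(ValueError):
            screen_heritability(rng.normal(size=30), np.empty((30, 0)))

    def test_too_few_subjects_rejected(self, rng):
        X = _geno(rng, 10, 5)
        with pytest.raises(ValueError, match="20 subjects"):
            screen_heritability(rng.normal(size=10), X)


class TestFitWeights:
    def test_single_variant_signal_selects_top1(self, rng):
        X = _geno(rng, 200, 8)
        y = X[:, 2].copy()
        ws = fit_weights(y, X, [f"v{i}" for i in range(8)], "G", "Ast", 1, 100)
        assert ws.model_tag == "top1"
        nz = np.flatnonzero(ws.weights)
        assert list(nz) == [2]

    def test_polygenic_signal_prefers_ridge(self, rng):
        n, m = 300, 10
        X = _geno(rng, n, m)
        y = X.sum(axis=1) + 0.5 * rng.normal(size=n)
        ws = fit_weights(y, X, [f"v{i}" for i in range(m)], "G", "Ast", 1, 100,
                         seed=1)
        assert ws.model_tag == "ridge"
        assert np.count_nonzero(ws.weights) == m

    def test_permuted_expression_dropped(self, rng):
        """Negative control: permuting expression destroys the cis signal,
        so the gene is dropped in the large majority of replicates (the CV
        R^2 criterion is stochastic at finite n)."""
        drops = 0
        n_rep = 20
        for rep in range(n_rep):
            X = _geno(rng, 150, 8)
            y = rng.permutation(X[:, 0] + rng.normal(size=150))
            if fit_weights(y, X, [f"v{i}" for i in range(8)],
                           "G", "Ast", 1, 100, seed=rep) is None:
                drops += 1
        assert drops >= 12  # ~80% expected under the null


def _ws(variants, weights):
    return WeightSet(gene="G", cell_type="Ast", chrom=1, tss=100,
                     variants=variants, weights=np.asarray(weights, float),
                     h2_p=0.01, model_tag="top1")


class TestAssociateKernel:
    def test_single_snp_identity(self):
        w = _ws(["a", "b"], [0.0, 1.0])
        R = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        z, p = twas_associate(w, {"a": 5.0, "b": 2.5}, R)
        assert z == pytest.approx(2.5)

    def test_algebraic_oracle_three_variants(self):
        """z = R w c  =>  z_twas = c * sqrt(w'Rw)."""
        Rm = np.array([[1.0, 0.4, 0.1], [0.4, 1.0, 0.3], [0.1, 0.3, 1.0]])
        w = np.array([0.5, -0.2, 0.8])
        c = 3.0
        ids = ["a", "b", "c"]
        z = dict(zip(ids, Rm @ w * c))
        zt, _ = twas_associate(_ws(ids, w), z, pd.DataFrame(Rm, index=ids, columns=ids))
        assert zt == pytest.approx(c * np.sqrt(w @ Rm @ w), abs=1e-9)

    def test_null_scores_give_zero(self):
        w = _ws(["a", "b"], [0.3, 0.7])
        R = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        z, p = twas_associate(w, {"a": 0.0, "b": 0.0}, R)
        assert z == 0.0 and p == 1.0

    def test_degenerate_ld_returns_missing(self):
        w = _ws(["a"], [1e-9])
        R = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        z, p = twas_associate(w, {"a": 3.0}, R)
        assert np.isnan(z) and np.isnan(p)

    def test_misaligned_variants_error(self):
        w = _ws(["a", "b"], [1.0, 1.0])
        R = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(KeyError, match="b"):
            twas_associate(w, {"a": 1.0}, R)

    def test_invariance_to_permutation_and_allele_flip(self, rng):
        ids = [f"v{i}" for i in range(4)]
        A = rng.normal(size=(4, 4))
        Rm = A @ A.T
        d = np.sqrt(np.diag(Rm))
        Rm = Rm / np.outer(d, d)
        w = rng.normal(size=4)
        zv = rng.normal(size=4)
        R = pd.DataFrame(Rm, index=ids, columns=ids)
        z0, _ = twas_associate(_ws(ids, w), dict(zip(ids, zv)), R)
        # permute variant order everywhere
        perm = [2, 0, 3, 1]
        ids_p = [ids[i] for i in perm]
        Rp = R.loc[ids_p, ids_p]
        z1, _ = twas_associate(_ws(ids_p, w[perm]), dict(zip(ids, zv)), Rp)
        assert z0 == pytest.approx(z1, abs=1e-12)
        # flip allele orientation of one variant in both w and z (and R rows)
        wf = w.copy(); wf[1] = -wf[1]
        zf = zv.copy(); zf[1] = -zf[1]
        F = np.diag([1, -1, 1, 1]).astype(float)
        Rf = pd.DataFrame(F @ Rm @ F, index=ids, columns=ids)
        z2, _ = twas_associate(_ws(ids, wf), dict(zip(ids, zf)), Rf)
        assert z0 == pytest.approx(z2, abs=1e-12)


class TestAssembly:
    def test_identical_stats_give_equal_strata(self, rng):
        ids = ["1:1", "1:2", "1:3"]
        Rm = np.eye(3)
        R = {1: pd.DataFrame(Rm, index=ids, columns=ids)}
        stats = pd.DataFrame({"variant": ids, "z": [1.0, -2.0, 0.5]})
        ws = [_ws(ids, [0.2, 0.5, -0.1])]
        table = run_ctwas(ws, {"carrier": stats, "non-carrier": stats.copy()}, R)
        assert len(table) == 1
        assert table.z_carrier[0] == pytest.approx(table["z_non-carrier"][0])

    def test_no_overlap_drops_pair(self):
        ids = ["1:1"]
        R = pd.DataFrame(np.eye(1), index=ids, columns=ids)
        stats = pd.DataFrame({"variant": ["1:99"], "z": [1.0]})
        table = run_ctwas([_ws(ids, [1.0])], {"carrier": stats, "non-carrier": stats}, R)
        assert table.empty

    def test_causal_stratum_carries_larger_signal(self):
        """A carrier-specific causal gene shows |z_twas| biased to the
        carrier stratum across seeded replicates (truth weights, single
        locus, n=20,000/stratum)."""
        from stratwas.assoc import run_stratified_gwas
        wins = 0
        n_rep = 12
        for rep in range(n_rep):
            cfg = SimulationConfig(n_loci=1, n_variants=10, n_genes=1, n_causal=1,
                                   n_per_stratum=20_000, seed=100 + rep)
            truth = make_truth(cfg)
            gene = truth.table.gene.iloc[0]
            assert truth.table.causal_stratum.iloc[0] == "carrier"
            zs = {}
            for stratum in ("carrier", "non-carrier"):
                c = simulate_cohort(cfg, truth, stratum)
                stats = run_stratified_gwas(c.genotypes, c.status,
                                            c.covariates[["sex", "age"]], c.variants)
                ids = list(stats.variant)
                R = pd.DataFrame(np.corrcoef(c.genotypes, rowvar=False),
                                 index=c.variants.variant, columns=c.variants.variant)
                vw = truth.weights[gene]
                w = WeightSet(gene=gene, cell_type="Ast", chrom=1, tss=0,
                              variants=[v for v, _ in vw],
                              weights=np.array([x for _, x in vw]),
                              h2_p=0.01, model_tag="top1")
                zs[stratum], _ = twas_associate(w, stats.set_index("variant").z, R)
            if abs(zs["carrier"]) > abs(zs["non-carrier"]):
                wins += 1
        assert wins >= 0.8 * n_rep
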