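"""Heterogeneity-criteria tests: BH against the brute-force step-up, the
stratum-bias rule table, locus clustering/exclusion, and the cross-ancestry
consistency rule."""

import numpy as np
import pandas as pd
import pytest

from stratwas.stratum_filter import (annotate_heterogeneity, bh_fdr, cluster_loci,
                                     cross_ancestry_consistent, heterogeneity_flag,
                                     locus_exclusion)


def brute_force_bh(p):
    """Independent step-up: sort ascending, q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


class TestBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_degenerate_cases(self):
        assert bh_fdr([0.321])[0] == pytest.approx(0.321)
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
        assert bh_fdr([]).size == 0

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)


class TestHeterogeneityFlag:
    @pytest.mark.parametrize("q_s,z_s,p_o,z_o,expected", [
        (0.01, 2.0, 0.5, 1.0, True),      # non-significant, same direction
        (0.01, 2.0, 0.001, 3.0, False),   # significant same-direction both strata
        (0.01, 2.0, 0.001, -3.0, True),   # opposite direction
        (0.10, 2.0, 0.5, 1.0, False),     # not FDR-significant
        (0.01, 2.0, 0.5, 0.0, True),      # zero z counts as same-direction
        (0.01, 2.0, np.nan, np.nan, False),  # missing other stratum
    ])
    def test_rule_table(self, q_s, z_s, p_o, z_o, expected):
        assert heterogeneity_flag(q_s, z_s, p_o, z_o) is expected

    def test_flags_mutually_exclusive_on_pipeline_fixture(self, small_workspace):
        """No pair in the synthetic pipeline output is biased to both
        strata at once."""
        ann = pd.read_csv(small_workspace / "pairs_annotated.tsv", sep="\t")
        assert not (ann.flag_carrier & ann["flag_non-carrier"]).any()


class TestLocusClustering:
    def _pairs(self, tss_mb):
        return pd.DataFrame({"gene": [f"G{i}" for i in range(len(tss_mb))],
                             "chrom": 1, "tss": (np.array(tss_mb) * 1e6).astype(int)})

    def test_single_linkage_by_hand(self):
        ids = cluster_loci(self._pairs([1.0, 1.8, 3.5]))
        assert ids[0] == ids[1] != ids[2]

    def test_chain_links_transitively(self):
        ids = cluster_loci(self._pairs([1.0, 1.9, 2.8]))
        assert ids.nunique() == 1

    def test_single_gene_single_cluster(self):
        assert cluster_loci(self._pairs([5.0])).nunique() == 1

    def test_chromosomes_never_merge(self):
        df = self._pairs([1.0, 1.2])
        df.loc[1, "chrom"] = 2
        assert cluster_loci(df).nunique() == 2


def _locus_table(flag_top: bool):
    """Constructed 3-gene locus: top gene (smallest p) optionally biased."""
    genes = ["A", "B", "C"]
    t = pd.DataFrame({
        "gene": genes, "chrom": 1, "tss": [1_000_000, 1_200_000, 1_400_000],
        "z_carrier": [5.0, 4.0, 3.5],
        "p_carrier": [1e-7, 1e-5, 5e-4],
        "z_non-carrier": [0.5 if flag_top else 4.8, 0.4, 3.4],
        "p_non-carrier": [0.6 if flag_top else 1e-6, 0.7, 6e-4],
    })
    return t


class TestLocusExclusion:
    def test_top_gene_flagged_keeps_flagged_members(self):
        ann = annotate_heterogeneity(_locus_table(flag_top=True))
        ann["locus_id"] = cluster_loci(ann)
        out = locus_exclusion(ann)
        # A and B carrier-biased; C significant in both strata, unflagged
        assert set(out.gene) == {"A", "B"}

    def test_top_gene_unflagged_drops_entire_locus(self):
        ann = annotate_heterogeneity(_locus_table(flag_top=False))
        ann["locus_id"] = cluster_loci(ann)
        assert locus_exclusion(ann).empty

    def test_flagged_singleton_retained(self):
        t = _locus_table(flag_top=True).iloc[[0]].reset_index(drop=True)
        ann = annotate_heterogeneity(t)
        ann["locus_id"] = cluster_loci(ann)
        assert list(locus_exclusion(ann).gene) == ["A"]

    def test_never_retains_unflagged_pair(self, rng):
        n = 200
        pairs = pd.DataFrame({
            "gene": [f"G{i}" for i in range(n)], "chrom": rng.integers(1, 5, n),
            "tss": rng.integers(1, 50, n) * 10_000_00,
            "z_carrier": rng.normal(0, 3, n), "z_non-carrier": rng.normal(0, 3, n)})
        from scipy import stats as sps
        for s in ("carrier", "non-carrier"):
            pairs[f"p_{s}"] = 2 * sps.norm.sf(np.abs(pairs[f"z_{s}"]))
        ann = annotate_heterogeneity(pairs)
        ann["locus_id"] = cluster_loci(ann)
        out = locus_exclusion(ann)
        assert (out.heterogeneity_stratum != "none").all()


class TestCrossAncestry:
    NEFF = {"carrier": {"primary": 10_000, "secondary": 2_000},
            "non-carrier": {"primary": 10_000, "secondary": 2_000}}

    def _case(self, z_sec_resp, z_sec_opp=0.1):
        from scipy import stats as sps
        zp = {"carrier": 4.5, "non-carrier": 0.5}
        pp = {s: 2 * sps.norm.sf(abs(z)) for s, z in zp.items()}
        zs = {"carrier": z_sec_resp, "non-carrier": z_sec_opp}
        return zp, pp, zs

    def test_supportive_secondary_improves(self):
        zp, pp, zs = self._case(3.0)
        assert cross_ancestry_consistent(zp, pp, zs, self.NEFF, "carrier")

    def test_null_secondary_shrinks_meta(self):
        zp, pp, zs = self._case(0.0)
        assert not cross_ancestry_consistent(zp, pp, zs, self.NEFF, "carrier")

    def test_significant_opposite_stratum_fails(self):
        zp, pp, zs = self._case(3.0, z_sec_opp=5.0)
        assert not cross_ancestry_consistent(zp, pp, zs, self.NEFF, "carrier")

    def test_missing_secondary_is_false(self):
        zp, pp, _ = self._case(3.0)
        assert not cross_ancestry_consistent(zp, pp, {}, self.NEFF, "carrier")
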