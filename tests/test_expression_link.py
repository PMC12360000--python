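import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from oracles import tmm_reference
from teepi.config import Config
from teepi.effect_calling import EffectCall
from teepi.expression_link import (
    CDS,
    DOWNSTREAM,
    INTRON,
    UPSTREAM,
    UTR5,
    compute_tmm_factors,
    link_te_genes,
    positional_category,
    quadrant_counts,
    score_links,
    tmm_cpm,
    zscore,
)
from teepi.io_formats import GeneModel, GenomicInterval, TEInsertion


def _nb_matrix(rng, n_genes=50, n_samples=6):
    mu = rng.lognormal(3, 1.5, n_genes)
    return rng.negative_binomial(10, 10 / (10 + mu[:, None] * np.ones(n_samples)),
                                 size=(n_genes, n_samples))


class TestTMM:
    def test_identical_libraries_give_unit_factors(self, rng):
        col = _nb_matrix(rng)[:, 0]
        x = np.tile(col[:, None], (1, 4))
        np.testing.assert_allclose(compute_tmm_factors(x), 1.0, atol=1e-12)

    def test_pure_depth_difference_gives_unit_factors(self, rng):
        col = _nb_matrix(rng)[:, 0] + 1
        x = np.column_stack([col, 2 * col])
        np.testing.assert_allclose(compute_tmm_factors(x), 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 7, 42])
    def test_matches_independent_reference(self, seed):
        rng = np.random.default_rng(seed)
        x = _nb_matrix(rng)
        np.testing.assert_allclose(
            compute_tmm_factors(x), tmm_reference(x), atol=1e-8
        )

    def test_matches_edger_calcnormfactors(self, rng, tmp_path):
        # cross-check against the Bioconductor implementation
        x = _nb_matrix(rng)
        counts_path = tmp_path / "counts.tsv"
        np.savetxt(counts_path, x, fmt="%d", delimiter="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.table("{counts_path}"))
            d <- calcNormFactors(DGEList(counts=x), method="TMM")
            cat(sprintf("%.15f", d$samples$norm.factors), sep="\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-"], input=script, capture_output=True, text=True,
            check=True,
        )
        edger = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(compute_tmm_factors(x), edger, atol=1e-8)

    def test_unit_geometric_mean(self, rng):
        f = compute_tmm_factors(_nb_matrix(rng))
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_sample_rejected(self):
        x = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError):
            compute_tmm_factors(x)

    def test_cpm_scales_by_effective_library(self):
        counts = pd.DataFrame({"s1": [100, 900], "s2": [200, 1800]},
                              index=["g1", "g2"])
        cpm = tmm_cpm(counts, np.array([1.0, 1.0]))
        np.testing.assert_allclose(cpm["s1"], [1e5, 9e5])
        np.testing.assert_allclose(cpm["s2"], [1e5, 9e5])


class TestZscore:
    def test_equal_means_give_zero(self):
        assert zscore([5, 6, 7], [6, 6, 6]) == 0.0

    def test_textbook_arithmetic(self):
        # SE+=0.6, SE-=0.8 -> z = 2 / sqrt(0.36+0.64) = 2
        rng = np.random.default_rng(0)
        x = np.array([10 - 0.6 * np.sqrt(3), 10, 10 + 0.6 * np.sqrt(3)])
        y = np.array([8 - 0.8 * np.sqrt(3), 8, 8 + 0.8 * np.sqrt(3)])
        assert zscore(x, y) == pytest.approx(2.0)

    def test_scale_invariance(self, rng):
        x, y = rng.lognormal(2, 0.5, 6), rng.lognormal(2, 0.5, 9)
        assert zscore(10 * x, 10 * y) == pytest.approx(zscore(x, y))

    def test_antisymmetric_under_group_exchange(self, rng):
        x, y = rng.lognormal(2, 0.5, 6), rng.lognormal(2.5, 0.5, 6)
        assert zscore(x, y) == pytest.approx(-zscore(y, x))

    def test_zero_variance_unequal_means_is_infinite(self):
        assert zscore([5, 5, 5], [3, 3, 3]) == np.inf
        assert zscore([3, 3, 3], [5, 5, 5]) == -np.inf

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValueError):
            zscore([5], [3, 4])


def _gene(gid="g1", start=20_000, strand="+"):
    iv = GenomicInterval("2L", start, start + 1850, strand)
    return GeneModel(
        gid, iv,
        cds=[(start + 150, start + 600), (start + 1100, start + 1700)],
        utr5=[(start, start + 150)],
        utr3=[(start + 1700, start + 1850)],
    )


def _call(te_id="te1", spread=3.0):
    return EffectCall(te_id, "head", "H3K9me3", "enrichment", 50.0, spread, 4, 4)


class TestLinking:
    def test_gene_within_spread_is_linked(self):
        te_iv = {"te1": GenomicInterval("2L", 10_000, 10_500)}
        links = link_te_genes([_call()], {}, [_gene(start=13_000)], te_iv)
        assert len(links) == 1 and links[0].distance_bp == 2_500

    def test_gene_beyond_spread_is_not_linked(self):
        te_iv = {"te1": GenomicInterval("2L", 10_000, 10_500)}
        links = link_te_genes([_call()], {}, [_gene(start=14_001)], te_iv)
        assert links == []

    def test_no_links_for_calls_without_spread(self):
        te_iv = {"te1": GenomicInterval("2L", 10_000, 10_500)}
        assert link_te_genes([_call(spread=0.0)], {}, [_gene(start=11_000)], te_iv) == []

    @pytest.mark.parametrize(
        "te_start,te_end,expected",
        [
            (20_700, 20_800, INTRON),       # between the two CDS blocks
            (20_200, 20_300, CDS),
            (20_050, 20_100, UTR5),
            (19_000, 19_100, UPSTREAM),
            (22_500, 22_600, DOWNSTREAM),
        ],
    )
    def test_positional_category(self, te_start, te_end, expected):
        cat, approx = positional_category(
            GenomicInterval("2L", te_start, te_end), _gene()
        )
        assert cat == expected and not approx

    def test_strand_flips_upstream_downstream(self):
        cat, _ = positional_category(
            GenomicInterval("2L", 19_000, 19_100), _gene(strand="-")
        )
        assert cat == DOWNSTREAM

    def test_unstructured_gene_flagged_approximate(self):
        bare = GeneModel("g1", GenomicInterval("2L", 20_000, 21_850, "+"))
        cat, approx = positional_category(
            GenomicInterval("2L", 20_500, 20_600), bare
        )
        assert approx


class TestScoreLinks:
    @pytest.fixture()
    def scored(self, small_cohort, small_config):
        from teepi.io_formats import parse_sample_names
        from teepi.synthetic_cohort import simulate_expression

        cohort = small_cohort
        counts = simulate_expression(cohort.truth, cohort)
        meta = parse_sample_names(counts.columns)
        cpm = tmm_cpm(counts)
        tes = {te.te_id: te for te in cohort.tes}
        links = []
        for gid, (te_id, _fc) in cohort.truth.gene_links.items():
            te = tes[te_id]
            (bp, mk) = next(iter(cohort.truth.te_effects[te_id]))
            eff = cohort.truth.te_effects[te_id][(bp, mk)][0]
            from teepi.expression_link import TEGeneLink

            links.append(TEGeneLink(te_id, gid, bp, mk, eff))
        return cohort, score_links(links, cpm, meta, tes, small_config)

    def test_planted_links_score_significant_and_concordant(self, scored):
        cohort, links = scored
        sig = [l for l in links if l.significant]
        assert len(sig) >= 0.7 * len(links)
        for l in sig:
            _te, fc = cohort.truth.gene_links[l.gene_id]
            assert (l.z < 0) == (fc < 0)

    def test_quadrants_match_planted_directions(self, scored):
        _cohort, links = scored
        quads = quadrant_counts(links)
        for _, row in quads.iterrows():
            if row["mark"] == "H3K9me3" and row["effect"] == "enrichment":
                assert row["direction"] == "down"
            if row["mark"] == "H3K27ac" and row["effect"] == "enrichment":
                assert row["direction"] == "up"

    def test_replicate_averaging_mode_runs(self, scored, small_cohort, small_config):
        from teepi.io_formats import parse_sample_names
        from teepi.synthetic_cohort import simulate_expression

        cohort, links = scored
        counts = simulate_expression(cohort.truth, cohort)
        meta = parse_sample_names(counts.columns)
        cpm = tmm_cpm(counts)
        tes = {te.te_id: te for te in cohort.tes}
        out = score_links(list(links), cpm, meta, tes, small_config,
                          average_replicates_first=True)
        assert all(np.isfinite(l.z) or np.isnan(l.z) for l in out)


class TestNullZSymmetry:
    def test_mean_z_near_zero_over_many_null_genes(self, rng):
        # 10,000 genes, no planted shift, 6 vs 9 NB samples
        n = 10_000
        mu = rng.lognormal(3, 1.0, n)
        x = rng.negative_binomial(10, 10 / (10 + mu[:, None] * np.ones(6)))
        y = rng.negative_binomial(10, 10 / (10 + mu[:, None] * np.ones(9)))
        zs = np.array([zscore(x[i], y[i]) for i in range(n)])
        zs = zs[np.isfinite(zs)]
        assert abs(zs.mean()) <= 0.05
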