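import numpy as np
import pytest

from teepi.config import Config
from teepi.expression_link import zscore
from teepi.io_formats import CARRIER
from teepi.synthetic_cohort import (
    CohortSpec,
    average_replicates,
    generate_cohort,
    simulate_expression,
    simulate_signal,
)


def _spec(**kw):
    base = dict(n_te=10, n_genes=15, n_windows_per_side=5, seed=11)
    base.update(kw)
    return CohortSpec(**base)


class TestSpecValidation:
    def test_chrom_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            CohortSpec(n_te=50, chrom_length=1000)

    @pytest.mark.parametrize(
        "kw", [dict(n_strains=1), dict(replicates=1),
               dict(enrichment_percentage=-150), dict(nb_dispersion=0)]
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            _spec(**kw)


class TestGenerateCohort:
    def test_same_seed_is_byte_identical(self):
        a = generate_cohort(_spec())
        b = generate_cohort(_spec())
        assert a.genomes == b.genomes
        assert [t.presence for t in a.tes] == [t.presence for t in b.tes]
        assert a.truth.te_effects == b.truth.te_effects
        assert a.truth.breakpoints == b.truth.breakpoints

    def test_different_seed_differs(self):
        a = generate_cohort(_spec())
        b = generate_cohort(_spec(seed=12))
        assert a.genomes != b.genomes

    def test_all_tes_polymorphic_and_truth_unique(self):
        cohort = generate_cohort(_spec(n_te=50))
        assert len(cohort.tes) == 50
        assert all(te.is_polymorphic for te in cohort.tes)
        ids = [te.te_id for te in cohort.tes]
        assert len(set(ids)) == 50
        assert set(cohort.truth.te_effects) <= set(ids)

    def test_carrier_genome_contains_te_and_noncarrier_contains_junction(self):
        cohort = generate_cohort(_spec())
        te = cohort.tes[0]
        carrier, non_carrier = te.carriers[0], te.non_carriers[0]
        iv = te.interval[carrier]
        flank_up = cohort.genomes[carrier][iv.start - 200 : iv.start]
        flank_down = cohort.genomes[carrier][iv.end : iv.end + 200]
        junction = cohort.truth.breakpoints[(te.te_id, non_carrier)]
        neighborhood = cohort.genomes[non_carrier][junction - 200 : junction + 200]
        assert neighborhood == flank_up + flank_down


class TestSimulateSignal:
    def test_zero_noise_doubling(self):
        # planted +100% over 3 kb: carrier innermost median exactly 2x
        spec = _spec(signal_noise_sd=1e-9, enrichment_percentage=100.0,
                     effect_fraction=1.0)
        cohort = generate_cohort(spec, with_sequences=False)
        tracks = simulate_signal(cohort.truth, cohort)
        te = next(t for t in cohort.tes if t.te_id in cohort.truth.te_effects)
        (bp, mk), _ = next(iter(cohort.truth.te_effects[te.te_id].items()))
        carrier, non_carrier = te.carriers[0], te.non_carriers[0]
        iv = te.interval[carrier]
        car = tracks[(carrier, bp, mk, 1)].values[cohort.chrom]
        jc = cohort.truth.breakpoints[(te.te_id, non_carrier)]
        non = tracks[(non_carrier, bp, mk, 1)].values[cohort.chrom]
        car_inner = car[(iv.start // 10) - 100 : iv.start // 10]
        non_inner = non[(jc // 10) - 100 : jc // 10]
        ratio = np.median(car_inner) / np.median(non_inner)
        assert ratio == pytest.approx(2.0, rel=1e-6)

    def test_no_effect_means_same_distribution(self):
        spec = _spec(effect_fraction=0.0)
        cohort = generate_cohort(spec, with_sequences=False)
        tracks = simulate_signal(cohort.truth, cohort)
        vals = [t.values[cohort.chrom] for t in tracks.values()]
        meds = [np.median(v) for v in vals]
        assert np.ptp(meds) < 0.05  # all baseline lognormal, median ~1

    def test_measured_percentage_recovers_planted_mean(self):
        # Monte-Carlo: median-ratio estimate over many TEs ~ planted +50%
        spec = _spec(n_te=200, effect_fraction=1.0, seed=5)
        cohort = generate_cohort(spec, with_sequences=False)
        avg = average_replicates(simulate_signal(cohort.truth, cohort))
        pcts = []
        for te in cohort.tes:
            (bp, mk), (eff, pct, _s) = next(
                iter(cohort.truth.te_effects[te.te_id].items())
            )
            carrier, non_carrier = te.carriers[0], te.non_carriers[0]
            iv = te.interval[carrier]
            jc = cohort.truth.breakpoints[(te.te_id, non_carrier)]
            car = avg[(carrier, bp, mk)].values[cohort.chrom]
            non = avg[(non_carrier, bp, mk)].values[cohort.chrom]
            inner_car = np.concatenate(
                [car[iv.start // 10 - 100 : iv.start // 10],
                 car[iv.end // 10 : iv.end // 10 + 100]]
            )
            inner_non = np.concatenate(
                [non[jc // 10 - 100 : jc // 10], non[jc // 10 : jc // 10 + 100]]
            )
            pcts.append(
                100 * (np.median(inner_car) - np.median(inner_non))
                / np.median(inner_non)
            )
        assert abs(np.mean(pcts) - 50.0) < 10.0

    def test_signal_nonnegative(self, small_tracks):
        for track in small_tracks.values():
            for arr in track.values.values():
                assert np.nanmin(arr) >= 0


class TestSimulateExpression:
    def test_matrix_dimensions(self):
        spec = _spec()
        cohort = generate_cohort(spec, with_sequences=False)
        counts = simulate_expression(cohort.truth, cohort)
        n_samples = spec.n_strains * len(spec.body_parts) * spec.replicates
        assert counts.shape == (len(cohort.genes), n_samples)
        assert (counts.to_numpy() >= 0).all()

    def test_null_log2fc_gives_symmetric_zscores(self):
        # genes with no planted shift: carrier/non-carrier z symmetric about 0
        spec = _spec(n_te=10, n_genes=400, linked_gene_fraction=0.0, seed=21)
        cohort = generate_cohort(spec, with_sequences=False)
        counts = simulate_expression(cohort.truth, cohort)
        strains = list(cohort.strains)
        cols_pos = [c for c in counts.columns
                    if c.split("_")[0] in strains[:2] and "_head_" in c]
        cols_neg = [c for c in counts.columns
                    if c.split("_")[0] in strains[2:] and "_head_" in c]
        zs = [
            zscore(row[cols_pos].to_numpy(float), row[cols_neg].to_numpy(float))
            for _, row in counts.iterrows()
        ]
        zs = np.array([z for z in zs if np.isfinite(z)])
        assert abs(np.mean(zs)) < 0.12

    def test_planted_log2fc_scales_carrier_mean(self):
        # log2FC -2, tiny dispersion: carrier mean ~ quarter of non-carrier
        spec = _spec(effect_fraction=1.0, linked_gene_fraction=1.0,
                     linked_log2fc=2.0, nb_dispersion=1e-4, seed=9,
                     depletion_fraction=0.0)
        cohort = generate_cohort(spec, with_sequences=False)
        counts = simulate_expression(cohort.truth, cohort)
        checked = 0
        for gid, (te_id, log2fc) in cohort.truth.gene_links.items():
            if log2fc > 0:
                continue  # only the downregulated links here
            te = next(t for t in cohort.tes if t.te_id == te_id)
            (bp, _mk) = next(iter(cohort.truth.te_effects[te_id]))
            pos = [c for c in counts.columns
                   if c.split("_")[0] in te.carriers and f"_{bp}_" in c]
            neg = [c for c in counts.columns
                   if c.split("_")[0] in te.non_carriers and f"_{bp}_" in c]
            ratio = counts.loc[gid, pos].mean() / max(counts.loc[gid, neg].mean(), 1)
            assert ratio == pytest.approx(0.25, abs=0.08)
            checked += 1
        assert checked >= 3

    def test_deterministic_under_seed(self):
        spec = _spec()
        a = simulate_expression(
            generate_cohort(spec, with_sequences=False).truth,
            generate_cohort(spec, with_sequences=False),
        )
        b = simulate_expression(
            generate_cohort(spec, with_sequences=False).truth,
            generate_cohort(spec, with_sequences=False),
        )
        assert a.equals(b)
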