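import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from mtspike.synthetic_data import (DEFAULT_TEMPLATE, SequencingSpec,
                                    SubsetTruth, build_plates,
                                    draw_cell_heteroplasmy, emit_fastq,
                                    generate_barcodes, simulate_counts)


class TestDrawCellHeteroplasmy:
    def test_degenerate_spike_collapses_to_its_mean(self):
        t = SubsetTruth("S", "T", pi_true=1.0, mu_true=0.02, sigma_true=1e-6)
        draws = draw_cell_heteroplasmy(t, np.random.default_rng(0), size=500)
        assert np.allclose(draws, 0.02, atol=1e-4)

    def test_slab_only_is_uniform(self):
        t = SubsetTruth("S", "T", pi_true=0.0)
        draws = draw_cell_heteroplasmy(t, np.random.default_rng(1),
                                       size=100_000)
        d, _ = stats.kstest(draws, "uniform")
        assert d < 0.01

    def test_mixture_cdf_matches_quadrature(self):
        # P(Y < 0.1) = pi * F_spike(0.1) + (1-pi) * 0.1, with F_spike from
        # numerical integration of the normal pdf restricted to (0,1)
        pi, mu, sg = 0.4, 0.02, 0.05
        t = SubsetTruth("S", "T", pi_true=pi, mu_true=mu, sigma_true=sg)
        n = 100_000
        draws = draw_cell_heteroplasmy(t, np.random.default_rng(2), size=n)
        norm = integrate.quad(lambda x: stats.norm.pdf(x, mu, sg), 0, 1)[0]
        f_spike = integrate.quad(lambda x: stats.norm.pdf(x, mu, sg),
                                 0, 0.1)[0] / norm
        expected = pi * f_spike + (1 - pi) * 0.1
        observed = np.mean(draws < 0.1)
        mc_sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * mc_sd

    def test_hard_zero_spike(self):
        t = SubsetTruth("S", "T", pi_true=1.0, hard_zero=True)
        draws = draw_cell_heteroplasmy(t, np.random.default_rng(3), size=100)
        assert np.all(draws == 0.0)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            SubsetTruth("S", "T", sigma_true=0.0)


class TestSimulateCounts:
    @pytest.mark.parametrize("h,expected_alt", [(0.0, 0), (1.0, 500)])
    def test_error_free_extremes(self, h, expected_alt):
        spec = SequencingSpec(error_rate=0.0)
        rng = np.random.default_rng(0)
        depth, ref, alt = simulate_counts(h, spec, rng, depth=500)
        assert depth == 500 and alt == expected_alt and ref + alt == depth

    def test_mean_alt_fraction_matches_binomial_mean(self):
        # E[alt/depth] = h(1-e) + (1-h)e = 0.3*0.995 + 0.7*0.005 = 0.302
        spec = SequencingSpec(error_rate=0.005)
        rng = np.random.default_rng(4)
        p = 0.3 * 0.995 + 0.7 * 0.005
        reps, depth = 10_000, 1000
        alts = np.array([simulate_counts(0.3, spec, rng, depth=depth)[2]
                         for _ in range(reps)])
        mc_sd = np.sqrt(p * (1 - p) / depth / reps)
        assert abs(alts.mean() / depth - p) < 3 * mc_sd

    def test_conservation(self):
        spec = SequencingSpec()
        rng = np.random.default_rng(5)
        for h in (0.0, 0.2, 0.77, 1.0):
            depth, ref, alt = simulate_counts(h, spec, rng)
            assert ref + alt == depth and depth >= 1


class TestBuildPlates:
    def test_single_plate_layout(self):
        spec = SequencingSpec(contaminated_plate_rate=0.0)
        cohort = [SubsetTruth("S1", "naive", n_cells=95)]
        plates, truth = build_plates(cohort, spec, np.random.default_rng(0))
        assert len(plates) == 1
        cells = truth[~truth.is_negative_control]
        assert len(cells) == 95
        assert truth.is_negative_control.sum() == 1

    def test_determinism(self):
        spec = SequencingSpec(doublet_rate=0.05, contaminated_plate_rate=0.1)
        cohort = [SubsetTruth("S1", "CM", n_cells=150, pi_true=0.4)]
        _, t1 = build_plates(cohort, spec, np.random.default_rng(9))
        _, t2 = build_plates(cohort, spec, np.random.default_rng(9))
        pd.testing.assert_frame_equal(t1, t2)

    def test_doublet_count_within_binomial_noise(self):
        spec = SequencingSpec(doublet_rate=0.05, contaminated_plate_rate=0.0)
        cohort = [SubsetTruth(f"S{i}", "T", n_cells=95) for i in range(22)]
        _, truth = build_plates(cohort, spec, np.random.default_rng(6))
        cells = truth[~truth.is_negative_control]
        n = len(cells)
        assert n >= 2000
        sd = np.sqrt(n * 0.05 * 0.95)
        assert abs(cells.is_doublet.sum() - n * 0.05) < 3 * sd

    def test_counts_conserved_for_every_well(self):
        spec = SequencingSpec(doublet_rate=0.1, failed_well_rate=0.1,
                              contaminated_plate_rate=0.2)
        cohort = [SubsetTruth("S1", "T", n_cells=200)]
        _, truth = build_plates(cohort, spec, np.random.default_rng(7))
        assert (truth.ref_count + truth.alt_count == truth.depth).all()

    def test_planted_vaf_distribution_converges(self):
        # empirical planted VAF distribution vs pi*TruncNorm + (1-pi)*U
        pi, mu, sg = 0.6, 0.03, 0.04
        t = SubsetTruth("S", "T", pi_true=pi, mu_true=mu, sigma_true=sg)
        draws = draw_cell_heteroplasmy(t, np.random.default_rng(8),
                                       size=100_000)
        a, b = (0 - mu) / sg, (1 - mu) / sg
        cdf = lambda x: (pi * stats.truncnorm.cdf(x, a, b, loc=mu, scale=sg)
                         + (1 - pi) * np.clip(x, 0, 1))
        d, _ = stats.kstest(draws, cdf)
        assert d < 0.02


class TestBarcodesAndFastq:
    def test_barcode_pairwise_hamming(self):
        codes = generate_barcodes(200, 10, np.random.default_rng(0))
        arr = np.array([[c for c in code] for code in codes])
        for i in range(0, 200, 17):  # spot-check rows against all others
            d = (arr != arr[i]).sum(axis=1)
            d[i] = 99
            assert d.min() >= 3

    def test_all_variant_well_emits_only_variant_reads(self, error_free_spec,
                                                       tmp_path):
        # slab Beta(1e6, 0.01) pins every planted VAF at ~1
        cohort = [SubsetTruth("S1", "T", n_cells=3, pi_true=0.0,
                              slab=("beta", 1e6, 1e-2))]
        rng = np.random.default_rng(0)
        plates, truth = build_plates(cohort, error_free_spec, rng)
        assert (truth[~truth.is_negative_control].h_true > 0.999).all()
        fq = tmp_path / "r.fastq"
        emit_fastq(plates, truth, DEFAULT_TEMPLATE, error_free_spec, rng, fq)
        off = DEFAULT_TEMPLATE.target_offset
        bc_len = error_free_spec.barcode_length
        from mtspike.synthetic_data import reverse_complement
        lines = fq.read_text().splitlines()
        seqs = lines[1::4]
        assert seqs
        for title, seq in zip(lines[0::4], seqs):
            if title.endswith(":rc"):
                seq = reverse_complement(seq)
            assert seq[bc_len + off] == "G"

    def test_orientation_symmetry(self, tmp_path):
        spec = SequencingSpec(error_rate=0.0, doublet_rate=0.0,
                              contaminated_plate_rate=0.0,
                              reverse_orientation_prob=0.5)
        cohort = [SubsetTruth("S1", "T", n_cells=20)]
        rng = np.random.default_rng(11)
        plates, truth = build_plates(cohort, spec, rng)
        fq = tmp_path / "r.fastq"
        n = emit_fastq(plates, truth, DEFAULT_TEMPLATE, spec, rng, fq)
        titles = fq.read_text().splitlines()[0::4]
        frac_rc = sum(t.endswith(":rc") for t in titles) / n
        assert abs(frac_rc - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_template_requires_marker(self):
        from mtspike.synthetic_data import AmpliconTemplate
        with pytest.raises(ValueError, match="marker"):
            AmpliconTemplate(seq="CCCC", target_offset=1)
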