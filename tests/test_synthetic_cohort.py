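"""Generator fidelity: determinism, ladder shape, depth model, qPCR truth."""

import numpy as np
import pandas as pd
import pytest

from cffrag.core_io import read_fragment_tsv
from cffrag.qpcr_quant import fit_standard_curve
from cffrag.synthetic_cohort import (
    BIN_SIZE,
    CANINE_HEALTHY,
    CANINE_TUMOR,
    DEFAULT_CURVE,
    HUMAN,
    CnaSegment,
    LadderModel,
    SubjectTruth,
    _amplifiable_weight,
    build_reference,
    expected_short_index,
    generate_cohort,
    make_dilution_series,
    sample_fragments,
    simulate_qpcr,
)


class TestBuildReference:
    def test_deterministic_given_seed(self):
        a = build_reference(1, 1_000_000, seed=3)
        b = build_reference(1, 1_000_000, seed=3)
        assert a.contigs == b.contigs

    def test_constant_gc_profile_hits_target(self):
        g = build_reference(1, 2_000_000, gc_profile=0.5, seed=4)
        enc = g.encoded("chr1")
        for start in range(0, 2_000_000, BIN_SIZE):
            window = enc[start : start + BIN_SIZE]
            gc = ((window == 1) | (window == 2)).mean()
            assert abs(gc - 0.50) < 0.02

    def test_bin_arithmetic(self):
        g = build_reference(2, 5_000_000, seed=5)
        n_bins = sum(length // BIN_SIZE for length in g.lengths.values())
        assert n_bins == 20

    def test_too_short_contig_rejected(self):
        with pytest.raises(ValueError, match="bin width"):
            build_reference(1, 100_000, seed=0)


class TestLadderModel:
    def test_weights_must_normalize(self):
        with pytest.raises(ValueError, match="summing to 1"):
            LadderModel(weights=(0.5, 0.5, 0.5, 0.5))

    def test_modal_sizes_and_species_ordering(self, rng):
        modes = {}
        for preset in (CANINE_HEALTHY, CANINE_TUMOR, HUMAN):
            lengths = preset.ladder.sample_lengths(100_000, rng)
            counts = np.bincount(lengths, minlength=10_001)
            modes[preset.name] = int(np.argmax(counts[100:201])) + 100
        assert abs(modes["CANINE_HEALTHY"] - 153) <= 2
        assert abs(modes["CANINE_TUMOR"] - 144) <= 2
        assert modes["CANINE_TUMOR"] < modes["CANINE_HEALTHY"] < modes["HUMAN"]

    def test_comb_creates_lag10_autocorrelation_excess(self):
        def autocorr_excess(amplitude):
            pmf = LadderModel(comb_amplitude=amplitude).length_pmf()
            band = np.log(pmf[79:143])
            x = np.arange(band.size)
            band = band - np.polyval(np.polyfit(x, band, 1), x)  # detrend

            def ac(lag):
                return float(np.corrcoef(band[:-lag], band[lag:])[0, 1])

            return ac(10) - max(ac(7), ac(13))

        # with the comb on, lag 10 dominates its neighbors; with it off, the
        # residual curvature favors short lags and the excess disappears
        assert autocorr_excess(0.45) > 0.3
        assert autocorr_excess(0.0) < 0.0
        assert autocorr_excess(0.0) < autocorr_excess(0.45)


class TestDepthModel:
    def test_neutral_sample_depth_is_flat(self, toy_genome):
        subj = SubjectTruth("H1", "healthy", 0.0)
        frags, labels = sample_fragments(subj, CANINE_HEALTHY, CANINE_TUMOR,
                                         depth=500, genome=toy_genome, seed=9,
                                         apply_end_bias=False)
        assert set(labels) == {"healthy"}
        counts = np.zeros(4)
        for f in frags:
            mid = (f.start + f.end) // 2
            counts[(0 if f.chrom == "chr1" else 2) + mid // BIN_SIZE] += 1
        se = np.sqrt(counts.mean())
        assert np.all(np.abs(counts - counts.mean()) < 4 * se)

    @pytest.mark.parametrize("tf,c,expected", [(1.0, 1, 0.5), (0.4, 4, 1.4)])
    def test_cna_depth_ratio_matches_model(self, toy_genome, tf, c, expected):
        seg = [CnaSegment("chr1", 0, BIN_SIZE, c)]
        subj = SubjectTruth("C1", "cancer", tf, seg)
        frags, _ = sample_fragments(subj, CANINE_HEALTHY, CANINE_TUMOR, depth=800,
                                    genome=toy_genome, seed=10, apply_end_bias=False)
        in_seg = neutral = 0
        for f in frags:
            mid = (f.start + f.end) // 2
            if f.chrom == "chr1" and mid < BIN_SIZE:
                in_seg += 1
            elif f.chrom == "chr2":
                neutral += 1
        ratio = in_seg / (neutral / 2)
        assert ratio == pytest.approx(expected, rel=0.15)

    def test_depth_regression_recovers_slope(self):
        # observed bin depth regressed on (1-tf)*2 + tf*c: slope within 5%
        genome = build_reference(2, 5_000_000, seed=17)
        tf = 0.5
        segs = [CnaSegment("chr1", 0, 5 * BIN_SIZE, 1),
                CnaSegment("chr2", 5 * BIN_SIZE, 10 * BIN_SIZE, 4)]
        subj = SubjectTruth("C1", "cancer", tf, segs)
        depth = 2_000
        frags, _ = sample_fragments(subj, CANINE_HEALTHY, CANINE_TUMOR, depth=depth,
                                    genome=genome, seed=11, apply_end_bias=False)
        counts = {}
        for f in frags:
            mid = (f.start + f.end) // 2
            key = (f.chrom, mid // BIN_SIZE)
            counts[key] = counts.get(key, 0) + 1
        x, y = [], []
        for chrom in genome.lengths:
            for b in range(10):
                c = 2
                for seg in segs:
                    if seg.chrom == chrom and seg.start <= b * BIN_SIZE < seg.end:
                        c = seg.copy_number
                x.append((1 - tf) * 2 + tf * c)
                y.append(counts.get((chrom, b), 0))
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(depth / 2, rel=0.05)


class TestSimulateQpcr:
    def test_all_short_fragments_give_index_one(self):
        lengths = np.full(500, 99)
        table, truth = simulate_qpcr(lengths, seed=0)
        assert truth == 1.0
        assert table.loc[table["assay"] == "long", "cq"].isna().all()

    def test_amplicon_boundary_weight(self):
        assert _amplifiable_weight(np.array([598]), 598) == 1.0
        assert _amplifiable_weight(np.array([597]), 598) == 0.0
        assert _amplifiable_weight(np.array([99]), 99) == 1.0

    def test_noise_free_series_recovers_curve_exactly(self):
        series = make_dilution_series(DEFAULT_CURVE, noise_sd_cq=0.0)
        curve = fit_standard_curve(series)
        assert curve.slope == pytest.approx(DEFAULT_CURVE.slope, abs=1e-9)
        assert curve.intercept == pytest.approx(DEFAULT_CURVE.intercept, abs=1e-9)

    def test_pmf_source_matches_closed_form_truth(self):
        ladder = CANINE_HEALTHY.ladder
        _, truth = simulate_qpcr(ladder, seed=1)
        assert truth == pytest.approx(expected_short_index(ladder), abs=1e-12)

    def test_short_amplicon_must_be_shorter(self):
        with pytest.raises(ValueError, match="shorter"):
            simulate_qpcr(np.array([200]), assay_short_len=600, assay_long_len=99)


class TestGenerateCohort:
    def test_deterministic_truth_tables(self, tmp_path):
        a = generate_cohort(tmp_path / "a", n_healthy=2, n_cancer=2, depth=50, seed=7)
        b = generate_cohort(tmp_path / "b", n_healthy=2, n_cancer=2, depth=50, seed=7)
        pd.testing.assert_frame_equal(a["truth"], b["truth"])
        fa = (tmp_path / "a" / "fragments" / "H001_s1.tsv").read_bytes()
        fb = (tmp_path / "b" / "fragments" / "H001_s1.tsv").read_bytes()
        assert fa == fb

    def test_healthy_subjects_have_zero_tumor_fraction(self, cohort):
        truth = cohort["truth"]
        assert (truth.loc[truth["group"] == "healthy", "tumor_fraction"] == 0).all()

    def test_cancer_truth_short_index_exceeds_healthy_by_construction(self, tmp_path):
        info = generate_cohort(tmp_path / "c", n_healthy=4, n_cancer=4, depth=50,
                               seed=13, subject_variability=0.0)
        truth = info["truth"]
        healthy = truth.loc[truth["group"] == "healthy", "true_short_index"]
        cancer = truth.loc[truth["group"] == "cancer", "true_short_index"]
        assert cancer.min() > healthy.max()
        assert cancer.median() > healthy.median()

    def test_outputs_complete(self, cohort):
        out = cohort["outdir"]
        for name in ("reference.fa", "samples.csv", "qpcr.csv", "dilutions.csv",
                     "truth.csv", "segments.tsv"):
            assert (out / name).exists()
        for sid in cohort["samples"]["sample_id"]:
            frags = list(read_fragment_tsv(out / "fragments" / f"{sid}.tsv"))
            assert len(frags) > 0

    def test_healthy_truth_invariant_enforced(self):
        with pytest.raises(ValueError, match="tumor_fraction 0"):
            SubjectTruth("H1", "healthy", 0.2)
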