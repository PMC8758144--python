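import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clipscope import (
    GeneReadSummary,
    TranscriptModel,
    assign_read_feature,
    classify_gene,
    metagene_ecdf,
    rank_and_select,
    relative_position,
    relative_position_of_midpoint,
    summarize_gene,
)
from conftest import make_read


class TestAssignReadFeature:
    def test_read_inside_utr5(self, model_100_300_200):
        assert assign_read_feature(make_read(10, 40), model_100_300_200) == "utr5"

    def test_majority_overlap_wins(self, model_100_300_200):
        # [90,120): 13 nt in 5'-UTR+start codon, 17 nt in coding
        assert assign_read_feature(make_read(90, 120), model_100_300_200) == "coding"

    def test_tie_goes_to_five_prime_region(self):
        model = TranscriptModel("G1", "T1", len5=97, lenC=300, len3=200)
        # [95,105): 5 nt in utr5 (with start codon through 100), 5 nt in coding
        assert assign_read_feature(make_read(95, 105), model) == "utr5"

    def test_start_codon_counts_with_utr5(self, model_100_300_200):
        assert assign_read_feature(make_read(100, 103), model_100_300_200) == "utr5"

    def test_stop_codon_counts_with_coding(self, model_100_300_200):
        assert assign_read_feature(make_read(397, 400), model_100_300_200) == "coding"

    def test_out_of_bounds_read_raises(self, model_100_300_200):
        with pytest.raises(ValueError, match="outside transcript"):
            assign_read_feature(make_read(590, 620), model_100_300_200)


class TestRelativePosition:
    def test_cap_maps_to_minus_one(self, model_100_300_200):
        assert relative_position_of_midpoint(model_100_300_200, 0.0, "utr5") == -1.0

    def test_start_codon_maps_to_zero(self, model_100_300_200):
        assert relative_position_of_midpoint(model_100_300_200, 100.0, "utr5") == 0.0
        assert relative_position_of_midpoint(model_100_300_200, 100.0, "coding") == 0.0

    def test_three_prime_terminus_maps_to_two(self, model_100_300_200):
        assert relative_position_of_midpoint(model_100_300_200, 600.0, "utr3") == 2.0
        # a read on the last nucleotide sits within 1/len3 of the endpoint
        v = relative_position(make_read(599, 600), model_100_300_200)
        assert 2.0 - v <= 1.0 / model_100_300_200.len3

    def test_region_boundaries_meet(self, model_100_300_200):
        m = model_100_300_200
        assert relative_position_of_midpoint(m, 400.0, "coding") == 1.0
        assert relative_position_of_midpoint(m, 400.0, "utr3") == 1.0

    def test_zero_length_region_is_an_error(self):
        model = TranscriptModel("G", "T", len5=0, lenC=300, len3=200)
        with pytest.raises(ValueError, match="zero length"):
            relative_position_of_midpoint(model, 0.0, "utr5")

    @settings(max_examples=200, derandomize=True)
    @given(
        len5=st.integers(1, 400),
        ncodons=st.integers(2, 400),
        len3=st.integers(1, 400),
        m1=st.floats(0, 1),
        m2=st.floats(0, 1),
    )
    def test_strictly_monotone_in_midpoint(self, len5, ncodons, len3, m1, m2):
        """Within and across regions the metagene map preserves midpoint order."""
        model = TranscriptModel("G", "T", len5, 3 * ncodons, len3)
        a, b = sorted([m1 * model.length, m2 * model.length])

        def value(m):
            l5, lc = model.len5, model.lenC
            region = "utr5" if m < l5 else ("coding" if m <= l5 + lc else "utr3")
            return relative_position_of_midpoint(model, m, region)

        if a != b:
            assert value(a) <= value(b)
            if (b - a) >= 1e-6 * model.length:
                within = value(b) - value(a) > 0 or math.isclose(value(a), value(b))
                assert within


class TestEcdf:
    def test_single_position_single_step(self):
        curve = metagene_ecdf([-0.5])
        assert curve(-0.6) == 0.0 and curve(-0.5) == 1.0 and curve(0.0) == 1.0

    def test_duplicated_positions_identical_curve(self):
        a = metagene_ecdf([0.1, 0.5, 0.9])
        b = metagene_ecdf([0.1, 0.5, 0.9] * 3)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_allclose(a.y, b.y)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            metagene_ecdf([])

    def test_uniform_sample_tracks_diagonal(self):
        """ECDF of uniform positions stays below the 1% Kolmogorov-Smirnov
        critical band around F(x) = x."""
        rng = np.random.default_rng(12)
        n = 10_000
        curve = metagene_ecdf(rng.uniform(0, 1, size=n))
        dev = np.abs(curve.y - curve.x)
        dev_left = np.abs(np.concatenate([[0], curve.y[:-1]]) - curve.x)
        ks = max(dev.max(), dev_left.max())
        assert ks < 1.63 / np.sqrt(n)  # 1% critical value


class TestPooledEcdfContrast:
    """Qualitative metagene contrast: pan-uniform genes spread crosslinks
    along the transcript while 5'-UTR-peaked genes concentrate them in
    [-1, 0]."""

    @staticmethod
    def _positions(frac_peaked, seed):
        from clipscope import ReadSimConfig, preprocess_reads, simulate_parclip_reads, simulate_transcriptome

        cfg = ReadSimConfig(seed=seed, n_genes=40, reads_per_gene=300,
                            frac_utr5_peaked=frac_peaked)
        sim = simulate_transcriptome(cfg)
        reads, _ = simulate_parclip_reads(sim, cfg)
        by_tx = {}
        for r in preprocess_reads(reads):
            by_tx.setdefault(r.transcript_id, []).append(r)
        pos, geoms = [], []
        for g in sim.truth.itertuples():
            m = sim.primary_model(g.gene_id)
            geoms.append((m.len5, m.lenC, m.len3))
            pos.extend(relative_position(r, m) for r in by_tx.get(m.transcript_id, []))
        return np.sort(pos), geoms

    def test_pan_uniform_matches_length_mixture_cdf(self):
        """Pooled pan positions follow the piecewise-linear CDF implied by
        the genes' own region-length fractions (uniform-in-nt law rescaled
        region by region)."""
        pos, geoms = self._positions(frac_peaked=0.0, seed=19)

        def mixture_cdf(x):
            tot = 0.0
            for l5, lc, l3 in geoms:
                L = l5 + lc + l3
                if x <= 0:
                    tot += (l5 / L) * min(1.0, x + 1)
                elif x <= 1:
                    tot += l5 / L + (lc / L) * x
                else:
                    tot += (l5 + lc) / L + (l3 / L) * min(1.0, x - 1)
            return tot / len(geoms)

        expected = np.array([mixture_cdf(x) for x in pos])
        emp = np.arange(1, len(pos) + 1) / len(pos)
        assert np.abs(emp - expected).max() < 0.03  # boundary-assignment smear

    def test_peaked_genes_concentrate_mass_in_utr5(self):
        pos, _ = self._positions(frac_peaked=1.0, seed=20)
        assert (pos <= 0).mean() >= 0.80


class TestSummarizeAndClassify:
    def _reads(self, model, n5, nC, n3):
        reads = []
        reads += [make_read(10, 30) for _ in range(n5)]
        mid = model.len5 + model.lenC // 2
        reads += [make_read(mid, mid + 20) for _ in range(nC)]
        reads += [make_read(model.length - 30, model.length - 10) for _ in range(n3)]
        return reads

    def test_density_arithmetic(self, model_100_300_200):
        s = summarize_gene(self._reads(model_100_300_200, 40, 10, 2), model_100_300_200)
        assert (s.reads5, s.readsC, s.reads3, s.total_reads) == (40, 10, 2, 52)
        assert s.dens5 == pytest.approx(0.4)
        assert s.dens3 == pytest.approx(0.01)
        assert s.ratio == pytest.approx(40.0)

    def test_no_utr3_reads_gives_infinite_ratio(self, model_100_300_200):
        s = summarize_gene(self._reads(model_100_300_200, 5, 0, 0), model_100_300_200)
        assert math.isinf(s.ratio)
        assert classify_gene(s) == "utr5_enriched"

    def test_zero_reads_unclassifiable(self, model_100_300_200):
        s = summarize_gene([], model_100_300_200)
        assert s.label == "unclassifiable" and classify_gene(s) == "unclassifiable"

    def test_missing_utr_flagged_unclassifiable(self):
        model = TranscriptModel("G", "T", len5=0, lenC=300, len3=200)
        s = summarize_gene([make_read(150, 170)], model)
        assert s.label == "unclassifiable"

    @pytest.mark.parametrize(
        "ratio,label",
        [(40.0, "utr5_enriched"), (20.0, "utr5_enriched"), (19.99, "pan_mRNA")],
    )
    def test_threshold_is_inclusive(self, ratio, label):
        s = GeneReadSummary("G", 10, 0, 1, 11, 1.0, 0.0, 1.0 / ratio, ratio)
        assert classify_gene(s, threshold=20) == label

    def test_classification_scale_invariant(self, model_100_300_200):
        base = summarize_gene(self._reads(model_100_300_200, 40, 10, 2), model_100_300_200)
        scaled = summarize_gene(self._reads(model_100_300_200, 120, 30, 6), model_100_300_200)
        assert classify_gene(base) == classify_gene(scaled)


class TestRankAndSelect:
    def _summary(self, gid, total, dens5):
        return GeneReadSummary(gid, total, 0, 0, total, dens5, 0.0, 0.1, dens5 / 0.1)

    def test_minimum_total_reads_boundary(self):
        ss = [self._summary(f"G{t}", t, 1.0) for t in (99, 100, 101)]
        assert len(rank_and_select(ss, top_n=10)) == 2

    def test_short_list_returns_all_with_warning(self, caplog):
        ss = [self._summary(f"G{i}", 200, 1.0 + i) for i in range(300)]
        with caplog.at_level("WARNING"):
            out = rank_and_select(ss, top_n=500)
        assert len(out) == 300
        assert any("qualify" in rec.message for rec in caplog.records)

    def test_sorted_by_density_then_total(self):
        ss = [
            self._summary("GA", 200, 2.0),
            self._summary("GB", 400, 2.0),
            self._summary("GC", 150, 5.0),
        ]
        assert rank_and_select(ss, top_n=3) == ["GC", "GB", "GA"]
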