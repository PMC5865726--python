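import numpy as np
import pytest
from scipy import stats

from rapscan.core import ChromSizes, CoverageTrack, Feature, GenomicInterval
from rapscan.occupancy import (
    DECREASE,
    INCREASE,
    NOCHANGE,
    UpDownCall,
    compare_to_background,
    decile_profile,
    decile_profiles,
    decile_updown_distribution,
    randomized_background,
    rap_updown_test,
    rap_updown_tests,
    updown_exact_p,
)

from _oracles import binom_two_sided_reference


def _track_with(sizes, chrom, strand, values, offset=0):
    track = CoverageTrack(sizes, "read_end_counts")
    vec = track.get(chrom, strand)
    vec[offset : offset + len(values)] = values
    return track


class TestDecileProfile:
    def test_constant_signal_constant_densities(self):
        sizes = ChromSizes({"c": 3_000})
        gene = Feature(GenomicInterval("c", 200, 2_600, "+"), "ORF", "g")  # body 2000
        track = _track_with(sizes, "c", "+", np.full(3_000, 3.0))
        prof = decile_profile(gene, track, trim=200)
        np.testing.assert_allclose(prof.densities, 3.0)

    def test_signal_only_in_first_decile(self):
        sizes = ChromSizes({"c": 3_000})
        gene = Feature(GenomicInterval("c", 200, 2_600, "+"), "ORF", "g")
        track = CoverageTrack(sizes, "read_end_counts")
        track.get("c", "+")[400:600] = 5.0  # first decile of the trimmed body
        prof = decile_profile(gene, track, trim=200)
        assert prof.densities[0] == pytest.approx(5.0)
        np.testing.assert_allclose(prof.densities[1:], 0.0)

    def test_minus_strand_decile_one_is_rightmost(self):
        sizes = ChromSizes({"c": 3_000})
        gene = Feature(GenomicInterval("c", 200, 2_600, "-"), "ORF", "g")
        track = CoverageTrack(sizes, "read_end_counts")
        track.get("c", "-")[2_200:2_400] = 7.0  # genomically rightmost trimmed decile
        prof = decile_profile(gene, track, trim=200)
        assert prof.densities[0] == pytest.approx(7.0)
        np.testing.assert_allclose(prof.densities[1:], 0.0)

    def test_short_gene_excluded_with_reason(self):
        sizes = ChromSizes({"c": 3_000})
        gene = Feature(GenomicInterval("c", 100, 650, "+"), "ORF", "shorty")
        track = CoverageTrack(sizes, "read_end_counts")
        with pytest.raises(ValueError, match="shorty"):
            decile_profile(gene, track, trim=200)
        profiles, excluded = decile_profiles([gene], track, trim=200)
        assert profiles == [] and excluded[0][0] == "shorty"

    def test_densities_scale_proportionally(self):
        sizes = ChromSizes({"c": 3_000})
        gene = Feature(GenomicInterval("c", 200, 2_600, "+"), "ORF", "g")
        rng = np.random.default_rng(0)
        vals = rng.poisson(2.0, 3_000).astype(float)
        p1 = decile_profile(gene, _track_with(sizes, "c", "+", vals), trim=200)
        p3 = decile_profile(gene, _track_with(sizes, "c", "+", 3 * vals), trim=200)
        np.testing.assert_allclose(p3.densities, 3 * p1.densities, rtol=1e-12)


class TestDecileRatios:
    def test_uniform_density_gives_zero_ratios(self):
        sizes = ChromSizes({"c": 3_000})
        genes = [Feature(GenomicInterval("c", 200, 2_600, "+"), "ORF", "g")]
        track = _track_with(sizes, "c", "+", np.full(3_000, 4.0))
        df = decile_updown_distribution(genes, [], track, trim=200)
        assert len(df) == 9
        np.testing.assert_allclose(df["log2_ratio"], 0.0, atol=1e-12)

    def test_halved_density_after_decile_five(self):
        sizes = ChromSizes({"c": 3_000})
        genes = [Feature(GenomicInterval("c", 200, 2_600, "+"), "ORF", "g")]
        vals = np.full(3_000, 2.0)
        vals[400 + 1_000 :] = 1.0  # halve after decile 5 of the trimmed body
        track = _track_with(sizes, "c", "+", vals)
        df = decile_updown_distribution(genes, [], track, trim=200)
        assert df.loc[df.boundary == 5, "log2_ratio"].iloc[0] == pytest.approx(1.0)

    def test_rap_harboring_flag_follows_focal_decile(self):
        sizes = ChromSizes({"c": 3_000})
        genes = [Feature(GenomicInterval("c", 200, 2_600, "+"), "ORF", "g")]
        track = _track_with(sizes, "c", "+", np.full(3_000, 4.0))
        # RAP inside decile 3 of the trimmed body ([800, 1000) genomic)
        rap = GenomicInterval("c", 850, 950, "+")
        df = decile_updown_distribution(genes, [rap], track, trim=200)
        assert df.loc[df.boundary == 3, "harbors_rap"].iloc[0]
        assert not df.loc[df.boundary == 7, "harbors_rap"].iloc[0]


class TestUpDownTest:
    def _gene_and_sizes(self):
        sizes = ChromSizes({"c": 4_000})
        gene = Feature(GenomicInterval("c", 500, 3_000, "+"), "ORF", "g")  # body 2100
        return sizes, gene

    def test_symmetric_null_is_nochange(self):
        sizes, gene = self._gene_and_sizes()
        vals = np.zeros(4_000)
        vals[700:1_700] = 0.1  # 100 counts over 1000 nt upstream
        vals[1_800:2_800] = 0.1  # 100 counts over 1000 nt downstream
        track = _track_with(sizes, "c", "+", vals)
        rap = GenomicInterval("c", 1_700, 1_800, "+")
        call = rap_updown_test(rap, gene, track, trim=200, alpha=0.01)
        assert call.call == NOCHANGE
        assert call.log2_ratio == 0.0
        assert call.p > 0.9

    def test_strong_drop_is_called_decrease(self):
        sizes, gene = self._gene_and_sizes()
        vals = np.zeros(4_000)
        vals[700:1_700] = 0.2   # n_up = 200
        vals[1_800:2_800] = 0.1  # n_down = 100
        track = _track_with(sizes, "c", "+", vals)
        rap = GenomicInterval("c", 1_700, 1_800, "+")
        call = rap_updown_test(rap, gene, track, trim=200, alpha=0.01)
        assert call.call == DECREASE
        assert call.n_up == 200 and call.n_down == 100
        assert call.p == pytest.approx(
            binom_two_sided_reference(200, 300, 1_000 / 2_000), abs=1e-12
        )
        assert call.log2_ratio == pytest.approx(1.0)

    def test_alpha_is_a_strict_threshold(self):
        sizes, gene = self._gene_and_sizes()
        vals = np.zeros(4_000)
        vals[700:1_700] = 0.2
        vals[1_800:2_800] = 0.1
        track = _track_with(sizes, "c", "+", vals)
        rap = GenomicInterval("c", 1_700, 1_800, "+")
        p = rap_updown_test(rap, gene, track, trim=200, alpha=0.5).p
        at_boundary = rap_updown_test(rap, gene, track, trim=200, alpha=p)
        assert at_boundary.call == NOCHANGE and at_boundary.log2_ratio == 0.0
        below = rap_updown_test(rap, gene, track, trim=200, alpha=p * 1.0000001)
        assert below.call == DECREASE

    def test_all_zero_counts(self):
        sizes, gene = self._gene_and_sizes()
        track = CoverageTrack(sizes, "read_end_counts")
        track.get("c", "+")
        rap = GenomicInterval("c", 1_700, 1_800, "+")
        call = rap_updown_test(rap, gene, track, trim=200)
        assert (call.p, call.call, call.log2_ratio) == (1.0, NOCHANGE, 0.0)

    def test_too_close_to_gene_edge_raises(self):
        sizes, gene = self._gene_and_sizes()
        track = CoverageTrack(sizes, "read_end_counts")
        rap = GenomicInterval("c", 710, 810, "+")  # only 10 nt upstream region
        with pytest.raises(ValueError, match="< 20"):
            rap_updown_test(rap, gene, track, trim=200)

    def test_exact_p_matches_enumeration_on_grid(self):
        for n_up, n_down, lu, ld in [
            (0, 5, 100, 100),
            (3, 3, 50, 150),
            (10, 40, 300, 700),
            (200, 100, 1_000, 1_000),
            (250, 250, 123, 456),
        ]:
            p0 = lu / (lu + ld)
            assert updown_exact_p(n_up, n_down, lu, ld) == pytest.approx(
                binom_two_sided_reference(n_up, n_up + n_down, p0), abs=1e-10
            )

    def test_minus_strand_orientation(self):
        sizes = ChromSizes({"c": 4_000})
        gene = Feature(GenomicInterval("c", 500, 3_000, "-"), "ORF", "g")
        vals = np.zeros(4_000)
        # transcription runs right->left: upstream (5') is the genomic right
        vals[1_800:2_800] = 0.2  # upstream of the RAP in transcription order
        vals[700:1_700] = 0.1
        track = _track_with(sizes, "c", "-", vals)
        rap = GenomicInterval("c", 1_700, 1_800, "-")
        call = rap_updown_test(rap, gene, track, trim=200, alpha=0.01)
        assert call.n_up == 200 and call.n_down == 100
        assert call.call == DECREASE


class TestHostAssignment:
    def test_raps_outside_trimmed_bodies_are_excluded(self, small_sizes, small_genes):
        track = CoverageTrack(small_sizes, "read_end_counts")
        for chrom in small_sizes:
            track.get(chrom, "+")
            track.get(chrom, "-")
        raps = [
            GenomicInterval("chrI", 100, 200, "+"),      # intergenic
            GenomicInterval("chrI", 550, 650, "+"),      # inside geneA but within trim
        ]
        calls, excluded = rap_updown_tests(raps, small_genes, track)
        assert calls == []
        assert len(excluded) == 2


class TestBackground:
    def test_relative_placement_is_proportional(self):
        # host body 1000 nt, RAP at relative (0.4, 0.5); a target with body
        # 1000 nt must receive it at 400..500
        sizes = ChromSizes({"c": 10_000})
        host = Feature(GenomicInterval("c", 0, 1_400, "+"), "ORF", "host")
        target = Feature(GenomicInterval("c", 2_000, 3_400, "+"), "ORF", "target")
        rng_vals = np.ones(10_000)
        track = _track_with(sizes, "c", "+", rng_vals)
        call = rap_updown_test(
            GenomicInterval("c", 600, 700, "+"), host, track, trim=200, rap_id="r0"
        )
        bg = randomized_background([call], [host, target], track, trim=200, n_per_rap=2, seed=1)
        for b in bg:
            assert (b.length_up, b.length_down) == (400, 500)

    def test_same_seed_identical_background(self, small_sizes):
        sizes = ChromSizes({"c": 50_000})
        genes = [
            Feature(GenomicInterval("c", 1_000 + 3_000 * i, 3_500 + 3_000 * i, "+"), "ORF", f"g{i}")
            for i in range(10)
        ]
        track = _track_with(sizes, "c", "+", np.ones(50_000))
        call = rap_updown_test(
            GenomicInterval("c", 2_000, 2_100, "+"), genes[0], track, trim=200, rap_id="r"
        )
        a = randomized_background([call], genes, track, n_per_rap=5, seed=42)
        b = randomized_background([call], genes, track, n_per_rap=5, seed=42)
        assert a == b


class TestCompareToBackground:
    def _calls(self, counts, ratios=None):
        out = []
        i = 0
        for cat, n in zip((INCREASE, DECREASE, NOCHANGE), counts):
            for _ in range(n):
                r = 0.0 if cat == NOCHANGE else (1.0 if cat == DECREASE else -1.0)
                if ratios is not None:
                    r = ratios[i]
                out.append(UpDownCall(f"r{i}", f"g{i}", 1, 100, 1, 100, r, 0.5, cat))
                i += 1
        return out

    def test_chi2_closed_form_example(self):
        observed = self._calls((5, 50, 45))
        background = self._calls((100, 200, 700))
        res = compare_to_background(observed, background)
        assert res.expected == pytest.approx({INCREASE: 10.0, DECREASE: 20.0, NOCHANGE: 70.0})
        expected_chi2 = 25 / 10 + 45.0 + 625 / 70
        assert res.chi2 == pytest.approx(expected_chi2, abs=1e-9)
        assert res.df == 2
        assert res.chi2_p == pytest.approx(stats.chi2.sf(expected_chi2, 2))
        assert not res.merged

    def test_identical_ratio_samples_ks_one(self):
        observed = self._calls((0, 0, 30))
        background = self._calls((0, 0, 30))
        res = compare_to_background(observed, background)
        assert res.ks_stat == 0.0
        assert res.ks_p == 1.0

    def test_small_expected_counts_merge_categories(self):
        observed = self._calls((0, 20, 10))
        background = self._calls((0, 1, 999))
        res = compare_to_background(observed, background)
        assert res.merged and res.df == 1

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_to_background([], self._calls((0, 0, 3)))
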