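import math

import numpy as np
import pytest

from strvalid.allele_call import CASEWORK_THRESHOLDS, call_alleles, count_called_alleles
from strvalid.epg_sim import (
    DEFAULT_DILUTION_LADDER_PG,
    Genotype,
    SimParams,
    read_peak_table,
    sample_genotype,
    simulate_dilution_series,
    simulate_mixture,
    simulate_population,
    simulate_profile,
    write_peak_table,
)
from strvalid.popgen import FrequencyTable


def noise_free(**kw):
    return SimParams(cv_height=0.0, **kw)


@pytest.fixture(scope="module")
def spread_genotype(full_panel):
    """Full-panel male genotype with alleles far enough apart that no
    stutter peak can land on a sibling allele."""
    calls = {}
    for loc in full_panel.loci:
        if loc.name == "AMEL":
            calls["AMEL"] = ("X", "Y")
        elif loc.is_y_only:
            calls[loc.name] = (loc.bins[0].allele_label,)
        else:
            ints = [b.allele_label for b in loc.bins if "." not in b.allele_label]
            calls[loc.name] = (ints[0], ints[-1])
    return Genotype(sample_id="spread", calls=calls)


class TestHeightModel:
    def test_noise_free_het_heights_exact(self, toy_panel):
        g = Genotype("s", {"TOYA": ("6", "9"), "TOYB": ("12", "16")})
        t = simulate_profile(g, toy_panel, noise_free(), seed=1)
        allele_peaks = [p for p in t.peaks if p.origin_tag == "allele"]
        assert len(allele_peaks) == 4
        assert all(p.height == pytest.approx(2000.0) for p in allele_peaks)

    def test_noise_free_homozygote_doubled(self, toy_panel):
        g = Genotype("s", {"TOYA": ("8", "8")})
        t = simulate_profile(g, toy_panel, noise_free(), seed=1)
        (peak,) = [p for p in t.peaks if p.origin_tag == "allele"]
        assert peak.height == pytest.approx(4000.0)

    def test_input_mass_scales_linearly(self, toy_panel):
        g = Genotype("s", {"TOYA": ("6", "9")})
        t = simulate_profile(g, toy_panel, noise_free(total_input=250.0), seed=1)
        for p in t.peaks:
            if p.origin_tag == "allele":
                assert p.height == pytest.approx(500.0)

    def test_inhibition_factor_scales(self, toy_panel):
        g = Genotype("s", {"TOYA": ("6", "9")})
        t = simulate_profile(g, toy_panel, noise_free(inhibition_factor=0.25), seed=1)
        for p in t.peaks:
            if p.origin_tag == "allele":
                assert p.height == pytest.approx(500.0)

    def test_saturation_cap(self, toy_panel):
        g = Genotype("s", {"TOYA": ("8", "8")})
        t = simulate_profile(
            g, toy_panel, noise_free(height_per_allele_at_1ng=20000.0), seed=1
        )
        assert max(p.height for p in t.peaks) == pytest.approx(30000.0)

    def test_conservation_het_hom_equal_total(self, toy_panel):
        # with cv=0 total allele-origin RFU is 2E regardless of zygosity
        params = noise_free()
        het = simulate_profile(
            Genotype("s", {"TOYA": ("6", "9")}), toy_panel, params, seed=1
        )
        hom = simulate_profile(
            Genotype("s", {"TOYA": ("8", "8")}), toy_panel, params, seed=2
        )
        tot = lambda t: sum(p.height for p in t.peaks if p.origin_tag == "allele")
        assert tot(het) == pytest.approx(tot(hom)) == pytest.approx(4000.0)


class TestDegradation:
    def test_ski_slope_log_height_decreasing_in_size(self, full_panel, spread_genotype):
        t = simulate_profile(
            spread_genotype, full_panel, noise_free(degradation_k=0.01), seed=3
        )
        peaks = sorted(
            (p for p in t.peaks if p.origin_tag == "allele"), key=lambda p: p.size
        )
        heights = [p.height for p in peaks]
        sizes = [p.size for p in peaks]
        for (s1, h1), (s2, h2) in zip(zip(sizes, heights), zip(sizes[1:], heights[1:])):
            if s2 > s1:
                assert h2 < h1

    def test_slope_recovery_within_10pct(self, full_panel, spread_genotype):
        k = 0.004
        params = SimParams(cv_height=0.05, degradation_k=k)
        xs, ys = [], []
        for i in range(50):
            t = simulate_profile(spread_genotype, full_panel, params, seed=100 + i)
            for p in t.peaks:
                if p.origin_tag == "allele":
                    xs.append(p.size)
                    ys.append(math.log(p.height))
        slope = np.polyfit(xs, ys, 1)[0]
        assert slope == pytest.approx(-k, rel=0.10)


class TestStutter:
    def test_stutter_peaks_at_exact_offsets(self, full_panel, spread_genotype):
        t = simulate_profile(spread_genotype, full_panel, SimParams(), seed=7)
        allele_sizes = {
            (p.dye, round(p.size, 3)) for p in t.peaks if p.origin_tag == "allele"
        }
        for p in t.peaks:
            if p.origin_tag == "allele":
                continue
            # find the generating parent at the implied offset
            candidates = []
            for loc in full_panel.loci:
                if loc.dye != p.dye:
                    continue
                for pos in loc.stutter_positions:
                    parent_size = round(p.size - loc.stutter_offset(pos), 3)
                    if (p.dye, parent_size) in allele_sizes:
                        candidates.append((loc.name, pos))
            assert candidates, f"stutter peak at {p.size} has no parent at a valid offset"

    def test_stutter_ratio_distribution_recovered(self, toy_panel):
        mean, sd = 7.0, 1.5
        params = noise_free(
            stutter_mean_pct={("TOYB", "minus_repeat"): mean},
            stutter_sd_pct={("TOYB", "minus_repeat"): sd},
        )
        g = Genotype("s", {"TOYB": ("14", "14")})
        ratios = []
        for i in range(1000):
            t = simulate_profile(g, toy_panel, params, seed=i)
            parent = next(p for p in t.peaks if p.origin_tag == "allele")
            stut = [p for p in t.peaks if p.origin_tag == "stutter_minus"]
            if stut:
                ratios.append(stut[0].height / parent.height * 100.0)
        se = sd / math.sqrt(len(ratios))
        assert np.mean(ratios) == pytest.approx(mean, abs=3 * se)


class TestMixtures:
    def test_zero_fraction_contributor_is_inert(self, toy_panel):
        g1 = Genotype("a", {"TOYA": ("6", "9")})
        g2 = Genotype("b", {"TOYA": ("7", "11")})
        mix = simulate_mixture([g1, g2], [1.0, 0.0], 1000.0, toy_panel, SimParams(), 5)
        solo = simulate_profile(g1, toy_panel, SimParams(), 5)
        assert mix.peaks == solo.peaks

    def test_1to1_equal_heights_noise_free(self, toy_panel):
        g1 = Genotype("a", {"TOYA": ("6", "10")})
        g2 = Genotype("b", {"TOYA": ("8", "12")})
        mix = simulate_mixture([g1, g2], [0.5, 0.5], 1000.0, toy_panel, noise_free(), 5)
        allele_peaks = [p for p in mix.peaks if p.origin_tag == "allele"]
        assert len(allele_peaks) == 4
        assert len({round(p.height, 6) for p in allele_peaks}) == 1

    def test_1to8_minor_is_eighth_of_major(self, toy_panel):
        g_minor = Genotype("m", {"TOYA": ("6", "10")})
        g_major = Genotype("M", {"TOYA": ("8", "12")})
        mix = simulate_mixture(
            [g_minor, g_major], [1 / 9, 8 / 9], 1000.0, toy_panel, noise_free(), 5
        )
        by_size = {round(p.size): p.height for p in mix.peaks if p.origin_tag == "allele"}
        minor_size = toy_panel.locus("TOYA").find_bin("6").nominal_size
        major_size = toy_panel.locus("TOYA").find_bin("8").nominal_size
        assert by_size[round(minor_size)] / by_size[round(major_size)] == pytest.approx(1 / 8)

    def test_shared_allele_stacks(self, toy_panel):
        g1 = Genotype("a", {"TOYA": ("6", "9")})
        g2 = Genotype("b", {"TOYA": ("6", "11")})
        mix = simulate_mixture([g1, g2], [0.5, 0.5], 1000.0, toy_panel, noise_free(), 5)
        shared_size = toy_panel.locus("TOYA").find_bin("6").nominal_size
        shared = next(p for p in mix.peaks if abs(p.size - shared_size) < 0.1)
        assert shared.height == pytest.approx(2000.0)  # 2 × (0.5 × 2000)

    def test_bad_fractions_rejected(self, toy_panel):
        g = Genotype("a", {"TOYA": ("6", "9")})
        with pytest.raises(ValueError, match="sum"):
            simulate_mixture([g, g], [0.6, 0.6], 1000.0, toy_panel, SimParams(), 1)


class TestDilutionSeries:
    def test_default_ladder_shape(self, toy_panel):
        g = Genotype("s", {"TOYA": ("6", "9")})
        out = simulate_dilution_series(g, toy_panel, replicates=4, seed=1)
        assert len(out) == 28  # 7 inputs × 4 replicates
        assert sorted({pg for pg, _, _ in out}, reverse=True) == list(
            DEFAULT_DILUTION_LADDER_PG
        )

    def test_single_input(self, toy_panel):
        g = Genotype("s", {"TOYA": ("6", "9")})
        out = simulate_dilution_series(g, toy_panel, inputs=[1000], replicates=4, seed=1)
        assert len(out) == 4
        assert all(pg == 1000.0 for pg, _, _ in out)

    def test_determinism(self, toy_panel):
        g = Genotype("s", {"TOYA": ("6", "9")})
        a = simulate_dilution_series(g, toy_panel, replicates=2, seed=9)
        b = simulate_dilution_series(g, toy_panel, replicates=2, seed=9)
        assert [(pg, r, t.peaks) for pg, r, t in a] == [(pg, r, t.peaks) for pg, r, t in b]

    def test_called_count_monotone_in_input(self, full_panel, control_genotype, full_params):
        means = []
        for pg in (250.0, 62.5, 15.6):
            counts = []
            for pg_, _, t in simulate_dilution_series(
                control_genotype, full_panel, inputs=[pg], replicates=20,
                params=full_params, seed=11,
            ):
                prof = call_alleles(t, full_panel, CASEWORK_THRESHOLDS)
                counts.append(count_called_alleles(prof))
            means.append(np.mean(counts))
        assert means[0] >= means[1] >= means[2]


class TestGenotypeSampling:
    def test_degenerate_single_allele_locus(self):
        freqs = FrequencyTable("t", {"L": {"12": 1.0}}, 1)
        for seed in range(5):
            g = sample_genotype(freqs, "female", seed)
            assert g.calls["L"] == ("12", "12")

    def test_heterozygosity_matches_binomial(self):
        freqs = FrequencyTable("t", {"L": {"a": 0.5, "b": 0.5}}, 1)
        n = 4000
        het = sum(
            len(set(sample_genotype(freqs, "female", s).calls["L"])) == 2
            for s in range(n)
        )
        se = math.sqrt(0.25 / n)
        assert het / n == pytest.approx(0.5, abs=3 * se)

    def test_female_has_xx_and_no_y_loci(self, full_panel, full_freqs):
        g = sample_genotype(full_freqs, "female", 3, panel=full_panel)
        assert g.calls["AMEL"] == ("X", "X")
        assert "DYS391" not in g.calls and "Yindel" not in g.calls

    def test_male_has_haploid_y_calls(self, full_panel, full_freqs):
        g = sample_genotype(full_freqs, "male", 3, panel=full_panel)
        assert g.calls["AMEL"] == ("X", "Y")
        assert len(g.calls["DYS391"]) == 1 and len(g.calls["Yindel"]) == 1

    def test_unnormalized_frequencies_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            FrequencyTable("t", {"L": {"a": 0.6, "b": 0.6}}, 1)


class TestPopulationAndIO:
    def test_population_shape_and_determinism(self, toy_panel):
        freqs = FrequencyTable(
            "t", {"TOYA": {"6": 0.3, "8": 0.4, "11": 0.3}}, 1
        )
        pop1 = simulate_population(freqs, 5, toy_panel, seed=2)
        pop2 = simulate_population(freqs, 5, toy_panel, seed=2)
        assert len(pop1) == 5
        assert [t.peaks for _, t in pop1] == [t.peaks for _, t in pop2]

    def test_adding_samples_preserves_earlier_streams(self, toy_panel):
        freqs = FrequencyTable("t", {"TOYA": {"6": 0.5, "9": 0.5}}, 1)
        small = simulate_population(freqs, 3, toy_panel, seed=2)
        big = simulate_population(freqs, 6, toy_panel, seed=2)
        assert [t.peaks for _, t in small] == [t.peaks for _, t in big[:3]]

    def test_peak_table_csv_round_trip(self, toy_panel, tmp_path):
        g = Genotype("rt", {"TOYA": ("6", "9"), "TOYC": ("8", "12")})
        t = simulate_profile(g, toy_panel, SimParams(), seed=4)
        path = tmp_path / "peaks.csv"
        write_peak_table(t, path)
        back = read_peak_table(path)
        assert back.sample_id == "rt"
        assert len(back.peaks) == len(t.peaks)
        for a, b in zip(back.peaks, t.peaks):
            assert a.dye == b.dye and a.origin_tag == b.origin_tag
            assert a.size == pytest.approx(b.size, abs=1e-3)
            assert a.height == pytest.approx(b.height, abs=1e-3)

    def test_missing_column_is_named(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,dye,size_nt\nx,6-FAM,100\n")
        with pytest.raises(ValueError, match="height_rfu"):
            read_peak_table(p)
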