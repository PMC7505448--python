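"""MS2 assignment: fragment matching, hypergeometric score, run merging."""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evlipid.lipid_library import (
    LipidLibrary,
    LipidSpecies,
    precursor_mz,
    predict_fragments,
)
from evlipid.ms2_assignment import (
    Ms2Spectrum,
    Peak,
    assign_spectrum,
    hypergeometric_score,
    match_fragments,
    merge_iterative_runs,
    read_mgf,
    review_table,
    write_mgf,
)


def spectrum_from(species_name, polarity="positive", adduct=None, extra=(), rt=5.0):
    sp = LipidSpecies.parse(species_name)
    adduct = adduct or ("[M+H]+" if polarity == "positive" else "[M-H]-")
    peaks = [Peak(f.mz, 1e4) for f in predict_fragments(sp, polarity, adduct)]
    peaks += [Peak(m, i) for m, i in extra]
    return Ms2Spectrum(precursor_mz(sp, adduct), polarity, rt, peaks, title=species_name)


def brute_force_tail(n_bins, n_theo, n_peaks, k):
    """P(X >= k) by direct combinatorial enumeration."""
    total = comb(n_bins, n_peaks)
    hits = sum(comb(n_theo, j) * comb(n_bins - n_theo, n_peaks - j)
               for j in range(k, min(n_theo, n_peaks) + 1))
    return hits / total


class TestMatchFragments:
    def frag(self, mz):
        from evlipid.lipid_library import FragmentIon
        return FragmentIon("x", mz, "positive")

    def spectrum(self, mzs):
        return Ms2Spectrum(500.0, "positive", 5.0, [Peak(m, 1.0) for m in mzs])

    def test_exact_hit(self):
        n, matched = match_fragments(self.spectrum([184.0733]),
                                     [self.frag(184.0733)], 10)
        assert n == 1 and matched == [184.0733]

    def test_outside_tolerance(self):
        n, matched = match_fragments(self.spectrum([184.10]),
                                     [self.frag(184.0733)], 10)
        assert (n, matched) == (0, [])

    def test_tie_broken_by_nearest_and_order_invariant(self):
        for order in ([100.000, 100.001], [100.001, 100.000]):
            n, matched = match_fragments(self.spectrum(order),
                                         [self.frag(100.0005)], 20)
            assert n == 1
            assert matched[0] == 100.000  # equidistant tie -> lower m/z

    def test_each_peak_consumed_once(self):
        spec = self.spectrum([200.0])
        n, matched = match_fragments(spec, [self.frag(200.0), self.frag(200.0005)], 20)
        assert n == 1

    def test_empty_fragment_list(self):
        assert match_fragments(self.spectrum([100.0]), [], 10) == (0, [])


class TestHypergeometricScore:
    def test_zero_matches_scores_zero(self):
        assert hypergeometric_score(100, 10, 10, 0) == 0.0

    def test_worked_case(self):
        # population 10, 4 marked, 5 drawn, >=3 hits: (60 + 6)/252
        assert hypergeometric_score(10, 4, 5, 3) == \
            pytest.approx(-math.log10(66 / 252), abs=1e-9)

    @given(st.integers(2, 25), st.data())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_equals_combinatorial_enumeration(self, n_bins, data):
        n_theo = data.draw(st.integers(0, n_bins))
        n_peaks = data.draw(st.integers(0, n_bins))
        k = data.draw(st.integers(0, min(n_theo, n_peaks)))
        expected = 0.0 if k == 0 else -math.log10(
            brute_force_tail(n_bins, n_theo, n_peaks, k))
        assert hypergeometric_score(n_bins, n_theo, n_peaks, k) == \
            pytest.approx(expected, abs=1e-9)

    def test_monotone_in_matches(self):
        scores = [hypergeometric_score(50, 8, 12, k) for k in range(9)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_precondition_errors(self):
        with pytest.raises(ValueError):
            hypergeometric_score(10, 11, 5, 1)
        with pytest.raises(ValueError):
            hypergeometric_score(10, 4, 5, 5)


class TestAssignSpectrum:
    def test_noise_free_round_trip_top_hit(self, library):
        spec = spectrum_from("PC 16:0/18:1")
        results = assign_spectrum(spec, library)
        assert results and results[0].species.name == "PC 16:0/18:1"

    def test_far_precursor_returns_empty(self, library):
        spec = Ms2Spectrum(123.456, "positive", 5.0, [Peak(100.0, 1.0)])
        assert assign_spectrum(spec, library) == []

    def test_results_sorted_by_score(self, library):
        spec = spectrum_from("PE 16:0/18:1", polarity="negative")
        results = assign_spectrum(spec, library)
        scores = [r.score for r in results]
        assert scores == sorted(scores, reverse=True)
        assert results[0].species.name == "PE 16:0/18:1"

    def test_invariant_to_peak_order_and_intensity_scale(self, library):
        spec = spectrum_from("SM d18:1/16:0")
        shuffled = Ms2Spectrum(spec.precursor_mz, spec.polarity, spec.retention_time,
                               list(reversed([Peak(p.mz, p.intensity * 1000)
                                              for p in spec.peaks])))
        a = assign_spectrum(spec, library)
        b = assign_spectrum(shuffled, library)
        assert [(r.species.name, r.score) for r in a] == \
               [(r.species.name, r.score) for r in b]

    def test_decoy_peaks_do_not_displace_top_hit(self, library):
        rng = np.random.default_rng(42)
        extra = [(float(rng.uniform(100, 850)), float(rng.uniform(1e3, 1e5)))
                 for _ in range(50)]
        spec = spectrum_from("PC 16:0/18:1", extra=extra)
        results = assign_spectrum(spec, library)
        assert results[0].species.name == "PC 16:0/18:1"

    def test_empty_library_is_error(self):
        spec = spectrum_from("PC 16:0/18:1")
        with pytest.raises(ValueError):
            assign_spectrum(spec, LipidLibrary([]))

    def test_review_table_lists_top_candidates(self, library):
        spec = spectrum_from("PC 16:0/18:1")
        table = review_table({"s1": assign_spectrum(spec, library)})
        assert list(table["rank"][:1]) == [1]
        assert table.iloc[0]["species"] == "PC 16:0/18:1"
        assert set(table.columns) >= {"spectrum", "score", "n_matched", "matched_mz"}


class TestMergeRuns:
    def make(self, mz, rt, n_peaks, run):
        peaks = [Peak(100.0 + i, 1.0) for i in range(n_peaks)]
        return Ms2Spectrum(mz, "positive", rt, peaks, run_id=run)

    def test_disjoint_runs_union(self):
        runs = [[self.make(500 + 10 * r + i, 5.0, 3, r) for i in range(3)]
                for r in range(4)]
        assert len(merge_iterative_runs(runs)) == 12

    def test_idempotent_on_duplicate_run(self):
        run = [self.make(500, 5.0, 3, 1), self.make(600, 7.0, 4, 1)]
        assert len(merge_iterative_runs([run, run])) == 2

    def test_shared_precursor_collapsed_keeping_richer(self):
        a = self.make(500.000, 5.0, 3, 1)
        b = self.make(500.001, 5.1, 6, 2)  # 2 ppm, 0.1 min away
        c = self.make(620.0, 9.0, 2, 2)
        merged = merge_iterative_runs([[a], [b, c]], precursor_tol_ppm=5,
                                      rt_window=0.2)
        assert len(merged) == 2
        kept = [s for s in merged if abs(s.precursor_mz - 500) < 1][0]
        assert len(kept.peaks) == 6

    def test_requires_at_least_one_run(self):
        with pytest.raises(ValueError):
            merge_iterative_runs([])


class TestMgfIO:
    def test_round_trip(self, tmp_path):
        spectra = [spectrum_from("PC 16:0/18:1"),
                   spectrum_from("PI 18:0/20:4", polarity="negative", rt=7.5)]
        path = tmp_path / "spectra.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert len(back) == 2
        for orig, rt in zip(spectra, back):
            assert rt.polarity == orig.polarity
            assert rt.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-5)
            assert rt.retention_time == pytest.approx(orig.retention_time, abs=1e-6)
            assert len(rt.peaks) == len(orig.peaks)
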