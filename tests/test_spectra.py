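"""Spectrum container, integer binning, normalization, padding and MSP I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aminospec.spectra import (
    MspParseError,
    Spectrum,
    bin_to_integer,
    normalize,
    pad_pair,
    read_msp,
    strip_zeros,
    write_msp,
)
from conftest import make_spectrum

peak_dicts = st.dictionaries(
    keys=st.integers(min_value=0, max_value=800),
    values=st.floats(min_value=1e-6, max_value=1e4, allow_nan=False),
    min_size=1,
    max_size=40,
)


class TestSpectrumInvariants:
    def test_rejects_all_zero(self):
        with pytest.raises(ValueError):
            Spectrum(peaks={50: 0.0})

    def test_rejects_negative_intensity(self):
        with pytest.raises(ValueError):
            Spectrum(peaks={50: -1.0})

    def test_rejects_negative_mz(self):
        with pytest.raises(ValueError):
            Spectrum(peaks={-5: 10.0})

    def test_peaks_sorted_by_mz(self):
        s = make_spectrum({90: 1.0, 30: 2.0, 60: 3.0})
        assert list(s.peaks) == [30, 60, 90]


class TestBinToInteger:
    @pytest.mark.parametrize(
        "peaks, expected",
        [
            ({59.9: 100.0, 60.2: 50.0}, {60: 150.0}),   # collision sums
            ({75.0: 310.0}, {75: 310.0}),               # integer input unchanged
            ({60.5: 10.0}, {61: 10.0}),                 # half-up rounding
        ],
    )
    def test_examples(self, peaks, expected):
        assert bin_to_integer(make_spectrum(peaks)).peaks == expected

    @given(peaks=st.dictionaries(
        keys=st.floats(min_value=0, max_value=1000, allow_nan=False),
        values=st.floats(min_value=1e-6, max_value=1e6, allow_nan=False),
        min_size=1, max_size=50,
    ))
    @settings(max_examples=100, deadline=None)
    def test_conserves_total_intensity(self, peaks):
        s = make_spectrum(peaks)
        binned = bin_to_integer(s)
        assert math.isclose(sum(binned.peaks.values()), sum(s.peaks.values()), rel_tol=1e-9)
        assert binned.has_integer_mz()


class TestNormalize:
    def test_base_peak_100(self):
        s = normalize(make_spectrum({50: 20.0, 60: 80.0}), "base_peak_100")
        assert s.peaks == {50: 25.0, 60: 100.0}

    def test_sum_to_one(self):
        s = normalize(make_spectrum({50: 20.0, 60: 80.0}), "sum_to_one")
        assert s.peaks[50] == pytest.approx(0.2)
        assert abs(sum(s.peaks.values()) - 1.0) < 1e-12

    @given(peaks=peak_dicts, mode=st.sampled_from(["base_peak_100", "sum_to_one"]))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, peaks, mode):
        once = normalize(make_spectrum(peaks), mode)
        twice = normalize(once, mode)
        for mz in once.peaks:
            assert twice.peaks[mz] == pytest.approx(once.peaks[mz], rel=1e-12)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            normalize(make_spectrum({50: 1.0}), "minmax")


class TestPadPair:
    def test_grid_covers_both_and_starts_at_zero(self):
        pair = pad_pair(make_spectrum({50: 100.0}), make_spectrum({60: 100.0}))
        assert pair.n == 61
        assert pair.observed[50] == 100.0
        assert pair.observed.sum() == 100.0
        assert pair.predicted[60] == 100.0

    def test_symmetric_length(self):
        a, b = make_spectrum({50: 1.0, 120: 3.0}), make_spectrum({200: 2.0})
        assert pad_pair(a, b).n == pad_pair(b, a).n == 201

    @given(a=peak_dicts, b=peak_dicts)
    @settings(max_examples=50, deadline=None)
    def test_strip_zeros_recovers_peak_sets(self, a, b):
        pair = pad_pair(make_spectrum(a), make_spectrum(b))
        assert strip_zeros(pair.observed) == pytest.approx(
            {k: v for k, v in a.items() if v != 0})
        assert strip_zeros(pair.predicted) == pytest.approx(
            {k: v for k, v in b.items() if v != 0})

    def test_fractional_mz_rejected(self):
        with pytest.raises(ValueError, match="fractional"):
            pad_pair(make_spectrum({50.4: 1.0}), make_spectrum({60: 1.0}))


class TestMspIO:
    def test_reads_basic_record(self, tmp_path):
        f = tmp_path / "one.msp"
        f.write_text("Name: glycine\nNum Peaks: 2\n30 999\n75 310\n")
        (s,) = read_msp(f)
        assert s.compound_id == "glycine"
        assert s.peaks == {30: 999.0, 75: 310.0}

    def test_pairs_on_one_line_and_semicolons(self, tmp_path):
        f = tmp_path / "one.msp"
        f.write_text("Name: x\nNum Peaks: 3\n30 10; 40 20; 50 30\n")
        (s,) = read_msp(f)
        assert s.peaks == {30: 10.0, 40: 20.0, 50: 30.0}

    def test_declared_count_mismatch_is_error(self, tmp_path):
        f = tmp_path / "bad.msp"
        f.write_text("Name: broken\nNum Peaks: 3\n30 999\n75 310\n")
        with pytest.raises(MspParseError, match="broken"):
            read_msp(f)

    def test_negative_intensity_is_error(self, tmp_path):
        f = tmp_path / "bad.msp"
        f.write_text("Name: neg\nNum Peaks: 1\n30 -5\n")
        with pytest.raises(MspParseError, match="negative intensity"):
            read_msp(f)

    def test_unparseable_line_names_record_and_line(self, tmp_path):
        f = tmp_path / "bad.msp"
        f.write_text("Name: junk\nNum Peaks: 1\n30 abc\n")
        with pytest.raises(MspParseError, match=r"bad\.msp:3"):
            read_msp(f)

    def test_empty_file_gives_empty_list(self, tmp_path):
        f = tmp_path / "empty.msp"
        f.write_text("")
        assert read_msp(f) == []

    def test_duplicate_mz_merged_with_warning(self, tmp_path, caplog):
        f = tmp_path / "dup.msp"
        f.write_text("Name: d\nNum Peaks: 2\n30 10\n30 5\n")
        with caplog.at_level("WARNING"):
            (s,) = read_msp(f)
        assert s.peaks == {30: 15.0}
        assert "duplicate m/z" in caplog.text

    def test_unknown_header_keys_preserved(self, tmp_path):
        f = tmp_path / "x.msp"
        f.write_text("Name: x\nRetentionIndex: 1200\nNum Peaks: 1\n30 10\n")
        (s,) = read_msp(f)
        assert s.extra["RetentionIndex"] == "1200"

    def test_round_trip_identity(self, tmp_path):
        spectra = [
            Spectrum(peaks={30: 999.0, 75: 310.4567891234}, compound_id="glycine",
                     smiles="NCC(=O)O", instrument="GC-EI-TOF", derivatized=False,
                     source_library="demo", extra={"Comments": "fixture"}),
            Spectrum(peaks={51: 1.0}, compound_id="tiny"),
        ]
        f = tmp_path / "roundtrip.msp"
        write_msp(spectra, f)
        back = read_msp(f)
        assert len(back) == 2
        for orig, re_read in zip(spectra, back):
            assert re_read.peaks == orig.peaks
            assert re_read.compound_id == orig.compound_id
            assert re_read.smiles == orig.smiles
            assert re_read.extra == orig.extra

    def test_round_trip_synthetic_library(self, tmp_path):
        from aminospec.synthetic import (
            DistortionModel, SyntheticLibraryConfig, generate_paired_library,
        )
        pairs, _ = generate_paired_library(
            SyntheticLibraryConfig(n_molecules=100, seed=1), DistortionModel(level=0.4)
        )
        f = tmp_path / "lib.msp"
        write_msp([p.observed for p in pairs], f)
        back = read_msp(f)
        assert len(back) == 100
        for orig, re_read in zip((p.observed for p in pairs), back):
            assert re_read.peaks == orig.peaks
            assert re_read.compound_id == orig.compound_id

    def test_matchms_reads_our_dialect(self, tmp_path):
        """Cross-check the writer against an independent MSP reader."""
        matchms = pytest.importorskip("matchms.importing")
        spectra = [Spectrum(peaks={30: 999.0, 75: 310.0}, compound_id="glycine",
                            smiles="NCC(=O)O")]
        f = tmp_path / "x.msp"
        write_msp(spectra, f)
        (ext,) = list(matchms.load_from_msp(str(f)))
        assert np.allclose(ext.peaks.mz, [30.0, 75.0])
        assert np.allclose(ext.peaks.intensities, [999.0, 310.0])
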