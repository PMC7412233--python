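"""Record container, lead algebra, I/O round-trips, and segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mousecg import (
    BeatAnnotations,
    ECGRecord,
    RRSeries,
    derive_augmented_leads,
    derive_lead_iii,
    read_record,
    segment_record,
    write_record,
)

finite_signals = arrays(
    np.float64,
    st.integers(min_value=1, max_value=200),
    elements=st.floats(-10, 10, allow_nan=False),
)


def make_record(n=100, n_leads=3, rate=1000.0, seed=0):
    rng = np.random.default_rng(seed)
    return ECGRecord(
        signals=rng.normal(size=(n_leads, n)),
        sample_rate=rate,
        lead_labels=["I", "II", "III"][:n_leads],
    )


class TestECGRecord:
    def test_duration_and_lead_access(self):
        rec = make_record(n=2500, rate=1000.0)
        assert rec.duration_s == pytest.approx(2.5)
        assert np.shares_memory(rec.lead("II"), rec.signals[1])
        assert np.array_equal(rec.lead("II"), rec.signals[1])
        with pytest.raises(KeyError):
            rec.lead("aVR")

    def test_label_count_must_match_rows(self):
        with pytest.raises(ValueError, match="lead labels"):
            ECGRecord(np.zeros((2, 10)), 1000.0, ["I"])

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            ECGRecord(np.zeros((1, 10)), 0.0, ["I"])


class TestAnnotations:
    def test_requires_strictly_increasing(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            BeatAnnotations([10, 10, 20], "detected", 1000.0)
        with pytest.raises(ValueError, match="strictly increasing"):
            BeatAnnotations([20, 10], "detected", 1000.0)

    def test_source_vocabulary(self):
        with pytest.raises(ValueError):
            BeatAnnotations([1, 2], "guessed", 1000.0)

    def test_times(self):
        ann = BeatAnnotations([0, 500, 1000], "reference", 1000.0)
        assert np.allclose(ann.times_s, [0, 0.5, 1.0])


class TestRRSeries:
    def test_rejects_nonpositive_intervals(self):
        with pytest.raises(ValueError, match="positive"):
            RRSeries(intervals_ms=[100.0, -5.0])

    def test_anchor_alignment(self):
        with pytest.raises(ValueError, match="align"):
            RRSeries(intervals_ms=[100.0, 100.0], anchor_indices=[100])


class TestLeadAlgebra:
    def test_lead_iii_example(self):
        assert derive_lead_iii(np.array([0.2]), np.array([0.5]))[0] == pytest.approx(0.3)

    def test_augmented_example(self):
        avr, avl, avf = derive_augmented_leads(np.array([0.2]), np.array([0.5]))
        assert avr[0] == pytest.approx(-0.35)
        assert avl[0] == pytest.approx(-0.05)
        assert avf[0] == pytest.approx(0.4)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            derive_lead_iii(np.zeros(3), np.zeros(4))

    @settings(deadline=None)
    @given(finite_signals)
    def test_einthoven_identity(self, lead_ii):
        # III = II − I for any pair; with I = 0, III = II
        lead_i = 0.25 * lead_ii
        iii = derive_lead_iii(lead_i, lead_ii)
        assert np.allclose(iii, lead_ii - lead_i)
        assert np.allclose(derive_lead_iii(np.zeros_like(lead_ii), lead_ii), lead_ii)
        assert np.allclose(derive_lead_iii(lead_ii, lead_ii), 0.0)

    @settings(deadline=None)
    @given(finite_signals)
    def test_augmented_leads_sum_to_zero(self, lead_ii):
        lead_i = -0.7 * lead_ii + 0.1
        avr, avl, avf = derive_augmented_leads(lead_i, lead_ii)
        assert np.allclose(avr + avl + avf, 0.0, atol=1e-12)


class TestRecordIO:
    def test_round_trip(self, tmp_path):
        rec = make_record(n=50)
        path = tmp_path / "rec.txt"
        write_record(rec, path)
        back = read_record(path)
        assert back.sample_rate == rec.sample_rate
        assert back.lead_labels == rec.lead_labels
        assert np.allclose(back.signals, rec.signals, atol=1e-6)

    def test_csv_delimited(self, tmp_path):
        path = tmp_path / "rec.csv"
        path.write_text("# sample_rate_hz=2000\n# leads=I,II,III\n0.1,0.2,0.1\n0.0,0.1,0.1\n")
        rec = read_record(path)
        assert rec.n_leads == 3
        assert rec.sample_rate == 2000
        assert rec.n_samples == 2

    def test_missing_sample_rate(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0.1\t0.2\n")
        with pytest.raises(ValueError, match="sample_rate"):
            read_record(path)

    def test_ragged_channels(self, tmp_path):
        path = tmp_path / "ragged.txt"
        path.write_text("# sample_rate_hz=1000\n0.1\t0.2\n0.1\n")
        with pytest.raises(ValueError, match="ragged"):
            read_record(path)

    def test_non_numeric(self, tmp_path):
        path = tmp_path / "text.txt"
        path.write_text("# sample_rate_hz=1000\nhello\tworld\n")
        with pytest.raises(ValueError):
            read_record(path)

    def test_rejects_other_units(self, tmp_path):
        path = tmp_path / "volts.txt"
        path.write_text("# sample_rate_hz=1000\n# unit=V\n0.1\n")
        with pytest.raises(ValueError, match="mV"):
            read_record(path)


class TestSegmentation:
    def test_even_split(self):
        # 80 minutes at a low rate splits into four 20-minute fragments
        rec = ECGRecord(np.zeros((1, 9600)), 2.0, ["II"])  # 4800 s = 80 min
        frags = segment_record(rec, fragment_s=1200)
        assert len(frags) == 4
        assert all(f.duration_s == 1200 for f in frags)
        assert not any(f.partial for f in frags)
        assert [f.start_time for f in frags] == [0, 1200, 2400, 3600]

    def test_partial_remainder_flagged(self):
        rec = ECGRecord(np.zeros((1, 3000)), 2.0, ["II"])  # 25 min
        frags = segment_record(rec, fragment_s=1200)
        assert len(frags) == 2
        assert frags[0].duration_s == 1200 and not frags[0].partial
        assert frags[1].duration_s == 300 and frags[1].partial

    def test_short_record_single_flagged_fragment(self):
        rec = ECGRecord(np.zeros((1, 100)), 2.0, ["II"])
        frags = segment_record(rec, fragment_s=1200)
        assert len(frags) == 1 and frags[0].partial

    @settings(deadline=None, max_examples=25)
    @given(
        n=st.integers(min_value=1, max_value=5000),
        fragment_s=st.floats(min_value=0.5, max_value=30),
    )
    def test_concatenation_conserves_samples(self, n, fragment_s):
        rng = np.random.default_rng(n)
        rec = ECGRecord(rng.normal(size=(2, n)), 100.0, ["I", "II"])
        frags = segment_record(rec, fragment_s=fragment_s)
        rebuilt = np.concatenate([f.signals for f in frags], axis=1)
        assert np.array_equal(rebuilt, rec.signals)
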