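"""Log parsing, merging, and state-machine segment extraction."""

import numpy as np
import pytest

from mrlqa import LinacState, extract_segments, merge_logs, read_log_csv
from mrlqa.errors import FormatError, IntegrityError, UsageError

from conftest import dialect_row, make_run, make_sample, write_log_file


class TestReadLogCsv:
    def test_three_row_fixture_maps_states(self, tmp_path, geometry):
        rows = [
            dialect_row(40, "Intersegment"),
            dialect_row(80, "Radiation On", dose=1.0),
            dialect_row(120, "Radiation On", dose=2.0),
        ]
        samples = read_log_csv(write_log_file(tmp_path / "log.csv", rows))
        assert len(samples) == 3
        assert [s.linac_state for s in samples] == [
            LinacState.INTERSEGMENT, LinacState.RADIATION_ON, LinacState.RADIATION_ON
        ]
        assert samples[1].step_dose_mu == 1.0
        assert samples[0].y1_mm.shape == (80,)

    def test_111_on_samples_at_40ms(self, tmp_path):
        """A ~17 MU segment spans 111 samples = 4400 ms at the 40 ms period."""
        rows = [dialect_row(40 * (k + 1), "Radiation On", dose=17.2 * (k + 1) / 111)
                for k in range(111)]
        samples = read_log_csv(write_log_file(tmp_path / "log.csv", rows))
        assert len(samples) == 111
        assert samples[-1].time_ms - samples[0].time_ms == pytest.approx(110 * 40.0)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(FormatError):
            read_log_csv(p)

    def test_header_only(self, tmp_path):
        p = write_log_file(tmp_path / "h.csv", [])
        with pytest.raises(FormatError, match="no samples"):
            read_log_csv(p)

    def test_missing_column_named(self, tmp_path):
        rows = [dialect_row(40)]
        p = write_log_file(tmp_path / "log.csv", rows)
        text = p.read_text().replace("step_dose_mu", "stepdose")
        p.write_text(text)
        with pytest.raises(FormatError, match="step_dose_mu"):
            read_log_csv(p)

    def test_unknown_state_rejected(self, tmp_path):
        rows = [dialect_row(40, "Beam Off")]
        with pytest.raises(FormatError, match="Beam Off"):
            read_log_csv(write_log_file(tmp_path / "log.csv", rows))

    def test_unparseable_numeric_reports_row(self, tmp_path):
        rows = [dialect_row(40), dialect_row(80)]
        rows[1][2] = "oops"
        with pytest.raises(FormatError, match="row 1"):
            read_log_csv(write_log_file(tmp_path / "log.csv", rows))

    def test_non_monotonic_time(self, tmp_path):
        rows = [dialect_row(80), dialect_row(40)]
        with pytest.raises(IntegrityError):
            read_log_csv(write_log_file(tmp_path / "log.csv", rows))


class TestMergeLogs:
    def test_single_file_identity(self, tmp_path):
        rows = [dialect_row(40, dose=1.0), dialect_row(80, dose=2.0)]
        p = write_log_file(tmp_path / "a.csv", rows)
        merged = merge_logs([p])
        direct = read_log_csv(p)
        assert [s.time_ms for s in merged] == [s.time_ms for s in direct]
        assert all(s.source_file == 0 for s in merged)

    def test_duplicate_file_offsets_times(self, tmp_path):
        rows = [dialect_row(40), dialect_row(80)]
        p = write_log_file(tmp_path / "a.csv", rows)
        merged = merge_logs([p, p])
        assert len(merged) == 4
        times = [s.time_ms for s in merged]
        assert all(b > a for a, b in zip(times, times[1:]))
        assert [s.source_file for s in merged] == [0, 0, 1, 1]

    def test_empty_path_list(self):
        with pytest.raises(UsageError):
            merge_logs([])


class TestExtractSegments:
    def test_two_runs_two_segments(self, geometry):
        stream = (make_run(40, 5, 5.0)
                  + [make_sample(240, LinacState.INTERSEGMENT)]
                  + make_run(280, 7, 7.0))
        segs = extract_segments(stream, geometry)
        assert [round(s.mu, 6) for s in segs] == [5.0, 7.0]
        assert [s.segment_index for s in segs] == [0, 1]
        assert segs[0].n_samples == 5 and segs[1].n_samples == 7

    def test_positions_averaged_over_run_only(self, geometry):
        """Leaf 40 jitters around 35.81 mm; the segment mean recovers it."""
        n = 111
        stream = []
        for k in range(n):
            y1 = np.full(80, -10.0)
            y1[40] = 35.81 + (0.08 if k % 2 == 0 else -0.08) * (0 if k == n - 1 else 1)
            stream.append(make_sample(40.0 * (k + 1), dose=17.2 * (k + 1) / n, y1=y1))
        (seg,) = extract_segments(stream, geometry)
        assert seg.mu == pytest.approx(17.2, abs=1e-9)
        assert seg.y1_mean_mm[40] == pytest.approx(35.81, abs=1e-9)
        assert seg.y1_sd_mm[40] == pytest.approx(0.08, abs=0.01)

    def test_zero_mu_run_dropped_with_warning(self, geometry):
        stream = make_run(40, 5, 0.0) + [make_sample(240, LinacState.INTERSEGMENT)] \
            + make_run(280, 5, 3.0)
        with pytest.warns(UserWarning, match="zero step dose"):
            segs = extract_segments(stream, geometry)
        assert len(segs) == 1 and segs[0].mu == pytest.approx(3.0)

    def test_file_boundary_interruption_merges(self, geometry):
        """A segment split across two files resumes with MU = sum of run maxima."""
        part1 = make_run(40, 5, 6.0)
        part2 = make_run(1000, 5, 4.5)
        for s in part2:
            s.source_file = 1
        segs = extract_segments(part1 + part2, geometry)
        assert len(segs) == 1
        assert segs[0].mu == pytest.approx(10.5)
        assert "merged_interruption" in segs[0].flags
        assert segs[0].n_samples == 10

    def test_no_merge_when_intersegment_between(self, geometry):
        part1 = make_run(40, 5, 6.0)
        mid = [make_sample(240, LinacState.INTERSEGMENT, source_file=1)]
        part2 = make_run(1000, 5, 4.5, source_file=1)
        segs = extract_segments(part1 + mid + part2, geometry)
        assert [round(s.mu, 6) for s in segs] == [6.0, 4.5]

    def test_no_merge_across_gantry_change(self, geometry):
        part1 = make_run(40, 5, 6.0, gantry=10.0)
        part2 = make_run(1000, 5, 4.5, gantry=50.0, source_file=1)
        segs = extract_segments(part1 + part2, geometry)
        assert len(segs) == 2

    def test_mu_conservation_over_random_streams(self, geometry):
        """Sum of segment MU equals the sum over runs of their final step dose."""
        rng = np.random.default_rng(3)
        stream, t, expected = [], 40.0, 0.0
        for _ in range(12):
            mu = float(rng.uniform(2, 20))
            n = int(rng.integers(3, 30))
            stream += make_run(t, n, mu, gantry=float(rng.uniform(0, 360)))
            t += 40.0 * n
            expected += mu
            stream.append(make_sample(t, LinacState.INTERSEGMENT))
            t += 40.0
        segs = extract_segments(stream, geometry)
        assert sum(s.mu for s in segs) == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_inserted_idle_samples(self, geometry):
        base = (make_run(40, 4, 5.0)
                + [make_sample(200, LinacState.INTERSEGMENT)]
                + make_run(240, 4, 7.0))
        padded = (make_run(40, 4, 5.0)
                  + [make_sample(200, LinacState.INTERSEGMENT),
                     make_sample(240, LinacState.MOVE_ONLY),
                     make_sample(280, LinacState.MOVE_ONLY),
                     make_sample(320, LinacState.INTERSEGMENT)]
                  + make_run(360, 4, 7.0))
        a = extract_segments(base, geometry)
        b = extract_segments(padded, geometry)
        assert [s.mu for s in a] == [s.mu for s in b]
        assert [s.n_samples for s in a] == [s.n_samples for s in b]

    def test_mean_error_shrinks_as_sqrt_n(self, geometry):
        """With sigma = 0.08 mm i.i.d. jitter and n = 111 samples, the SD of the
        per-segment mean position is sigma / sqrt(n)."""
        rng = np.random.default_rng(11)
        sigma, n, reps = 0.08, 111, 80
        errors = []
        for _ in range(reps):
            stream = []
            for k in range(n):
                y1 = np.full(80, -10.0)
                y1[40] = 35.81 + rng.normal(0, sigma)
                stream.append(make_sample(40.0 * (k + 1), dose=(k + 1) / n, y1=y1))
            (seg,) = extract_segments(stream, geometry)
            errors.append(seg.y1_mean_mm[40] - 35.81)
        se = sigma / np.sqrt(n)
        assert 0.6 * se < np.std(errors) < 1.4 * se
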