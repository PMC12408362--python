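"""Plan-vs-log deviation statistics and segment pairing."""

import numpy as np
import pytest

from mrlqa import (
    compute_deviation_report,
    leaf_max_deviation,
    leaf_rms,
    match_segments,
    mu_and_jaw_deviations,
)
from mrlqa.deviations import SegmentPair, SegmentPairing
from mrlqa.errors import PairingError
from mrlqa.log_io import DeliveredSegment
from mrlqa.plan_io import PlannedBeam, PlannedSegment


def planned(gantry=0.0, idx=0, mu=10.0, y1=None, y2=None, x1=-50.0, x2=50.0):
    return PlannedSegment(
        beam_key=gantry, segment_index=idx, mu=mu,
        y1_mm=np.full(80, -10.0) if y1 is None else np.asarray(y1, float),
        y2_mm=np.full(80, 10.0) if y2 is None else np.asarray(y2, float),
        x1_mm=x1, x2_mm=x2,
    )


def delivered(gantry=0.0, idx=0, mu=10.0, y1=None, y2=None, x1=-50.0, x2=50.0):
    return DeliveredSegment(
        beam_key=gantry, segment_index=idx, mu=mu,
        y1_mean_mm=np.full(80, -10.0) if y1 is None else np.asarray(y1, float),
        y2_mean_mm=np.full(80, 10.0) if y2 is None else np.asarray(y2, float),
        x1_mean_mm=x1, x2_mean_mm=x2, n_samples=10,
    )


def pairing_from(plan_logs):
    return SegmentPairing([SegmentPair(0, 0.0, p, l) for p, l in plan_logs])


class TestMatching:
    def test_identity_pairing(self):
        beams = [PlannedBeam(0.0, [planned(idx=i) for i in range(3)], 30.0),
                 PlannedBeam(90.0, [planned(gantry=90.0, idx=i) for i in range(2)], 20.0)]
        logs = ([delivered(gantry=0.0, idx=i) for i in range(3)]
                + [delivered(gantry=90.0, idx=3 + i) for i in range(2)])
        pairing = match_segments(beams, logs)
        assert pairing.m == 5
        assert [p.beam_index for p in pairing.pairs] == [0, 0, 0, 1, 1]

    def test_missing_segment_names_beam(self):
        beams = [PlannedBeam(0.0, [planned(idx=i) for i in range(2)], 20.0),
                 PlannedBeam(90.0, [planned(gantry=90.0, idx=i) for i in range(2)], 20.0)]
        logs = [delivered(gantry=0.0), delivered(gantry=0.0, idx=1),
                delivered(gantry=90.0, idx=2)]  # second 90 deg segment missing
        with pytest.raises(PairingError, match="90"):
            match_segments(beams, logs)

    def test_pairing_by_gantry_not_global_order(self):
        """Beams at 192 and 240 deg delivered in swapped order still pair correctly."""
        beams = [PlannedBeam(192.0, [planned(gantry=192.0, mu=5.0)], 5.0),
                 PlannedBeam(240.0, [planned(gantry=240.0, mu=7.0)], 7.0)]
        logs = [delivered(gantry=240.02, mu=7.1), delivered(gantry=191.98, idx=1, mu=5.1)]
        pairing = match_segments(beams, logs)
        by_beam = {p.beam_index: p for p in pairing.pairs}
        assert by_beam[0].log.mu == 5.1
        assert by_beam[1].log.mu == 7.1

    def test_orphan_segment_rejected(self):
        beams = [PlannedBeam(0.0, [planned()], 10.0)]
        logs = [delivered(), delivered(gantry=45.0, idx=1)]
        with pytest.raises(PairingError, match="45"):
            match_segments(beams, logs)


class TestDeviations:
    def test_identical_gives_zeros(self):
        pairing = pairing_from([(planned(), delivered())])
        mu, x1, x2 = mu_and_jaw_deviations(pairing)
        assert mu[0] == 0.0 and x1[0] == 0.0 and x2[0] == 0.0
        assert np.nanmax(leaf_rms(pairing)) == 0.0
        assert np.nanmax(leaf_max_deviation(pairing)) == 0.0

    def test_sign_convention_plan_minus_log(self):
        pairs = [(planned(mu=10.0), delivered(mu=9.7)) for _ in range(4)]
        mu, _, _ = mu_and_jaw_deviations(pairing_from(pairs))
        assert np.allclose(mu, 0.3)

    def test_two_segment_rms_of_plus_minus_one(self):
        """Deviations of +1 and -1 mm give RMS exactly 1.0 mm."""
        y1a = np.full(80, -10.0); y1a[5] = -9.0   # log - plan = +1
        y1b = np.full(80, -10.0); y1b[5] = -11.0  # log - plan = -1
        pairing = pairing_from([(planned(), delivered(y1=y1a)),
                                (planned(), delivered(y1=y1b))])
        rms = leaf_rms(pairing)
        assert rms[5] == 1.0
        mx = leaf_max_deviation(pairing)
        assert mx[5] == 1.0

    def test_max_of_mixed_deviations(self):
        y1a = np.full(80, -10.0); y1a[7] = -9.8   # +0.2
        y1b = np.full(80, -10.0); y1b[7] = -10.9  # -0.9
        pairing = pairing_from([(planned(), delivered(y1=y1a)),
                                (planned(), delivered(y1=y1b))])
        assert leaf_max_deviation(pairing)[7] == pytest.approx(0.9)

    def test_against_literal_formula(self):
        """Both leaf statistics match a direct transcription of their formulas."""
        rng = np.random.default_rng(6)
        m = 12
        dev1 = rng.normal(0, 0.5, (m, 80))
        dev2 = rng.normal(0, 0.5, (m, 80))
        pairs = []
        for j in range(m):
            pairs.append((planned(),
                          delivered(y1=np.full(80, -10.0) + dev1[j],
                                    y2=np.full(80, 10.0) + dev2[j])))
        pairing = pairing_from(pairs)
        rms = leaf_rms(pairing, exclude_closed=False)
        mx = leaf_max_deviation(pairing, exclude_closed=False)
        all_dev = np.hstack([dev1, dev2])
        np.testing.assert_allclose(rms, np.sqrt((all_dev**2).sum(axis=0) / m), atol=1e-12)
        np.testing.assert_allclose(mx, np.abs(all_dev).max(axis=0), atol=1e-12)
        assert np.all(rms <= mx + 1e-12)

    def test_rms_recovers_jitter_scale(self):
        """log = plan + N(0, sigma^2) over many segments -> leaf RMS near sigma."""
        rng = np.random.default_rng(13)
        sigma, m = 0.08, 300
        pairs = [(planned(),
                  delivered(y1=np.full(80, -10.0) + rng.normal(0, sigma, 80),
                            y2=np.full(80, 10.0) + rng.normal(0, sigma, 80)))
                 for _ in range(m)]
        rms = leaf_rms(pairing_from(pairs))
        assert 0.8 * sigma < np.median(rms) < 1.2 * sigma

    def test_bank_shift_localization(self):
        """A +1 mm systematic shift on bank Y1 shows up only in Y1 statistics."""
        rng = np.random.default_rng(14)
        sigma, m = 0.01, 50
        pairs = [(planned(),
                  delivered(y1=np.full(80, -10.0) + 1.0 + rng.normal(0, sigma, 80),
                            y2=np.full(80, 10.0) + rng.normal(0, sigma, 80)))
                 for _ in range(m)]
        rms = leaf_rms(pairing_from(pairs))
        assert np.all(np.abs(rms[:80] - 1.0) < 0.01)
        assert np.all(rms[80:] < 0.05)

    def test_closed_pair_exclusion(self):
        """Pairs closed in both plan and log are ignored; closed-in-one is kept."""
        y1p = np.full(80, -10.0); y2p = np.full(80, 10.0)
        y1p[3] = y2p[3] = 0.0                 # pair 3 closed in the plan
        y1l = y1p.copy(); y2l = y2p.copy()
        y1l[3] = 5.0; y2l[3] = 5.0            # closed in the log too, but parked elsewhere
        pairing = pairing_from([(planned(y1=y1p, y2=y2p), delivered(y1=y1l, y2=y2l))])
        rms_excl = leaf_rms(pairing, exclude_closed=True)
        assert np.isnan(rms_excl[3])          # no included segment for that leaf
        rms_incl = leaf_rms(pairing, exclude_closed=False)
        assert rms_incl[3] == pytest.approx(5.0)

    def test_report_invariant_and_summary(self):
        rng = np.random.default_rng(15)
        pairs = [(planned(),
                  delivered(mu=10.0 + rng.normal(0, 0.1),
                            y1=np.full(80, -10.0) + rng.normal(0, 0.1, 80)))
                 for _ in range(6)]
        report = compute_deviation_report(pairing_from(pairs))
        finite = np.isfinite(report.leaf_rms)
        assert np.all(report.leaf_rms[finite] <= report.leaf_max_dev[finite] + 1e-12)
        s = report.summary()
        assert s["n_segments"] == 6
        assert s["max_abs_mu_dev"] >= 0.0
        assert len(report.leaf_frame()) == 160
        assert len(report.segment_frame()) == 6
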