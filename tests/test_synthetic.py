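"""Generator contracts: fGn statistics, record structure, cohort grouping."""

from dataclasses import replace

import numpy as np
import pytest

import preictal as p


class TestFgn:
    def test_white_noise_is_uncorrelated(self):
        x = p.gen_fgn(4096, 0.5, seed=1)
        rho1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(rho1) <= 0.05

    def test_lag1_autocovariance_matches_closed_form(self):
        # gamma(1) = 2^(2H-1) - 1 for unit-variance fGn; the mean-free
        # ensemble estimator is unbiased for it (the in-sample estimator is
        # not, at this H: Var(sample mean) ~ n^(2H-2) is non-negligible)
        rng = np.random.default_rng(12345)
        acc = []
        for _ in range(200):
            x = p.gen_fgn(8192, 0.9, rng=rng)
            acc.append(np.mean(x[:-1] * x[1:]))
        assert abs(np.mean(acc) - (2 ** 0.8 - 1)) <= 0.05

    def test_seeded_reproducibility(self):
        a = p.gen_fgn(4096, 0.7, seed=1)
        b = p.gen_fgn(4096, 0.7, seed=1)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("h", [0.3, 0.5, 0.7])
    def test_marginal_moments(self, h):
        x = p.gen_fgn(8192, h, seed=2)
        # under long-range dependence the sample mean has sd ~ n^(H-1)
        assert abs(x.mean()) <= 3.0 * x.size ** (h - 1)
        assert abs(x.var() - 1.0) <= 0.1

    @pytest.mark.parametrize("bad", [dict(n=1, h=0.5), dict(n=128, h=0.0),
                                     dict(n=128, h=1.0), dict(n=128, h=-0.2)])
    def test_parameter_errors(self, bad):
        with pytest.raises(ValueError):
            p.gen_fgn(bad["n"], bad["h"], seed=0)


class TestSeizureRecord:
    def test_ictal_amplitude_dominates(self, seizure_record, default_spec):
        rec, ann = seizure_record
        x = rec.data[default_spec.dominant_channel]
        fs = rec.fs
        ictal = np.ptp(x[int(80 * fs):int(160 * fs)])
        pre = np.ptp(x[:int(80 * fs)])
        assert ictal >= 5 * pre

    def test_decimated_ictal_range_spans_reported_band(self, seizure_decimated,
                                                       default_spec):
        # after 35 Hz preprocessing the dominant-channel seizure voltage
        # should swing roughly from -769 to +1230 microvolts
        dec, _ = seizure_decimated
        x = dec.data[default_spec.dominant_channel]
        seg = x[int(80 * dec.fs):int(160 * dec.fs)]
        assert -1100 < seg.min() < -400
        assert 900 < seg.max() < 1600

    def test_annotation_echoes_spec(self, seizure_record, default_spec):
        _, ann = seizure_record
        assert ann.t_precursor == default_spec.t_precursor
        assert ann.t_onset == default_spec.t_onset
        assert ann.t_end == default_spec.t_end

    def test_determinism(self, default_spec):
        r1, a1 = p.gen_seizure_record(default_spec)
        r2, a2 = p.gen_seizure_record(default_spec)
        assert np.array_equal(r1.data, r2.data)
        assert a1 == a2

    def test_no_precursor_limit_is_statistically_flat(self):
        # h_precursor == h_baseline and no discharge: the nominal precursor
        # boundary should be invisible in the second moment
        spec = replace(p.DEFAULT_SPEC, t_precursor=79.9, h_precursor=0.9,
                       discharge_amp=0.0, n_channels=4, dominant_channel=0,
                       seed=11)
        rec, _ = p.gen_seizure_record(spec)
        fs = rec.fs
        a = rec.data[2, int(30 * fs):int(55 * fs)].var()
        b = rec.data[2, int(55 * fs):int(79.9 * fs)].var()
        assert 0.8 <= a / b <= 1.25

    @pytest.mark.parametrize("kw", [dict(t_precursor=90.0),       # after onset
                                    dict(h_baseline=1.5),
                                    dict(ictal_amp=5.0),          # below baseline
                                    dict(t_end=200.0)])           # past duration
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(ValueError):
            replace(p.DEFAULT_SPEC, **kw)


class TestCohort:
    BASE = replace(p.DEFAULT_SPEC, n_channels=2, dominant_channel=0)

    def test_grouping_and_lead_jitter(self):
        cohort = p.gen_cohort(3, 2, [30, 20, 26], seed=7, base_spec=self.BASE)
        assert len(cohort) == 3
        assert sum(len(g) for g in cohort) == 6
        for (rec, ann) in cohort[0]:
            assert abs((ann.t_onset - ann.t_precursor) - 30) <= 1.0

    def test_minimum_lead_subject(self):
        cohort = p.gen_cohort(1, 1, [19], seed=1, base_spec=self.BASE)
        (rec, ann), = cohort[0]
        assert abs((ann.t_onset - ann.t_precursor) - 19) <= 1.0

    def test_zero_trials_vacuous(self):
        cohort = p.gen_cohort(2, 0, [25, 25], seed=0, base_spec=self.BASE)
        assert sum(len(g) for g in cohort) == 0

    def test_validation(self):
        with pytest.raises(ValueError):
            p.gen_cohort(0, 2, [], seed=0)
        with pytest.raises(ValueError):
            p.gen_cohort(2, 2, [30], seed=0)
        with pytest.raises(ValueError):
            p.gen_cohort(1, 1, [90], seed=0, base_spec=self.BASE)
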