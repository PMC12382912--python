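"""Energy/nitrogen balance arithmetic and the Brouwer heat calculation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nepartition.balance import (
    BalanceRecord,
    BrouwerCoefficients,
    GasTrace,
    attd,
    de_me_values,
    heat_production,
    metabolic_weight,
    net_protein_availability,
    nitrogen_retention,
    partition,
    summarize_trace,
)


def make_record(**kw):
    base = dict(
        pig_id="p1", diet_id="T1", dmi=0.9, ge_intake=18.0, fecal_ge=2.3,
        urinary_ge=0.35, ch4_energy=0.07, n_intake=28.38, fecal_n=3.71,
        urinary_n=4.44, bw_start=28.1, bw_end=33.2,
    )
    base.update(kw)
    return BalanceRecord(**base)


class TestDigestibility:
    @pytest.mark.parametrize(
        "intake,fecal,expected",
        [
            (100.0, 0.0, 1.0),
            (100.0, 100.0, 0.0),
            # T6 crude protein N: printed 90.01%, inputs rounded to 2 dp
            (39.39, 3.94, pytest.approx(0.9001, abs=1e-3)),
        ],
    )
    def test_examples(self, intake, fecal, expected):
        assert attd(intake, fecal) == expected

    @given(
        nd=st.floats(1e-3, 1e6), nf_frac=st.floats(0, 1),
        k=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, nd, nf_frac, k):
        nf = nd * nf_frac
        assert attd(k * nd, k * nf) == pytest.approx(attd(nd, nf), rel=1e-9)

    def test_invalid_intake(self):
        with pytest.raises(ValueError):
            attd(0.0, 0.0)

    def test_excess_fecal_warns_not_clamps(self):
        with pytest.warns(UserWarning, match="negative digestibility"):
            v = attd(10.0, 12.0)
        assert v == pytest.approx(-0.2)


class TestNitrogenBalance:
    @pytest.mark.parametrize(
        "n_in,f,u,expected,tol",
        [
            (39.39, 3.94, 8.34, 27.11, 1e-12),   # T6
            (0.0, 0.0, 0.0, 0.0, 0.0),
            (28.38, 3.71, 4.44, 20.23, 1e-12),   # T1 (printed 20.22 after rounding)
        ],
    )
    def test_retention(self, n_in, f, u, expected, tol):
        assert nitrogen_retention(n_in, f, u) == pytest.approx(expected, abs=max(tol, 1e-12))

    def test_availability(self):
        # T6 prints 0.69, T1 prints 0.71
        assert net_protein_availability(39.39, 3.94, 8.34) == pytest.approx(0.6882, abs=1e-3)
        assert net_protein_availability(28.38, 3.71, 4.44) == pytest.approx(0.7128, abs=1e-3)
        assert net_protein_availability(5.0, 0.0, 0.0) == 1.0

    def test_zero_intake_rejected(self):
        with pytest.raises(ValueError):
            net_protein_availability(0.0, 0.0, 0.0)


class TestEnergyValues:
    def test_no_losses_means_de_equals_me_equals_ge(self):
        rec = make_record(fecal_ge=0.0, urinary_ge=0.0, ch4_energy=0.0, ge_intake=20.0)
        assert de_me_values(rec) == (20.0, 20.0)

    def test_hand_arithmetic(self):
        rec = make_record(ge_intake=20.0, fecal_ge=2.0, urinary_ge=0.5, ch4_energy=0.1)
        de, me = de_me_values(rec)
        assert de == pytest.approx(18.0) and me == pytest.approx(17.4)

    def test_density_requires_dmi(self):
        rec = make_record(dmi=0.0)
        with pytest.raises(ValueError):
            de_me_values(rec, per_kg_dm=True)

    def test_t1_de_density_chain(self):
        # GE 17.53 MJ/kg as-fed, DM 85.99%, ATTD(GE) 87.28% -> 17.79 MJ/kg DM
        ge_dm = 17.53 / 0.8599
        assert ge_dm * 0.8728 == pytest.approx(17.79, abs=0.01)


class TestHeatProduction:
    def test_zero(self):
        assert heat_production(0, 0, 0, 0) == 0.0

    def test_single_coefficients(self):
        assert heat_production(1, 0) == pytest.approx(16.18)
        assert heat_production(0, 1) == pytest.approx(5.02)

    def test_hand_arithmetic(self):
        assert heat_production(500, 450, 2, 8) == pytest.approx(10296.74)

    @given(
        a=st.tuples(*[st.floats(0, 1e3) for _ in range(3)], st.floats(0, 50)),
        b=st.tuples(*[st.floats(0, 1e3) for _ in range(3)], st.floats(0, 50)),
    )
    def test_linearity(self, a, b):
        s = tuple(x + y for x, y in zip(a, b))
        assert heat_production(*s) == pytest.approx(
            heat_production(*a) + heat_production(*b), rel=1e-9, abs=1e-9
        )

    def test_custom_coefficients(self):
        c = BrouwerCoefficients(c_o2=10.0, c_co2=0.0, c_ch4=0.0, c_un=0.0)
        assert heat_production(2.0, 5.0, coef=c) == pytest.approx(20.0)


class TestTraceSummary:
    def make_trace(self, n_fed=288, n_fasted=96, o2=1.5, rq=1.0):
        n = n_fed + n_fasted
        return GasTrace(
            pig_id="p1",
            time_min=5.0 * np.arange(n),
            o2=np.full(n, o2),
            co2=np.full(n, rq * o2),
            ch4=np.zeros(n),
            fed=np.arange(n) < n_fed,
        )

    def test_constant_trace_closed_form(self):
        tr = self.make_trace()
        s = summarize_trace(tr, urinary_n=8.0)
        expected = (16.18 * 1.5 + 5.02 * 1.5) * 288 - 5.99 * 8.0
        assert s.thp == pytest.approx(expected, rel=1e-12)
        assert s.fhp == pytest.approx(expected, rel=1e-12)
        assert (s.n_fed, s.n_fasted) == (288, 96)

    def test_no_fasted_window_reports_absent(self):
        tr = self.make_trace(n_fasted=0)
        assert summarize_trace(tr).fhp is None

    def test_all_fasted_rejected(self):
        tr = self.make_trace(n_fed=0, n_fasted=96)
        with pytest.raises(ValueError):
            summarize_trace(tr)

    def test_trace_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            GasTrace("p", [0, 0], [1, 1], [1, 1], [0, 0], [True, True])
        with pytest.raises(ValueError, match=">= 0"):
            GasTrace("p", [0, 5], [-1, 1], [1, 1], [0, 0], [True, True])


class TestPartition:
    def test_metabolic_weight(self):
        assert metabolic_weight(1.0) == 1.0
        assert metabolic_weight(32.0) == pytest.approx(8.0)
        assert metabolic_weight(30.72) == pytest.approx(7.8064, abs=1e-4)
        with pytest.raises(ValueError):
            metabolic_weight(0.0)

    def test_t6_protein_deposition(self):
        # NR 27.11 g/d at BW 30.72 kg -> 517.88, printed 518.03
        pd = 27.11 * 6.25 * 23.86 / 30.72 ** 0.6
        assert pd == pytest.approx(518.03, abs=0.5)

    def test_identities_and_t1_ld(self):
        # RE - PD = LD: 890.09 - 386.42 = 503.67 vs printed 503.66
        assert 890.09 - 386.42 == pytest.approx(503.66, abs=0.02)
        rec = make_record()
        p = partition(rec, thp=9000.0, fhp=6500.0)
        assert p.mei == pytest.approx(p.thp + p.re, abs=1e-9)
        assert p.re == pytest.approx(p.pd + p.ld, abs=1e-9)
        assert p.hi == pytest.approx(p.thp - p.fhp, abs=1e-9)
        assert p.pd_free_ne == pytest.approx((p.mei - p.hi) - p.pd, abs=1e-9)

    def test_zero_retention_zero_deposition(self):
        rec = make_record(n_intake=8.15, fecal_n=3.71, urinary_n=4.44,
                          urinary_ge=0.0, ch4_energy=0.0)
        me = rec.ge_intake - rec.fecal_ge
        p = partition(rec, thp=me * 1000.0, fhp=me * 1000.0 - 100.0)
        assert p.pd == pytest.approx(0.0, abs=1e-9)
        assert p.re == pytest.approx(0.0, abs=1e-9)
        assert p.ld == pytest.approx(0.0, abs=1e-9)

    def test_thp_below_fhp_warns(self):
        with pytest.warns(UserWarning, match="THP"):
            partition(make_record(), thp=5000.0, fhp=6000.0)

    def test_record_validation(self):
        with pytest.raises(ValueError, match="body weights"):
            make_record(bw_start=0.0)
        with pytest.raises(ValueError, match="fecal GE"):
            make_record(fecal_ge=30.0)
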