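import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sulforasim.physio_model import (
    AbsorptionElimination,
    CompartmentLayout,
    DomainError,
    GutConversion,
    ModelParams,
    MouthKinetics,
    ProductSpec,
    StateLayout,
    TransitParams,
    gastric_rate_constant,
    gut_conversion_rates,
    initial_state,
    make_jacobian,
    make_rhs,
    mouth_hydrolysis_rate,
    mouth_split,
    rhs,
    total_amount,
    transfer_rate,
    update_params,
)

TABLE_MOUTH = MouthKinetics(vmax=2070.0, km=110.2, ki=893.0, srr=0.357)
HIGHBP = ProductSpec("HighBP", myr=3.49e-2, cgl0=383.3, itc0=354.2, br=5000.0)


class TestGastricRateConstant:
    def test_st_30(self):
        # closed form -ln(0.05)/30 evaluated independently
        assert gastric_rate_constant(30.0) == pytest.approx(0.09985774245179969)

    def test_identity_case(self):
        assert gastric_rate_constant(-math.log(0.05)) == pytest.approx(1.0)

    @given(st.floats(min_value=1e-3, max_value=1e4))
    def test_defining_property(self, st_min):
        s = gastric_rate_constant(st_min)
        assert math.exp(-s * st_min) == pytest.approx(0.05, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(DomainError):
            gastric_rate_constant(bad)


class TestMouthHydrolysis:
    def test_zero_substrate(self):
        assert mouth_hydrolysis_rate(0.0, TABLE_MOUTH, HIGHBP) == 0.0

    def test_reference_values(self):
        # direct scalar evaluation of the rate law with tabulated constants
        c = 383.3
        expected = (2070.0 * 3.49e-2 * 5000.0 * c) / (110.2 + c + c * c / 893.0)
        got = mouth_hydrolysis_rate(c, TABLE_MOUTH, HIGHBP)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(2.104e5, rel=1e-3)

    def test_unimodal_max_at_sqrt_km_ki(self):
        grid = np.linspace(1.0, 2000.0, 40000)
        rates = [mouth_hydrolysis_rate(c, TABLE_MOUTH, HIGHBP) for c in grid]
        c_star = grid[int(np.argmax(rates))]
        assert c_star == pytest.approx(math.sqrt(110.2 * 893.0), rel=1e-3)
        # unimodality: increasing then decreasing
        d = np.diff(rates)
        switch = np.flatnonzero(np.diff(np.sign(d)))
        assert len(switch) == 1

    def test_negative_substrate_rejected(self):
        with pytest.raises(DomainError):
            mouth_hydrolysis_rate(-1.0, TABLE_MOUTH, HIGHBP)


class TestMouthSplit:
    @pytest.mark.parametrize(
        "rate,srr,expected",
        [
            (10.0, 1.0, (10.0, 0.0)),
            (10.0, 0.0, (0.0, 10.0)),
            (8.0, 0.357, (2.856, 5.144)),
        ],
    )
    def test_examples(self, rate, srr, expected):
        sr, nit = mouth_split(rate, srr)
        assert sr == pytest.approx(expected[0])
        assert nit == pytest.approx(expected[1])

    @given(
        st.floats(min_value=0, max_value=1e6),
        st.floats(min_value=0, max_value=1),
    )
    def test_partition_property(self, rate, srr):
        sr, nit = mouth_split(rate, srr)
        assert sr + nit == pytest.approx(rate, rel=1e-12, abs=1e-12)
        assert sr >= 0 and nit >= 0

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_srr_out_of_range(self, bad):
        with pytest.raises(DomainError):
            mouth_split(1.0, bad)


class TestTransferRate:
    def test_equal_volumes(self):
        assert transfer_rate(50.0, 0.1, 0.25, 0.25) == pytest.approx(5.0)

    def test_amount_conservation_bookkeeping(self):
        # upstream loses k*c = 5 uM/min in 0.25 L -> 1.25 umol/min;
        # downstream gains 2.5 uM/min in 0.5 L -> 1.25 umol/min
        inflow = transfer_rate(50.0, 0.1, 0.25, 0.5)
        assert inflow == pytest.approx(2.5)
        assert inflow * 0.5 == pytest.approx(0.1 * 50.0 * 0.25)

    def test_zero_concentration(self):
        assert transfer_rate(0.0, 0.1, 1.0, 1.0) == 0.0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(DomainError):
            transfer_rate(1.0, 0.1, 0.0, 1.0)


class TestGutConversion:
    def test_zero_substrate(self):
        assert gut_conversion_rates(0.0, GutConversion(0.0033, 0.0015)) == (0, 0, 0)

    def test_fixed_high_product_constants(self):
        sr, eni, loss = gut_conversion_rates(100.0, GutConversion(0.0033, 0.0015))
        assert (sr, eni, loss) == pytest.approx((0.33, 0.15, 0.48))

    def test_longrun_conversion_fraction(self):
        # independent oracle: integrate the two-sink linear ODE to t -> inf
        from scipy.integrate import solve_ivp

        k_f, k_eni, c0 = 0.02, 0.05, 100.0
        sol = solve_ivp(
            lambda t, y: [-(k_f + k_eni) * y[0], k_f * y[0]],
            (0, 2000),
            [c0, 0.0],
            rtol=1e-10,
            atol=1e-12,
        )
        frac = sol.y[1, -1] / c0
        assert frac == pytest.approx(k_f / (k_f + k_eni), rel=1e-6)


def _random_params(rng):
    product = ProductSpec("rand", myr=rng.uniform(0, 0.05), cgl0=rng.uniform(0, 800),
                          itc0=rng.uniform(0, 400), br=5000.0)
    return ModelParams(
        product=product,
        mouth=MouthKinetics(srr=rng.uniform(0, 1)),
        transit=TransitParams(
            k_mouth=rng.uniform(1, 60),
            k_sh=rng.uniform(0.005, 0.2),
            st=rng.uniform(10, 60),
            k_tsi=rng.uniform(0.005, 0.1),
            k_tli=rng.uniform(0.001, 0.05),
        ),
        absorb=AbsorptionElimination(k_a=rng.uniform(0, 0.5), k_e=rng.uniform(0, 0.2)),
        gut=GutConversion(k_f=rng.uniform(0, 0.1), k_eni=rng.uniform(0, 0.1)),
    )


class TestRhs:
    def test_zero_state_zero_derivative(self):
        params = ModelParams(product=HIGHBP)
        y = np.zeros(StateLayout.from_layout(params.layout).size)
        assert np.all(rhs(0.0, y, params) == 0.0)

    def test_li1_reaction_terms_isolated(self):
        # GR only in LI1, frozen transit, no absorption: pure gut kinetics
        k_f, k_eni = 0.0033, 0.0015
        params = ModelParams(
            product=ProductSpec("x", myr=0.0, cgl0=0.0, itc0=0.0),
            transit=TransitParams(k_mouth=1e-12, k_sh=1e-12, st=1e12,
                                  k_tsi=1e-12, k_tli=1e-12),
            absorb=AbsorptionElimination(k_a=0.0, k_e=0.0),
            gut=GutConversion(k_f=k_f, k_eni=k_eni),
        )
        sl = StateLayout.from_layout(params.layout)
        li1 = 4 + params.layout.n_si
        y = np.zeros(sl.size)
        y[li1] = 200.0
        dy = rhs(0.0, y, params)
        assert dy[sl.itc][li1] == pytest.approx(k_f * 200.0, rel=1e-9)
        assert dy[sl.gl][li1] == pytest.approx(-(k_f + k_eni) * 200.0, rel=1e-6)

    def test_amount_conservation_at_random_states(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            params = _random_params(rng)
            fn = make_rhs(params)
            sl = StateLayout.from_layout(params.layout)
            y = rng.uniform(0, 500, sl.size)
            dy = fn(0.0, y)
            d_total = total_amount(y + 0.5 * dy, params) - total_amount(
                y - 0.5 * dy, params
            )  # linear in state entries, so this is exactly d(total)/dt
            influx_scale = total_amount(np.abs(dy), params)
            assert abs(d_total) < 1e-10 * max(influx_scale, 1.0)

    def test_jacobian_matches_fd(self):
        rng = np.random.default_rng(3)
        params = _random_params(rng)
        fn, jac = make_rhs(params), make_jacobian(params)
        sl = StateLayout.from_layout(params.layout)
        y = rng.uniform(1.0, 300.0, sl.size)
        J = jac(0.0, y)
        eps = 1e-6
        for j in range(sl.size):
            yp, ym = y.copy(), y.copy()
            yp[j] += eps * max(y[j], 1.0)
            ym[j] -= eps * max(y[j], 1.0)
            col = (fn(0.0, yp) - fn(0.0, ym)) / (yp[j] - ym[j])
            assert np.allclose(J[:, j], col, rtol=1e-4, atol=1e-8)

    def test_dimension_mismatch_rejected(self):
        params = ModelParams(product=HIGHBP)
        with pytest.raises(ValueError, match="shape"):
            rhs(0.0, np.zeros(7), params)

    def test_initial_state_places_dose_in_mouth(self):
        params = ModelParams(product=HIGHBP)
        y0 = initial_state(params)
        sl = StateLayout.from_layout(params.layout)
        assert y0[0] == HIGHBP.cgl0
        assert y0[sl.n_gut] == HIGHBP.itc0
        assert np.count_nonzero(y0) == 2


class TestTypes:
    def test_layout_is_18_compartments(self):
        assert CompartmentLayout().n_compartments == 18

    def test_state_size(self):
        sl = StateLayout.from_layout(CompartmentLayout())
        assert sl.n_gut == 17
        assert sl.size == 39

    def test_per_compartment_volumes(self):
        lay = CompartmentLayout()
        assert lay.v_si == pytest.approx(0.25)
        assert lay.v_li == pytest.approx(3.4 / 7)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(name="", myr=1.0, cgl0=1.0, itc0=1.0),
            dict(name="x", myr=-1.0, cgl0=1.0, itc0=1.0),
        ],
    )
    def test_product_validation(self, kwargs):
        with pytest.raises(DomainError):
            ProductSpec(**kwargs)

    def test_srr_validation(self):
        with pytest.raises(DomainError):
            MouthKinetics(srr=1.5)

    def test_peff_radius_consistency(self):
        AbsorptionElimination(k_a=0.18, k_e=0.02, p_eff=0.09, radius=1.0)
        with pytest.raises(DomainError):
            AbsorptionElimination(k_a=0.2, k_e=0.02, p_eff=0.09, radius=1.0)

    def test_update_params(self):
        params = ModelParams(product=HIGHBP)
        new = update_params(params, srr=0.25, k_tsi=0.05, v_blood=4.5)
        assert new.mouth.srr == 0.25
        assert new.transit.k_tsi == 0.05
        assert new.layout.v_blood == 4.5
        assert params.mouth.srr != 0.25  # original untouched
        with pytest.raises(KeyError):
            update_params(params, nonsense=1.0)
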