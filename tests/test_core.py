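"""UEV rescaling, emergy conversion, same-origin rule, account aggregation."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st
from pydantic import ValidationError

from emfarm.core import (
    Baseline,
    EmergyFlow,
    UEVEntry,
    aggregate_account,
    flow_emergy,
    money_to_emergy,
    net_service_flow,
    rescale_uev,
    resolve_same_origin,
)


def entry(**overrides) -> UEVEntry:
    base = dict(
        resource_name="x",
        uev_value=1.2e5,
        unit_class="energy",
        source_baseline=15.83e24,
        renewability_factor=0.3,
        category="P",
    )
    base.update(overrides)
    return UEVEntry(**base)


class TestRescaleUEV:
    def test_hand_example(self):
        target = Baseline(name="t", value=12.0e24)
        rescaled = rescale_uev(entry(), target)
        assert rescaled.uev_value == pytest.approx(9.0967e4, rel=1e-4)
        assert rescaled.source_baseline == target.value

    def test_identity_when_baselines_match(self):
        e = entry(source_baseline=12.0e24)
        assert rescale_uev(e, Baseline(name="t", value=12.0e24)).uev_value == e.uev_value

    def test_linearity_in_target(self):
        e = entry()
        doubled = rescale_uev(e, Baseline(name="t", value=2 * e.source_baseline))
        assert doubled.uev_value == pytest.approx(2 * e.uev_value)


class TestFlowEmergy:
    def test_zero_quantity(self):
        flow = flow_emergy(0.0, entry())
        assert flow.total == flow.renewable == flow.nonrenewable == 0.0

    def test_hand_example(self):
        flow = flow_emergy(1e10, entry(uev_value=1e5))
        assert flow.total == pytest.approx(1e15)
        assert flow.renewable == pytest.approx(3e14)
        assert flow.nonrenewable == pytest.approx(7e14)

    def test_fully_renewable_boundary(self):
        flow = flow_emergy(5.0, entry(renewability_factor=1.0))
        assert flow.nonrenewable == 0.0

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            flow_emergy(1.0, entry(unit_class="mass"), quantity_unit="energy")

    def test_negative_quantity_rejected(self):
        with pytest.raises(ValueError):
            flow_emergy(-1.0, entry())

    @given(
        quantity=st.floats(min_value=0, max_value=1e12),
        scale=st.floats(min_value=1e-3, max_value=1e3),
        rf=st.floats(min_value=0, max_value=1),
    )
    def test_homogeneous_degree_one(self, quantity, scale, rf):
        e = entry(renewability_factor=rf)
        one = flow_emergy(quantity, e)
        scaled = flow_emergy(quantity * scale, e)
        assert scaled.total == pytest.approx(one.total * scale, rel=1e-12)

    @given(
        quantity=st.floats(min_value=1e-3, max_value=1e12),
        rf=st.floats(min_value=0, max_value=1),
        target=st.floats(min_value=1e24, max_value=3e25),
    )
    def test_rescale_commutes_with_conversion(self, quantity, rf, target):
        """Rescaling then converting equals converting then rescaling."""
        e = entry(renewability_factor=rf)
        baseline = Baseline(name="t", value=target)
        via_rescale = flow_emergy(quantity, rescale_uev(e, baseline)).total
        via_convert = flow_emergy(quantity, e).total * target / e.source_baseline
        assert via_rescale == pytest.approx(via_convert, rel=1e-12)


class TestMoneyToEmergy:
    def test_table_value(self):
        assert money_to_emergy(32_420, 1e12) == pytest.approx(3.242e16)

    def test_zero(self):
        assert money_to_emergy(0.0, 1e12) == 0.0

    def test_sign_linearity(self):
        assert money_to_emergy(-100.0, 1e12) == pytest.approx(-1e14)

    def test_nonpositive_em_euro_rejected(self):
        with pytest.raises(ValueError):
            money_to_emergy(1.0, 0.0)


def solar_flow(name: str, total: float) -> EmergyFlow:
    return EmergyFlow(
        resource_name=name,
        total=total,
        renewable=total,
        nonrenewable=0.0,
        category="R",
        origin_tag="solar_derived",
    )


class TestResolveSameOrigin:
    def test_keeps_maximum_only(self):
        flows = [
            solar_flow("sunlight", 1e14),
            solar_flow("wind_kinetic", 2e14),
            solar_flow("rain_chemical_potential", 5e14),
            solar_flow("evapotranspiration", 7e14),
        ]
        kept = resolve_same_origin(flows)
        assert [f.resource_name for f in kept] == ["evapotranspiration"]
        assert kept[0].total == 7e14

    def test_single_flow_identity(self):
        flow = solar_flow("sunlight", 3.0)
        assert resolve_same_origin([flow]) == [flow]

    def test_tie_breaks_alphabetically(self):
        kept = resolve_same_origin(
            [solar_flow("wind_kinetic", 5.0), solar_flow("sunlight", 5.0)]
        )
        assert kept[0].resource_name == "sunlight"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            resolve_same_origin([])

    def test_mixed_origins_rejected(self):
        flows = [solar_flow("sunlight", 1.0)]
        other = flows[0].model_copy(update={"origin_tag": "geothermal"})
        with pytest.raises(ValueError):
            resolve_same_origin(flows + [other])


def flow(total, rf, category, name="f"):
    return EmergyFlow(
        resource_name=name,
        total=total,
        renewable=total * rf,
        nonrenewable=total * (1 - rf),
        category=category,
    )


class TestAggregateAccount:
    def test_empty_list_is_zero_account(self):
        account = aggregate_account([])
        assert account.Y == 0.0

    def test_single_r_flow(self):
        account = aggregate_account([flow(5e15, 1.0, "R")])
        assert account.R == account.Y == 5e15
        assert account.N == account.P == account.S == 0.0

    def test_worked_account(self):
        flows = [
            flow(25e14, 1.0, "R"),
            flow(10e14, 0.0, "N"),
            flow(45e14, 5 / 45, "P"),
            flow(20e14, 5 / 20, "S"),
        ]
        account = aggregate_account(flows)
        assert account.R == pytest.approx(25e14)
        assert account.N == pytest.approx(10e14)
        assert account.Pr == pytest.approx(5e14)
        assert account.Pn == pytest.approx(40e14)
        assert account.Sr == pytest.approx(5e14)
        assert account.Sn == pytest.approx(15e14)
        assert account.Y == pytest.approx(100e14)

    @given(
        data=st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=1e18),
                st.floats(min_value=0, max_value=1),
                st.sampled_from(["R", "N", "P", "S"]),
            ),
            max_size=30,
        )
    )
    def test_yield_identity_for_any_flow_list(self, data):
        """Y = R + N + Pr + Pn + Sr + Sn for arbitrary classified flows."""
        flows = [flow(t, rf, cat) for t, rf, cat in data]
        account = aggregate_account(flows)
        assert account.Y == pytest.approx(
            account.R + account.N + account.Pr + account.Pn + account.Sr + account.Sn
        )
        assert account.Y == pytest.approx(sum(f.total for f in flows), rel=1e-9)


class TestFlowInvariant:
    def test_inconsistent_split_rejected(self):
        with pytest.raises(ValidationError):
            EmergyFlow(
                resource_name="bad", total=1.0, renewable=0.6, nonrenewable=0.6,
                category="R",
            )


class TestNetServices:
    def test_cap_minus_taxes(self):
        e = entry(
            resource_name="cap_payments", unit_class="money", uev_value=1e12,
            renewability_factor=0.1, category="S", source_baseline=1.2e25,
        )
        net = net_service_flow(30_000, 800, e)
        assert net.total == pytest.approx(2.92e16)
        assert net.renewable == pytest.approx(2.92e15)

    def test_floors_at_zero_with_warning(self):
        e = entry(
            resource_name="cap_payments", unit_class="money", uev_value=1e12,
            renewability_factor=0.1, category="S", source_baseline=1.2e25,
        )
        with pytest.warns(UserWarning, match="floored"):
            net = net_service_flow(100, 500, e)
        assert net.total == 0.0
        assert math.isfinite(net.total)
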