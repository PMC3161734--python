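"""Carbon-yield computation and distribution summaries."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chlamyflux.efm import classify_by_target, enumerate_efms
from chlamyflux.network import Metabolite, MetabolicNetwork, ModelConfig, Reaction
from chlamyflux.simulate import toy_network
from chlamyflux.yields import (
    YieldRecord,
    carbon_yield,
    scenario_compare,
    summarise,
    weighted_quantile,
    yield_records,
)


def _single_reaction_net(stoich, carbons, external, sources):
    mets = [Metabolite(m, carbon_count=c, is_external=m in external) for m, c in carbons.items()]
    net = MetabolicNetwork(mets, [Reaction("R", {m: Fraction(c) for m, c in stoich.items()})])
    return net.with_config(ModelConfig(external=frozenset(external), carbon_sources=frozenset(sources)))


@pytest.mark.parametrize(
    "stoich, carbons, target, expected",
    [
        # 1 G6P + 2 NH4 -> 2 Gly + 2 CO2 : Y = (2*2)/(1*6) = 2/3
        ({"G6P": -1, "NH4": -2, "Gly": 2, "CO2": 2},
         {"G6P": 6, "NH4": 0, "Gly": 2, "CO2": 1}, "Gly", Fraction(2, 3)),
        # 3 acetate -> 1 Lys : Y = 6/6 = 1
        ({"Ac": -3, "Lys": 1},
         {"Ac": 2, "Lys": 6}, "Lys", Fraction(1)),
        # 1 G6P + 1 acetate -> 2 Ala + 2 CO2 : Y = 6/8 = 3/4
        ({"G6P": -1, "Ac": -1, "Ala": 2, "CO2": 2},
         {"G6P": 6, "Ac": 2, "Ala": 3, "CO2": 1}, "Ala", Fraction(3, 4)),
    ],
)
def test_carbon_yield_worked_examples(stoich, carbons, target, expected):
    external = set(stoich)  # one overall reaction: everything is boundary
    sources = {s for s in ("G6P", "Ac") if s in stoich}
    net = _single_reaction_net(stoich, carbons, external, sources)
    assert carbon_yield([1], target, net, sources) == expected


def test_carbon_yield_rejects_nonproducing_and_sourceless_modes():
    net = _single_reaction_net(
        {"Ac": -1, "P": 1}, {"Ac": 2, "P": 2}, {"Ac", "P"}, {"Ac"}
    )
    with pytest.raises(ValueError, match="net-produce"):
        carbon_yield([1], "Ac", net, carbon_sources={"Ac"})  # consumed, not produced
    with pytest.raises(ValueError, match="carbon source"):
        carbon_yield([1], "P", net, carbon_sources={"P"})  # no designated source consumed
    with pytest.raises(ValueError, match="CO2"):
        carbon_yield([1], "P", net, carbon_sources={"CO2"})


def test_toy_t4_single_mode_yield_is_two_thirds():
    net, _ = toy_network("T4_co2")
    efms = enumerate_efms(net)
    sub = classify_by_target(efms, "P_ext")
    assert len(sub) == 1
    assert carbon_yield(sub.vectors[0], "P_ext", net) == Fraction(2, 3)


# -- summaries -------------------------------------------------------------


def _records(pairs):
    return [
        YieldRecord(i, "X", Fraction(y).limit_denominator(1000), affected)
        for i, (y, affected) in enumerate(pairs)
    ]


def test_weighted_mean_worked_example():
    recs = _records([(0.5, True), (1.0, False)])
    s = summarise(recs, "weighted", w_affected=Fraction(1, 10))
    assert s.weighted_mean == pytest.approx((0.1 * 0.5 + 1.0) / 1.1)
    assert s.mean == pytest.approx(0.75)


def test_equal_weights_reduce_weighted_mean_to_plain_mean():
    recs = _records([(0.5, True), (1.0, False)])
    s = summarise(recs, "weighted", w_affected=Fraction(1))
    assert s.weighted_mean == pytest.approx(s.mean) == pytest.approx(0.75)


def test_plain_summary_five_numbers():
    recs = _records([(0.2, False), (0.4, False), (0.6, False), (0.8, False), (1.0, False)])
    s = summarise(recs, "all")
    assert (s.minimum, s.median, s.maximum) == (0.2, 0.6, 1.0)
    assert s.mean == pytest.approx(0.6)
    assert s.q1 == pytest.approx(0.4)
    assert s.q3 == pytest.approx(0.8)


def test_knockout_of_fully_affected_set_is_infeasible_not_an_error():
    recs = _records([(0.5, True), (0.7, True)])
    s = summarise(recs, "knockout")
    assert s.infeasible and s.n_modes == 0 and s.mean is None


def test_invalid_weight_rejected():
    recs = _records([(0.5, True)])
    with pytest.raises(ValueError):
        summarise(recs, "weighted", w_affected=Fraction(0))
    with pytest.raises(ValueError):
        summarise(recs, "weighted", w_affected=Fraction(11, 10))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.fractions(0, 2), st.booleans()), min_size=1, max_size=30
    ).filter(lambda ps: any(a for _, a in ps) and any(not a for _, a in ps))
)
def test_weighted_quantiles_equal_explicit_replication(pairs):
    """w_a = 1/10 quantiles == numpy quantiles of the 10x/1x replicated sample."""
    values = [float(y) for y, _ in pairs]
    weights = [Fraction(1, 10) if a else Fraction(1) for _, a in pairs]
    replicated = np.repeat(values, [1 if a else 10 for _, a in pairs])
    for q in (0, 0.25, 0.5, 0.75, 1):
        ours = float(weighted_quantile(values, weights, Fraction(q).limit_denominator(4)))
        ref = float(np.quantile(replicated, q, method="linear"))
        assert ours == pytest.approx(ref, abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.fractions(0, 2), st.booleans()), min_size=2, max_size=25
    ).filter(lambda ps: any(a for _, a in ps) and any(not a for _, a in ps))
)
def test_weighted_mean_is_monotone_in_downregulation(pairs):
    """As w_a falls from 1 to 0 the weighted mean moves monotonically from the
    overall mean toward the unaffected-only mean."""
    recs = _records([(float(y), a) for y, a in pairs])
    ws = [Fraction(1), Fraction(1, 2), Fraction(1, 10), Fraction(1, 100)]
    means = [summarise(recs, "weighted", w).weighted_mean for w in ws]
    unaffected_mean = summarise(recs, "knockout").mean
    diffs = [m - unaffected_mean for m in means]
    assert all(abs(b) <= abs(a) + 1e-12 for a, b in zip(diffs, diffs[1:]))
    assert all(d * diffs[0] >= -1e-12 for d in diffs)  # no sign change


def test_scenario_compare_constructed_shift():
    """Knockout removes the low-yield affected modes: mean rises, max holds."""
    mets = [
        Metabolite("S", carbon_count=2, is_external=True),
        Metabolite("M", carbon_count=2),
        Metabolite("X", carbon_count=2, is_external=True),
    ]
    rxns = [
        Reaction("Rin", {"S": Fraction(-1), "M": Fraction(1)}),
        Reaction("Rgood", {"M": Fraction(-1), "X": Fraction(1)}),
        Reaction("Rbad", {"M": Fraction(-2), "X": Fraction(1), "S": Fraction(0)}),
    ]
    # Rbad wastes half the carbon: 2 M -> 1 X  (balance the loss as CO2-like external)
    mets.append(Metabolite("W", carbon_count=2, is_external=True))
    rxns[2] = Reaction("Rbad", {"M": Fraction(-2), "X": Fraction(1), "W": Fraction(1)})
    net = MetabolicNetwork(mets, rxns).with_config(
        ModelConfig(external=frozenset({"S", "X", "W"}), carbon_sources=frozenset({"S"}),
                    targets=("X",))
    )
    efms = enumerate_efms(net)
    df = scenario_compare(efms, regulated={"Rbad"}, targets=["X"])
    row_all = df[(df.scheme == "all")].iloc[0]
    row_ko = df[(df.scheme == "knockout")].iloc[0]
    row_w = df[(df.scheme == "weighted")].iloc[0]
    assert row_all.n_modes == 2 and row_all.n_affected == 1
    assert row_ko["mean"] > row_all["mean"]
    assert row_ko["max"] <= row_all["max"]
    assert bool(row_ko.mean_increases) and bool(row_w.mean_increases)


def test_yield_records_carry_weights_and_affection(core_model, core_efms):
    sub = classify_by_target(core_efms, "Asn")
    recs = yield_records(sub, "Asn", core_model.config.regulated_reactions)
    assert len(recs) == len(sub)
    assert all(r.weight == Fraction(1, 10) for r in recs if r.affected)
    assert all(r.weight == Fraction(1) for r in recs if not r.affected)
    assert all(r.yield_value > 0 for r in recs)


def test_carbon_conservation_identity(core_model, core_efms):
    """When the target is the only carbon-bearing product besides CO2,
    Y = 1 - (CO2 released)/(source carbon consumed)."""
    from chlamyflux.efm import overall_equation

    carbon = {m.id: m.carbon_count for m in core_model.metabolites}
    sub = classify_by_target(core_efms, "Lys")
    checked = 0
    for v in sub.vectors[:400]:
        ov = overall_equation(v, core_model, sub.reaction_ids)
        prods = {m for m, c in ov.items() if c > 0 and carbon[m] > 0}
        if prods != {"Lys", "CO2"} and prods != {"Lys"}:
            continue
        denom = sum(-c * carbon[s] for s, c in ov.items() if c < 0 and carbon[s] > 0)
        y = carbon_yield(v, "Lys", core_model, reaction_ids=sub.reaction_ids)
        co2 = ov.get("CO2", Fraction(0))
        assert y == 1 - Fraction(co2, denom)
        checked += 1
    assert checked > 10
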