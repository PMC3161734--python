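"""Elementary flux mode enumeration: exactness, completeness, invariants."""

import random
from fractions import Fraction

import numpy as np
import pytest

from chlamyflux.bruteforce import bruteforce_efms
from chlamyflux.efm import (
    EfmSet,
    classify_by_target,
    enumerate_efms,
    is_affected,
    knockout_filter,
    overall_equation,
    split_internal_matrix,
)
from chlamyflux.network import MetabolicNetwork, subnetwork
from chlamyflux.simulate import SyntheticSpec, random_network, toy_network


def _flux_dicts(efms: EfmSet) -> set[tuple]:
    return {
        tuple(sorted((r, v) for r, v in zip(efms.reaction_ids, vec) if v))
        for vec in efms.vectors
    }


@pytest.mark.parametrize(
    "name, n_expected",
    [("T1_linear", 1), ("T2_diamond", 2), ("T3_revcross", 4), ("T4_co2", 1)],
)
def test_toy_networks_enumerate_exactly(name, n_expected):
    net, expected = toy_network(name)
    efms = enumerate_efms(net, verify=True)
    assert len(efms) == n_expected
    assert _flux_dicts(efms) == {
        tuple(sorted(d.items())) for d in expected
    }
    # and the reference enumerator agrees
    assert set(efms.vectors) == set(bruteforce_efms(net).vectors)


def test_single_mode_has_unit_fluxes():
    net, _ = toy_network("T1_linear")
    (mode,) = list(enumerate_efms(net))
    assert mode.flux_dict() == {"R1": 1, "R2": 1, "R3": 1}
    assert mode.overall_dict() == {"A_ext": Fraction(-1), "B_ext": Fraction(1)}


def test_overall_equation_cancels_internals():
    net, _ = toy_network("T4_co2")
    efms = enumerate_efms(net)
    ov = overall_equation(efms.mode(0), net)
    assert ov == {"X_ext": Fraction(-1), "P_ext": Fraction(1), "CO2_ext": Fraction(1)}
    assert all(m in {x.id for x in net.external_metabolites} for m in ov)


def _random_small(seed):
    return random_network(
        SyntheticSpec(
            seed=seed,
            n_pathways=3,
            pathway_length=4,
            n_shared_metabolites=2,
            reversibility_fraction=0.3,
        )
    )


@pytest.mark.parametrize("seed", range(40))
def test_enumeration_matches_bruteforce_oracle(seed):
    """Set equality of canonical mode vectors against exhaustive subset search."""
    net = _random_small(seed)
    if len(split_internal_matrix(net)[1]) > 16:
        net = random_network(SyntheticSpec(seed=seed, n_pathways=2, pathway_length=4,
                                           n_shared_metabolites=1, reversibility_fraction=0.2))
    dd = enumerate_efms(net, verify=True)
    bf = bruteforce_efms(net)
    assert set(dd.vectors) == set(bf.vectors)


def test_steady_state_and_sign_constraints_hold_everywhere(core_efms, core_model):
    """Exact S.v = 0 on internal metabolites, irreversible fluxes >= 0."""
    rows, columns = split_internal_matrix(core_model)
    n_rxn = len(core_model.reactions)
    A = np.zeros((len(rows), n_rxn), dtype=np.int64)
    for i, row in enumerate(rows):
        for k, (j, sgn) in enumerate(columns):
            if sgn == +1:
                A[i, j] = row[k]
    V = np.array(core_efms.vectors, dtype=np.int64)
    assert np.all(A @ V.T == 0)
    irrev = np.array([not r.reversible for r in core_model.reactions])
    assert np.all(V[:, irrev] >= 0)


def test_support_minimality_is_pairwise(core_efms):
    """No mode's support strictly contains another's (exhaustive, ~3.8k modes)."""
    masks = [
        sum(1 << j for j, x in enumerate(v) if x) for v in core_efms.vectors
    ]
    masks.sort(key=lambda m: m.bit_count())
    for i, small in enumerate(masks):
        for big in masks[i + 1 :]:
            assert not (small & big == small and small != big)


def test_no_two_cycles_and_order_invariance():
    """Re-enumeration with permuted reaction order yields the same canonical set."""
    net, _ = toy_network("T3_revcross")
    base = enumerate_efms(net)
    for v in base.vectors:
        support = [r for r, x in zip(base.reaction_ids, v) if x]
        assert len(support) > 2 or len(set(support)) == len(support)
    rng = random.Random(7)
    for _ in range(5):
        order = list(range(len(net.reactions)))
        rng.shuffle(order)
        permuted = MetabolicNetwork(
            list(net.metabolites), [net.reactions[i] for i in order], net.name
        )
        permuted.config = net.config
        efms_p = enumerate_efms(permuted.with_config(net.config))
        assert _flux_dicts(efms_p) == _flux_dicts(base)


def test_classify_by_target_requires_production_and_source():
    net, _ = toy_network("T1_linear")
    efms = enumerate_efms(net)
    assert len(classify_by_target(efms, "B_ext", {"A_ext"})) == 1
    with pytest.raises(ValueError, match="external"):
        classify_by_target(efms, "A", {"A_ext"})


def test_co2_only_producers_are_excluded_from_targets(core_model, core_efms):
    """Modes producing no amino acid (full oxidation to CO2) never classify."""
    for target in core_model.config.targets:
        sub = classify_by_target(core_efms, target)
        ids, M = sub.overall_matrix()
        t = ids.index(target)
        assert np.all(M[:, t] > 0)
        src = [ids.index(s) for s in core_model.config.carbon_sources]
        assert np.all(M[:, src].min(axis=1) < 0)


def test_knockout_filter_equals_subnetwork_enumeration():
    """EFMs avoiding removed reactions == EFMs of the reduced network."""
    for seed in range(12):
        net = _random_small(seed)
        efms = enumerate_efms(net)
        rng = random.Random(seed)
        drop = {rng.choice(net.reaction_ids)}
        filtered = knockout_filter(efms, drop)
        try:
            sub = subnetwork(net, drop)
            re_enum = enumerate_efms(sub)
        except ValueError:
            assert len(filtered) == 0 or len(sub.internal_metabolites) == 0
            continue
        assert _flux_dicts(filtered) == _flux_dicts(re_enum)


def test_knockout_on_diamond():
    net, _ = toy_network("T2_diamond")
    efms = enumerate_efms(net)
    assert len(knockout_filter(efms, {"R3"})) == 1
    assert len(knockout_filter(efms, set())) == 2


def test_is_affected_support_intersection():
    net, _ = toy_network("T2_diamond")
    efms = enumerate_efms(net)
    modes = list(efms)
    assert is_affected(modes[0].support, modes[0].support)
    assert not any(is_affected(m, set()) for m in modes)


def test_enumeration_requires_internal_metabolites():
    from chlamyflux.network import Metabolite, Reaction

    net = MetabolicNetwork(
        [Metabolite("A", is_external=True), Metabolite("B", is_external=True)],
        [Reaction("R1", {"A": Fraction(-1), "B": Fraction(1)})],
    )
    with pytest.raises(ValueError, match="internal"):
        enumerate_efms(net)


def test_mode_cap_aborts_with_progress():
    from chlamyflux.efm import EnumerationCapExceeded

    net = _random_small(3)
    with pytest.raises(EnumerationCapExceeded) as exc:
        enumerate_efms(net, cap=1)
    assert exc.value.cap == 1
    assert exc.value.rows_done >= 1


def test_serialisation_round_trip(tmp_path):
    net, _ = toy_network("T3_revcross")
    efms = enumerate_efms(net)
    p = tmp_path / "efms.json"
    efms.to_json(p)
    back = EfmSet.from_json(p, net)
    assert back.vectors == efms.vectors
    efms.to_tsv(tmp_path / "efms.tsv")
    lines = (tmp_path / "efms.tsv").read_text().splitlines()
    assert len(lines) == 2 + len(efms)
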