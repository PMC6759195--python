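"""EMU decomposition and MID simulation against the isotopomer oracle."""

from fractions import Fraction

import numpy as np
import pytest

from kfitlab.core import (
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    parse_atom_map,
    parse_equation,
)
from kfitlab.emu import EMU, MIDSet, build_emu_network, simulate_mids
from kfitlab.isotopomer import isotopomer_mids
from kfitlab.synth import (
    ToySpec,
    default_fragments,
    default_tracer,
    make_toy_network,
    wildtype_flux_distribution,
)


def _mk(mets, reactions):
    return MetabolicModel(
        {m.id: m for m in mets}, {r.id: r for r in reactions})


def _rxn(rid, eq, amap, **kw):
    stoich, rev = parse_equation(eq)
    return Reaction(rid, stoich, reversible=rev,
                    atom_map=parse_atom_map(amap), **kw)


@pytest.fixture
def linear_model():
    return _mk(
        [Metabolite("A", 2, is_extracellular=True), Metabolite("B", 2),
         Metabolite("C", 2), Metabolite("out", 2, is_extracellular=True)],
        [_rxn("R1", "A --> B", "A(ab) --> B(ab)"),
         _rxn("R2", "B --> C", "B(ab) --> C(ab)"),
         _rxn("R3", "C --> out", "C(ab) --> out(ab)")],
    )


def test_linear_pathway_decomposition(linear_model):
    net = build_emu_network(linear_model, [("C", (1, 2))])
    # C[1,2] <- B[1,2] <- A[1,2] (source): one size-2 block of 2 EMUs
    assert net.block_sizes() == [(2, 2)]
    assert EMU("A", frozenset({1, 2})) in net.source_emus
    assert net.n_emus == 3


def test_identity_pathway_propagates_tracer(linear_model):
    net = build_emu_network(linear_model, [("C", (1, 2)), ("C", (2,))])
    tracer = {"A": [(0.7, frozenset({1})), (0.3, frozenset())]}
    mids = simulate_mids(net, {"R1": 5.0, "R2": 5.0, "R3": 5.0}, tracer)
    np.testing.assert_allclose(mids[("C", (1, 2))], [0.3, 0.7, 0.0],
                               atol=1e-12)
    np.testing.assert_allclose(mids[("C", (2,))], [1.0, 0.0], atol=1e-12)


def test_condensation_is_convolution():
    model = _mk(
        [Metabolite("B", 2, is_extracellular=True),
         Metabolite("D", 1, is_extracellular=True), Metabolite("E", 3),
         Metabolite("out", 3, is_extracellular=True)],
        [_rxn("R1", "B + D --> E", "B(ab) + D(c) --> E(abc)"),
         _rxn("R2", "E --> out", "E(abc) --> out(abc)")],
    )
    net = build_emu_network(model, [("E", (1, 2, 3))])
    prods = net.productions[EMU("E", frozenset({1, 2, 3}))]
    assert len(prods[0].sources) == 2  # convolution node
    tracer = {"B": [(0.5, frozenset({1, 2})), (0.5, frozenset())],
              "D": [(0.8, frozenset({1})), (0.2, frozenset())]}
    mids = simulate_mids(net, {"R1": 2.0, "R2": 2.0}, tracer)
    expected = np.convolve([0.5, 0.0, 0.5], [0.2, 0.8])
    np.testing.assert_allclose(mids[("E", (1, 2, 3))], expected, atol=1e-12)


def test_fragment_exceeding_carbon_count_errors(linear_model):
    with pytest.raises(ModelError):
        build_emu_network(linear_model, [("C", (1, 2, 3))])


def test_singular_balance_names_the_emu(linear_model):
    net = build_emu_network(linear_model, [("C", (1, 2))])
    with pytest.raises(ModelError, match=r"C\[1,2\]"):
        simulate_mids(net, {"R1": 1.0, "R2": 1.0, "R3": 0.0},
                      {"A": [(1.0, frozenset({1}))]})


def test_emu_equals_isotopomer_enumeration_on_branched_toy(rng):
    """EMU cascade equals brute-force isotopomer simulation for random
    flux vectors on the branched toy network (atom-permuting routes)."""
    model = make_toy_network(ToySpec(seed=1))
    frags = default_fragments(model)
    tracer = default_tracer(model)
    net = build_emu_network(model, frags)
    for _ in range(3):
        splits = rng.uniform(0.2, 0.8, size=2)
        fluxes = wildtype_flux_distribution(model, list(splits)).as_dict()
        mids = simulate_mids(net, fluxes, tracer)
        ref = isotopomer_mids(model, fluxes, tracer, frags)
        for key in mids.mids:
            np.testing.assert_allclose(mids.mids[key], ref.mids[key],
                                       atol=1e-9)


def test_reversible_exchange_flux_affects_labeling():
    """Exchange flux through a reversible step mixes downstream labeling
    back upstream; EMU result still matches the isotopomer oracle."""
    model = _mk(
        [Metabolite("A", 2, is_extracellular=True), Metabolite("B", 2),
         Metabolite("C", 2), Metabolite("out", 2, is_extracellular=True)],
        [_rxn("R1", "A --> B", "A(ab) --> B(ab)"),
         _rxn("R2", "B <=> C", "B(ab) --> C(ba)"),
         _rxn("R4", "A --> C", "A(ab) --> C(ab)"),
         _rxn("R3", "C --> out", "C(ab) --> out(ab)")],
    )
    frags = [("B", (1,)), ("C", (1, 2))]
    tracer = {"A": [(1.0, frozenset({1}))]}
    net = build_emu_network(model, frags)
    fluxes = {"R1": 10.0, "R2": 10.0, "R4": 5.0, "R3": 15.0}
    base = simulate_mids(net, fluxes, tracer)
    mixed = simulate_mids(net, fluxes, tracer, exchange={"R2": 30.0})
    assert not np.allclose(base[("B", (1,))], mixed[("B", (1,))])
    ref = isotopomer_mids(model, fluxes, tracer, frags,
                          exchange={"R2": 30.0})
    for key in mixed.mids:
        np.testing.assert_allclose(mixed.mids[key], ref.mids[key], atol=1e-9)


def test_mids_are_distributions_and_scale_invariant(toy_model, rng):
    frags = default_fragments(toy_model)
    tracer = default_tracer(toy_model)
    net = build_emu_network(toy_model, frags)
    fluxes = wildtype_flux_distribution(toy_model, [0.55, 0.45]).as_dict()
    mids = simulate_mids(net, fluxes, tracer)
    mids.validate()
    for c in (0.01, 3.7, 250.0):
        scaled = simulate_mids(net, {k: c * v for k, v in fluxes.items()},
                               tracer)
        for key in mids.mids:
            np.testing.assert_allclose(mids.mids[key], scaled.mids[key],
                                       atol=1e-12)


def test_midset_tsv_roundtrip(tmp_path, toy_model):
    frags = default_fragments(toy_model)
    net = build_emu_network(toy_model, frags)
    fluxes = wildtype_flux_distribution(toy_model, [0.5, 0.5]).as_dict()
    mids = simulate_mids(net, fluxes, default_tracer(toy_model))
    mids.strain_id = "wt"
    mids.write(tmp_path / "mids.tsv")
    back = MIDSet.read(tmp_path / "mids.tsv", "wt")
    assert set(back.mids) == set(mids.mids)
    for key in mids.mids:
        np.testing.assert_allclose(back.mids[key], mids.mids[key])
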