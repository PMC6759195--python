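"""Elementary decomposition, anchoring, steady-state solver, stability."""

from fractions import Fraction

import numpy as np
import pytest

from kfitlab.core import (
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    Regulation,
    parse_equation,
)
from kfitlab.elementary import (
    NonConvergentError,
    UnstableError,
    anchor_wildtype,
    decompose,
    machine_for,
    ode_steady_state,
    stability_check,
    steady_state,
)
from kfitlab.synth import ToySpec, make_toy_network, sample_ground_truth


def _uni_uni(regs=()):
    mets = {"A": Metabolite("A", 0, is_extracellular=True),
            "P": Metabolite("P", 0, is_extracellular=True),
            "I": Metabolite("I", 0)}
    st, _ = parse_equation("A --> P")
    rxn = Reaction("R", st, enzyme_id="E1")
    return MetabolicModel(mets, {"R": rxn}, list(regs))


def test_uni_uni_mechanism_definition():
    net = decompose(_uni_uni())
    c = net.counts()
    assert c["steps"] == 2
    assert c["elementary_constants"] == 4
    assert c["complexes"] == 2
    kinds = [s.kind for s in net.steps]
    assert kinds == ["binding", "conversion"]


def test_competitive_inhibitor_adds_one_step():
    net = decompose(_uni_uni([Regulation("R", "I", "competitive")]))
    c = net.counts()
    assert c["steps"] == 3
    assert c["inhibitor_constants"] == 2
    # competitive inhibitor binds *free* enzyme
    inh = [s for s in net.steps if s.kind == "inhibitor_binding"][0]
    assert inh.complex_in == net.free_complex["R"]


def test_inhibition_mode_binding_targets():
    net_u = decompose(_uni_uni([Regulation("R", "I", "uncompetitive")]))
    inh = [s for s in net_u.steps if s.kind == "inhibitor_binding"][0]
    assert inh.complex_in != net_u.free_complex["R"]  # terminal complex
    net_n = decompose(_uni_uni([Regulation("R", "I", "noncompetitive")]))
    inh_steps = [s for s in net_n.steps if s.kind == "inhibitor_binding"]
    assert len(inh_steps) == 2
    assert net_n.counts()["inhibitor_constants"] == 4


def test_regulation_without_enzyme_errors():
    model = _uni_uni()
    model.reactions["R"].enzyme_id = None
    model.regulations = [Regulation("R", "I", "competitive")]
    with pytest.raises(ModelError):
        decompose(model)


def test_anchoring_arithmetic_forced_by_definitions():
    """One-step reaction, v_net = 1, v_r = 0.5: forward flux 1.5; with
    e_free = 0.6 and unit concentrations k_fwd = 1.5/0.6 = 2.5."""
    net = decompose(_uni_uni())
    e = np.array([0.6, 0.4])
    v_r = np.array([0.5, 0.2])
    params = anchor_wildtype(net, {"R": 1.0}, e, v_r)
    assert params.k_fwd[0] == pytest.approx(1.5 / 0.6)  # == 2.5
    assert params.k_rev[0] == pytest.approx(0.5 / 0.4)
    # equilibrium reaction: v_net = 0, v_r = 2 -> v_fwd = 2
    params_eq = anchor_wildtype(net, {"R": 0.0}, e, np.array([2.0, 2.0]))
    assert params_eq.k_fwd[0] * e[0] == pytest.approx(2.0)


def test_anchoring_rejects_negative_forward_flux():
    net = decompose(_uni_uni())
    with pytest.raises(ModelError, match="forward flux"):
        anchor_wildtype(net, {"R": -1.0}, np.array([0.5, 0.5]),
                        np.array([0.5, 0.5]))


def test_anchored_wildtype_is_exact_steady_state(toy_net, toy_truth):
    st = steady_state(toy_net, toy_truth.params)
    wt = toy_truth.params.wt_fluxes
    for rid, v in wt.items():
        assert st.flux(rid) == pytest.approx(v, abs=1e-8)
    np.testing.assert_allclose(st.c, 1.0, atol=1e-12)


def test_enzyme_conservation_at_every_state(toy_net, toy_truth):
    mach = machine_for(toy_net)
    for levels in ({}, {"E_A1": 0.0}, {"E_clv": 1.7, "E_B1": 0.4}):
        st = steady_state(toy_net, toy_truth.params, levels, max_iter=400)
        sums = mach.cons_mat @ st.x
        expect = mach.levels_vector(levels)
        np.testing.assert_allclose(sums, expect, atol=1e-9)


def test_knockout_zeroes_all_fluxes_of_deleted_enzyme(toy_model, toy_net,
                                                      toy_truth):
    st = steady_state(toy_net, toy_truth.params, {"E_A1": 0.0}, max_iter=400)
    for rid, rxn in toy_model.reactions.items():
        if rxn.enzyme_id == "E_A1":
            assert st.flux(rid) == pytest.approx(0.0, abs=1e-9)


def test_sole_producer_knockout_zeroes_consumers(toy_model, toy_net,
                                                 toy_truth):
    """Deleting the only enzyme producing pa1 forces all pa1-consuming
    fluxes to zero at steady state (mass balance)."""
    st = steady_state(toy_net, toy_truth.params, {"E_A1": 0.0}, max_iter=400)
    # A1b consumes pa1, produced only by A1a (enzyme E_A1)
    assert st.flux("A1b") == pytest.approx(0.0, abs=1e-6)


def test_solver_matches_ode_oracle(toy_net, toy_truth):
    for levels in ({"E_clv": 1.5}, {"E_A1": 0.0}):
        st = steady_state(toy_net, toy_truth.params, levels, max_iter=400)
        ode = ode_steady_state(toy_net, toy_truth.params, levels)
        np.testing.assert_allclose(st.v, ode.v, atol=1e-6)
        np.testing.assert_allclose(st.c, ode.c, atol=1e-6)


def test_dynamic_jacobian_matches_finite_differences(toy_net, toy_truth):
    mach = machine_for(toy_net)
    rng = np.random.default_rng(4)
    kf, kr = toy_truth.params.k_fwd, toy_truth.params.k_rev
    nfree = len(mach.free_idx)
    y = np.concatenate([rng.uniform(0.5, 2.0, nfree),
                        rng.uniform(0.01, 0.2, mach.nx)])
    J = mach.dynamic_jacobian(y, kf, kr)
    h = 1e-7
    for j in rng.choice(len(y), size=8, replace=False):
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        col = (mach.dynamic_rhs(yp, kf, kr) - mach.dynamic_rhs(ym, kf, kr)) \
            / (2 * h)
        np.testing.assert_allclose(J[:, j], col, rtol=1e-4, atol=1e-4)


def test_wildtype_state_is_stable_with_conservation_modes_excluded(
        toy_net, toy_truth):
    st = steady_state(toy_net, toy_truth.params)
    ok, lead = stability_check(toy_net, toy_truth.params, st)
    assert ok and lead < 0
    # the raw Jacobian *does* have (near-)zero conservation eigenvalues
    mach = machine_for(toy_net)
    y = np.concatenate([st.c[mach.free_idx], st.x])
    eig = np.linalg.eigvals(mach.dynamic_jacobian(
        y, toy_truth.params.k_fwd, toy_truth.params.k_rev))
    assert np.max(eig.real) > -1e-9  # conservation nullspace


def test_unstable_parameter_set_detected(toy_model, toy_net):
    """Scan raw parameter draws for a mutant steady state that is locally
    unstable and confirm the verdict against the leading eigenvalue of an
    independently computed finite-difference Jacobian (projected off the
    enzyme-conservation nullspace)."""
    from scipy.linalg import null_space

    from kfitlab.synth import wildtype_flux_distribution

    mach = machine_for(toy_net)
    wt = wildtype_flux_distribution(toy_model, [0.5, 0.5])
    found = False
    for trial in range(200):
        rng = np.random.default_rng([56, trial])
        e = np.zeros(toy_net.n_complexes)
        for im in range(len(toy_net.mechanisms)):
            cxs = np.flatnonzero(toy_net.complex_mechanism == im)
            d = rng.dirichlet(np.ones(len(cxs)))
            d = np.maximum(d, 1e-3)
            e[cxs] = d / d.sum()
        v_r = 10 ** rng.uniform(-3, 4, size=toy_net.n_steps)
        try:
            params = anchor_wildtype(toy_net, wt, e, v_r)
            st = steady_state(toy_net, params, {"E_clv": 0.1}, max_iter=200)
        except (ModelError, NonConvergentError, UnstableError):
            continue
        ok, lead = stability_check(toy_net, params, st)
        if ok or lead < 0.1:
            continue  # want a robustly positive eigenvalue
        found = True
        nfree = len(mach.free_idx)
        y0 = np.concatenate([st.c[mach.free_idx], st.x])
        n = len(y0)
        J = np.zeros((n, n))
        for j in range(n):
            h = 1e-6 * max(1.0, abs(y0[j]))
            yp, ym = y0.copy(), y0.copy()
            yp[j] += h
            ym[j] -= h
            J[:, j] = (mach.dynamic_rhs(yp, params.k_fwd, params.k_rev)
                       - mach.dynamic_rhs(ym, params.k_fwd, params.k_rev)
                       ) / (2 * h)
        C = np.zeros((mach.n_mech, n))
        C[:, nfree:] = mach.cons_mat
        Q = null_space(C)
        lead_fd = np.max(np.linalg.eigvals(Q.T @ J @ Q).real)
        assert lead_fd > 0
        # extreme concentration scales make the exact eigenvalue sensitive;
        # the sign and order of magnitude must agree with the FD oracle
        assert lead == pytest.approx(lead_fd, rel=0.25)
        break
    assert found, "no unstable draw found in scan"


def test_divergence_raises_unstable(toy_net, toy_truth):
    """Driving an enzyme level absurdly high must either converge or fail
    cleanly (Unstable/NonConvergent), never return an unconverged state."""
    try:
        st = steady_state(toy_net, toy_truth.params, {"E_upt": 1e9},
                          max_iter=60)
        assert st.max_dcdt < 1e-6
    except (UnstableError, NonConvergentError):
        pass


def test_ground_truth_postconditions(toy_truth):
    assert toy_truth.wildtype_state.stable
    for st in toy_truth.strain_states.values():
        assert st.max_dcdt < 1e-6
        assert st.stable
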