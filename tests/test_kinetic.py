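"""Training-set assembly, SSR weighting, acceptance rules, fitting and
leave-one-out cross-validation."""

import numpy as np
import pytest

from kfitlab.core import FluxDistribution, ModelError
from kfitlab.elementary import SteadyState
from kfitlab.kinetic import (
    KineticModel,
    KineticResults,
    LocalFit,
    StrainData,
    TrainingSet,
    accept_models,
    apply_sd_floor,
    compute_ssr,
    cross_validate,
    prepare_training,
)
from kfitlab.synth import simulate_dataset


@pytest.mark.parametrize(
    "v, sd_mfa, expected",
    [
        (100.0, 0.5, 5.0),   # 5% of flux dominates
        (2.0, 3.0, 3.0),     # MFA SD dominates
        (0.1, 0.01, 1.0),    # absolute floor dominates
    ],
)
def test_sd_floor_rule(v, sd_mfa, expected):
    assert apply_sd_floor(v, sd_mfa) == expected


def test_prepare_training_scales_by_uptake_ratio():
    reactions = ["R1", "R2"]
    wt = FluxDistribution("wildtype", reactions, np.array([100.0, 40.0]))
    mut = FluxDistribution("mutA", reactions, np.array([100.0, 60.0]),
                           sd=np.array([0.5, 0.2]))
    train = prepare_training(
        {"wildtype": wt, "mutA": mut},
        uptakes={"wildtype": 10.0, "mutA": 8.0},
        knockouts={"mutA": {"E1": 0.0}},
    )
    s = train.strains[0]
    v, sd = s.fluxes["R1"]
    assert v == pytest.approx(80.0)            # 100 * 8/10
    assert sd == pytest.approx(4.0)            # max(1, 0.05*80, 0.4)
    assert s.enzyme_levels == {"E1": 0.0}
    with pytest.raises(ModelError):
        prepare_training({"wildtype": wt, "mutA": mut},
                         uptakes={"wildtype": 10.0})


def _state(reactions, v):
    return SteadyState(reactions=list(reactions), v=np.asarray(v, float),
                       metabolites=[], c=np.zeros(0), x=np.zeros(0),
                       max_dcdt=0.0, converged=True)


def _toy_train(obs):
    wt = FluxDistribution("wildtype", ["R1", "R2"], np.array([10.0, 5.0]))
    return TrainingSet(wt, [
        StrainData("s1", {r: (o, 2.0) for r, o in obs.items()})])


def test_compute_ssr_cases():
    train = _toy_train({"R1": 10.0, "R2": 5.0})
    pred = {"s1": _state(["R1", "R2"], [10.0, 5.0])}
    ssr, shares, r = compute_ssr(pred, train)
    assert ssr == 0.0 and shares["s1"] == 0.0
    # one flux off by exactly one SD -> SSR 1
    pred = {"s1": _state(["R1", "R2"], [12.0, 5.0])}
    ssr, _, _ = compute_ssr(pred, train)
    assert ssr == pytest.approx(1.0)


def test_ssr_invariant_under_reordering():
    wt = FluxDistribution("wildtype", ["R1", "R2"], np.array([10.0, 5.0]))
    s = StrainData("s1", {"R1": (9.0, 1.5), "R2": (6.0, 2.5)})
    s_rev = StrainData("s1", dict(reversed(list(s.fluxes.items()))))
    pred = {"s1": _state(["R2", "R1"], [5.5, 9.5])}
    ssr1, _, _ = compute_ssr(pred, TrainingSet(wt, [s]))
    ssr2, _, _ = compute_ssr(pred, TrainingSet(wt, [s_rev]))
    assert ssr1 == pytest.approx(ssr2)


def test_training_set_enforces_sd_floor():
    wt = FluxDistribution("wildtype", ["R1"], np.array([10.0]))
    with pytest.raises(ModelError):
        TrainingSet(wt, [StrainData("s1", {"R1": (10.0, 0.5)})])


def _fake_fit(ssr, preds):
    return LocalFit(0, np.zeros(1), ssr, True, params=None, predictions=preds)


def _fake_results(ssrs, v_by_fit, n_starts=None):
    preds = [{"s": _state(["R1"], [v])} for v in v_by_fit]
    fits = [_fake_fit(s, p) for s, p in zip(ssrs, preds)]
    res = KineticResults.__new__(KineticResults)
    res.model_ = None
    res.fits = sorted(fits, key=lambda f: f.ssr)
    res.n_starts = n_starts or len(fits)
    res.seed = 0
    res.selection = None
    return res


def test_neighbor_acceptance_rule():
    # 360 <= 1.1 * 338 -> accepted
    res = _fake_results([338.0, 360.0, 500.0], [1.0, 1.0, 1.0])
    sel = accept_models(res)
    assert sel.accepted and sel.neighbors_within_10pct == 1
    # no neighbor within 10% -> rejected
    res = _fake_results([100.0, 200.0], [1.0, 1.0])
    sel = accept_models(res)
    assert not sel.accepted and sel.neighbors_within_10pct == 0


def test_recovery_rate_uses_005_per_flux_rule():
    # fits at flux distance d from best: MSD = d^2 <= 0.05 counts
    res = _fake_results([1.0, 2.0, 3.0, 4.0],
                        [0.0, 0.1, 0.3, 5.0], n_starts=4)
    sel = accept_models(res)
    # d^2: 0, 0.01, 0.09, 25 -> two within 0.05
    assert sel.recovery_rate == pytest.approx(2 / 4)


def test_fit_is_reproducible_given_seed(toy_model, toy_net,
                                        noise_free_training):
    km = KineticModel(toy_model, noise_free_training, net=toy_net)
    a = km.fit(n_starts=2, seed=6)
    b = km.fit(n_starts=2, seed=6)
    assert [f.ssr for f in a.fits] == [f.ssr for f in b.fits]
    for fa, fb in zip(a.fits, b.fits):
        np.testing.assert_array_equal(fa.theta, fb.theta)


def test_adding_a_strain_never_decreases_ssr_at_fixed_parameters(
        toy_model, toy_net, toy_truth, noise_free_training, rng):
    """SSR is a sum of per-strain non-negative shares, so any parameter
    point scores at least as high once a strain is added."""
    km_full = KineticModel(toy_model, noise_free_training, net=toy_net)
    dropped = noise_free_training.strains[0].strain_id
    km_sub = KineticModel(toy_model, noise_free_training.without(dropped),
                          net=toy_net)
    for _ in range(3):
        theta = km_full.transform.sample(rng)
        try:
            ssr_full, _, _ = km_full.ssr_components(theta)
            ssr_sub, _, _ = km_sub.ssr_components(theta)
        except Exception:
            continue
        assert ssr_full >= ssr_sub - 1e-9


def test_parameter_recovery_on_noise_free_data(kinetic_fit_results,
                                               noise_free_training):
    best = kinetic_fit_results.best
    assert best.ssr < 1e-4
    for s in noise_free_training.strains:
        pred = best.predictions[s.strain_id].as_flux_dict()
        for rid, (vobs, _sd) in s.fluxes.items():
            assert pred.get(rid, 0.0) == pytest.approx(vobs, abs=1e-3)


def test_cross_validation_with_duplicate_phenotype(toy_model, toy_net,
                                                   toy_truth):
    """Holding out a strain whose phenotype is duplicated in training
    leaves an equivalent strain behind: held-out SSR stays small."""
    train, _ = simulate_dataset(toy_model, toy_truth, noise_cv=0.0, seed=0)
    dup_src = train.strains[0]
    dup = StrainData("dup", dict(dup_src.fluxes), dict(dup_src.enzyme_levels))
    train2 = TrainingSet(train.wildtype, train.strains + [dup])
    km = KineticModel(toy_model, train2, net=toy_net)
    cv = cross_validate(km, "dup", seed=11, max_starts=8)
    assert cv.held_out_ssr < 1.0
    assert cv.held_out_ssr == pytest.approx(cv.fit_ssr, abs=1.0)


def test_cross_validation_penalizes_unique_phenotype(toy_model, toy_net,
                                                     toy_truth):
    """Holding out the only strain exercising a flux re-routing leaves the
    refit unconstrained there: held-out SSR far exceeds the fitted SSR."""
    train, _ = simulate_dataset(toy_model, toy_truth, noise_cv=0.0, seed=0)
    keep = [s.strain_id for s in train.strains][:2]
    sub = TrainingSet(train.wildtype,
                      [s for s in train.strains if s.strain_id in keep])
    km = KineticModel(toy_model, sub, net=toy_net)
    cv = cross_validate(km, keep[0], seed=11, max_starts=8)
    assert cv.held_out_ssr > 5.0 * max(cv.fit_ssr, 1.0)
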