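"""Synthetic toy networks with ground-truth kinetics and simulated data.

The generator emits the three artifact classes the pipeline consumes:

* carbon-balanced atom-mapped toy networks with an uptake reaction,
  parallel routes around each branch point (so knockouts re-route flux,
  mimicking upper-glycolysis/PP-pathway deletion strains), a terminal
  cleavage into biomass-precursor sinks, and substrate-level regulations
  of all three inhibition modes;
* ground-truth elementary kinetics sampled inside the parameterization
  bounds and accepted only when the wild type and every planned knockout
  reach a stable steady state;
* simulated training sets (strain flux distributions with multiplicative
  Gaussian noise, SD-floor weighting) and tracer MIDs.

One route of every branch motif permutes its carbon atoms, so partial
fragments distinguish the two routes under a [1,2-13C] substrate — the
flux split is identifiable from labeling alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from kfitlab.core import (
    FluxDistribution,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    Regulation,
    parse_atom_map,
)
from kfitlab.elementary import (
    KineticParameterization,
    NonConvergentError,
    SteadyState,
    UnstableError,
    anchor_wildtype,
    decompose,
    stability_check,
    steady_state,
    K_UPPER,
)
from kfitlab.emu import MIDSet, TracerSpec, build_emu_network, simulate_mids
from kfitlab.kinetic import StrainData, TrainingSet, apply_sd_floor

__all__ = ["ToySpec", "GroundTruth", "make_toy_network", "sample_ground_truth",
           "simulate_dataset", "default_tracer", "default_fragments",
           "default_knockouts"]


@dataclass
class ToySpec:
    n_branch_points: int = 2
    n_reactions: int | None = None
    regulations_per_mode: dict[str, int] = field(
        default_factory=lambda: {"competitive": 1, "uncompetitive": 1,
                                 "noncompetitive": 1})
    n_reversible: int = 0
    seed: int = 0


@dataclass
class GroundTruth:
    params: KineticParameterization
    wildtype_state: SteadyState
    strain_states: dict[str, SteadyState]
    knockouts: dict[str, dict[str, float]]

    @property
    def wildtype_fluxes(self) -> dict[str, float]:
        return self.wildtype_state.as_flux_dict()


def make_toy_network(spec: ToySpec) -> MetabolicModel:
    """Build a deterministic carbon-balanced toy network from a spec.

    Topology: uptake -> chain of branch motifs (each with two parallel
    routes, one atom-permuting) -> cleavage into a 2-carbon and a
    1-carbon precursor, each drained by a biomass sink.
    """
    nbp = spec.n_branch_points
    if nbp < 1:
        raise ModelError("need at least one branch point")
    n_needed = 4 * nbp + 4
    if spec.n_reactions is not None and spec.n_reactions < n_needed:
        raise ModelError(
            f"{nbp} branch points need at least {n_needed} reactions, "
            f"got target {spec.n_reactions}")
    rng = np.random.default_rng(spec.seed)

    mets: dict[str, Metabolite] = {
        "sub_ext": Metabolite("sub_ext", 3, is_extracellular=True),
        "x0": Metabolite("x0", 3),
    }
    rxns: dict[str, Reaction] = {}

    def add_rxn(rid, eq, amap, enzyme, role="", reversible=False):
        from kfitlab.core import parse_equation

        stoich, rev = parse_equation(eq)
        rxns[rid] = Reaction(
            id=rid, stoichiometry=stoich, reversible=rev or reversible,
            atom_map=parse_atom_map(amap), enzyme_id=enzyme, role=role,
        )

    add_rxn("UPT", "sub_ext --> x0", "sub_ext(abc) --> x0(abc)", "E_upt",
            role="uptake")
    for i in range(1, nbp + 1):
        prev, cur = f"x{i-1}", f"x{i}"
        pa, pb = f"pa{i}", f"pb{i}"
        mets[cur] = Metabolite(cur, 3)
        mets[pa] = Metabolite(pa, 3)
        mets[pb] = Metabolite(pb, 3)
        add_rxn(f"A{i}a", f"{prev} --> {pa}", f"{prev}(abc) --> {pa}(abc)",
                f"E_A{i}")
        add_rxn(f"A{i}b", f"{pa} --> {cur}", f"{pa}(abc) --> {cur}(abc)",
                f"E_A{i}x")
        # the B route permutes carbons 2 and 3
        add_rxn(f"B{i}a", f"{prev} --> {pb}", f"{prev}(abc) --> {pb}(acb)",
                f"E_B{i}")
        add_rxn(f"B{i}b", f"{pb} --> {cur}", f"{pb}(abc) --> {cur}(abc)",
                f"E_B{i}x")
    last = f"x{nbp}"
    mets["pre2"] = Metabolite("pre2", 2, is_biomass_precursor=True)
    mets["pre1"] = Metabolite("pre1", 1, is_biomass_precursor=True)
    add_rxn("CLV", f"{last} --> pre2 + pre1",
            f"{last}(abc) --> pre2(ab) + pre1(c)", "E_clv")
    add_rxn("SNK2", "pre2 -->", "pre2(ab) -->", "E_snk2", role="sink")
    add_rxn("SNK1", "pre1 -->", "pre1(a) -->", "E_snk1", role="sink")

    # optional reversibility on the second leg of A routes
    rev_candidates = [f"A{i}b" for i in range(1, nbp + 1)]
    for rid in rev_candidates[: spec.n_reversible]:
        rxns[rid].reversible = True

    # seeded regulation placement: inhibitors are internal metabolites not
    # participating in the regulated reaction
    regs: list[Regulation] = []
    internal = [m for m in mets.values() if not m.is_extracellular]
    reg_targets = [r for r in rxns.values() if r.role == ""]
    for mode in ("competitive", "uncompetitive", "noncompetitive"):
        for _ in range(spec.regulations_per_mode.get(mode, 0)):
            for _try in range(100):
                rxn = reg_targets[rng.integers(len(reg_targets))]
                met = internal[rng.integers(len(internal))]
                if met.id in rxn.stoichiometry:
                    continue
                if any(g.reaction_id == rxn.id and
                       g.inhibitor_metabolite_id == met.id for g in regs):
                    continue
                regs.append(Regulation(rxn.id, met.id, mode))
                break
    model = MetabolicModel(mets, rxns, regs, uptake_reaction_id="UPT")
    return model


def default_tracer(model: MetabolicModel) -> TracerSpec:
    """100% substrate labeled at carbons 1 and 2."""
    return {"sub_ext": [(1.0, frozenset({1, 2}))]}


def default_fragments(model: MetabolicModel) -> list[tuple[str, tuple[int, ...]]]:
    """Full-carbon fragments for every internal metabolite plus the [1,2]
    fragment of 3-carbon species (distinguishes permuting routes)."""
    frags = []
    for m in model.metabolites.values():
        if m.is_extracellular or m.carbon_count == 0:
            continue
        frags.append((m.id, tuple(range(1, m.carbon_count + 1))))
        if m.carbon_count >= 3:
            frags.append((m.id, (1, 2)))
    return frags


def default_knockouts(model: MetabolicModel, n_strains: int = 3
                      ) -> dict[str, dict[str, float]]:
    """Single-enzyme deletions of alternating branch routes."""
    enzymes = []
    i = 1
    while f"A{i}a" in model.reactions:
        enzymes.append(model.reactions[f"A{i}a"].enzyme_id)
        enzymes.append(model.reactions[f"B{i}a"].enzyme_id)
        i += 1
    if n_strains > len(enzymes):
        raise ModelError(f"only {len(enzymes)} branch enzymes available")
    return {f"d{e}": {e: 0.0} for e in enzymes[:n_strains]}


def wildtype_flux_distribution(model: MetabolicModel, splits: list[float],
                               uptake: float = 100.0) -> FluxDistribution:
    """Steady-state wild-type fluxes given per-branch split fractions."""
    nbp = sum(1 for r in model.reactions if r.startswith("A") and r.endswith("a"))
    if len(splits) != nbp:
        raise ModelError(f"need {nbp} split fractions")
    v = {"UPT": uptake}
    for i, s in enumerate(splits, start=1):
        v[f"A{i}a"] = v[f"A{i}b"] = uptake * s
        v[f"B{i}a"] = v[f"B{i}b"] = uptake * (1.0 - s)
    v["CLV"] = uptake
    v["SNK2"] = uptake
    v["SNK1"] = uptake
    reactions = list(model.reactions)
    return FluxDistribution(
        strain_id="wildtype", reactions=reactions,
        v=np.array([v.get(r, 0.0) for r in reactions]),
    )


def sample_ground_truth(
    model: MetabolicModel,
    seed: int = 0,
    knockouts: dict[str, dict[str, float]] | None = None,
    max_tries: int = 60,
    net=None,
) -> GroundTruth:
    """Sample (e, v_r) inside the parameterization bounds, anchor to a
    wild-type flux distribution, and keep the first draw for which the
    wild type and every planned knockout reach a stable steady state."""
    if knockouts is None:
        knockouts = default_knockouts(model)
    if net is None:
        net = decompose(model)
    last_err: Exception | None = None
    for trial in range(max_tries):
        rng = np.random.default_rng([seed, trial])
        splits = rng.uniform(0.35, 0.65, size=sum(
            1 for r in model.reactions if r.startswith("A") and r.endswith("a")))
        wt = wildtype_flux_distribution(model, list(splits))
        wt_map = wt.as_dict()
        e = np.zeros(net.n_complexes)
        for imech in range(len(net.mechanisms)):
            cxs = np.flatnonzero(net.complex_mechanism == imech)
            d = rng.dirichlet(np.full(len(cxs), 2.0))
            d = np.maximum(d, 1e-3)
            e[cxs] = d / d.sum()
        vr_min = np.array([
            max(0.0, -wt_map.get(s.reaction_id, 0.0)) if s.is_main_path else 0.0
            for s in net.steps])
        v_r = vr_min + 10 ** rng.uniform(-1.0, 2.5, size=net.n_steps)
        try:
            params = anchor_wildtype(net, wt, e, v_r)
            if params.k_fwd.max() >= K_UPPER or params.k_rev.max() >= K_UPPER:
                raise ModelError("rate constant above bound")
            wt_state = steady_state(net, params, max_iter=200)
            ok, _ = stability_check(net, params, wt_state)
            if not ok:
                raise UnstableError("wild-type state unstable")
            strain_states = {}
            for sid, levels in knockouts.items():
                st = steady_state(net, params, levels, max_iter=400)
                ok, _ = stability_check(net, params, st)
                if not ok:
                    raise UnstableError(f"{sid} state unstable")
                strain_states[sid] = st
        except (ModelError, NonConvergentError, UnstableError) as exc:
            last_err = exc
            continue
        return GroundTruth(params, wt_state, strain_states, dict(knockouts))
    raise ModelError(
        f"no stable ground truth found in {max_tries} tries "
        f"(last failure: {last_err})")


def simulate_dataset(
    model: MetabolicModel,
    truth: GroundTruth,
    noise_cv: float = 0.05,
    seed: int = 0,
    with_mids: bool = False,
    mid_sd: float = 0.003,
) -> tuple[TrainingSet, dict[str, MIDSet] | None]:
    """Simulate a training set from the ground truth.

    Strain fluxes receive multiplicative Gaussian noise (CV ``noise_cv``,
    truncated at +/- 4 sigma); weighting SDs follow the floor rule
    ``max(1.0, 0.05 |v|, CV-implied SD)``.  Optionally simulates each
    strain's tracer MIDs with additive Gaussian noise of SD ``mid_sd``.
    """
    rng = np.random.default_rng(seed)
    reactions = list(model.reactions)
    wt = FluxDistribution(
        strain_id="wildtype", reactions=reactions,
        v=np.array([truth.wildtype_fluxes.get(r, 0.0) for r in reactions]),
    )
    strains = []
    skipped = []
    for sid, levels in truth.knockouts.items():
        st = truth.strain_states.get(sid)
        if st is None:
            skipped.append(sid)
            continue
        fluxes = {}
        for rid in reactions:
            v_true = st.as_flux_dict().get(rid, 0.0)
            eps = np.clip(rng.normal(0.0, 1.0), -4.0, 4.0) * noise_cv
            v_obs = v_true * (1.0 + eps)
            sd_mfa = noise_cv * abs(v_true)
            fluxes[rid] = (v_obs, apply_sd_floor(v_obs, sd_mfa))
        strains.append(StrainData(sid, fluxes, dict(levels)))
    train = TrainingSet(wt, strains)

    mids = None
    if with_mids:
        tracer = default_tracer(model)
        mids = {}
        for sid, st in [("wildtype", truth.wildtype_state),
                        *truth.strain_states.items()]:
            # fragments of metabolites that still carry flux in this
            # strain (a dead branch yields no measurable labeling)
            produced: dict[str, float] = {}
            fluxes = st.as_flux_dict()
            for rxn in model.reactions.values():
                if rxn.atom_map is None:
                    continue
                for met in rxn.products:
                    produced[met] = produced.get(met, 0.0) + abs(fluxes[rxn.id])
            frags = [(met, atoms) for met, atoms in default_fragments(model)
                     if produced.get(met, 0.0) > 1e-6]
            emu_net = build_emu_network(model, frags)
            clean = simulate_mids(emu_net, fluxes, tracer)
            noisy = {}
            sds = {}
            for key, mid in clean.mids.items():
                noise = np.clip(rng.normal(0.0, 1.0, size=mid.shape),
                                -4.0, 4.0) * mid_sd
                noisy[key] = mid + noise
                sds[key] = np.full_like(mid, mid_sd)
            mids[sid] = MIDSet(sid, noisy, sds)
    return train, mids
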