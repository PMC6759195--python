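"""Kinetic model parameterization against mutant flux distributions.

:class:`KineticModel` assembles a metabolic model, its elementary-step
decomposition and a :class:`TrainingSet` of strain flux distributions.
``fit`` runs randomly initialized multi-starts of a damped least-squares
(Levenberg-Marquardt) search over the anchoring variables — wild-type
enzyme-complex fractions ``e`` (on the per-enzyme simplex, via logits)
and reverse elementary fluxes ``v_r`` (log-transformed) — minimizing the
variance-weighted SSR between predicted mutant steady-state fluxes and
the training distributions.  Gradients use analytic steady-state
sensitivities (implicit function theorem on the mass-action system).

Weighting follows the SD floor rule ``SD = max(1.0, 0.05 |v|, SD_MFA)``
and mutant training fluxes are scaled to the wild-type basis by the
ratio of absolute glucose uptake rates.  A parameterization is accepted
when another local minimum lies within 10% of the best SSR and the best
model is stable under the requested validation perturbations; the
recovery rate is the fraction of starts whose mean squared flux
deviation from the best model is at most 0.05 per reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from kfitlab.core import FluxDistribution, MetabolicModel, ModelError
from kfitlab.elementary import (
    ElementaryNetwork,
    KineticParameterization,
    NonConvergentError,
    SteadyState,
    UnstableError,
    decompose,
    machine_for,
    stability_check,
    steady_state,
    E_LOWER,
    VR_UPPER,
    K_UPPER,
)

__all__ = [
    "StrainData", "TrainingSet", "KineticModel", "KineticResults", "LocalFit",
    "ModelSelection", "CVResult", "prepare_training", "compute_ssr",
    "accept_models", "cross_validate",
]

SD_FLOOR = 1.0
SD_REL = 0.05
NEIGHBOR_TOL = 0.10          # 10% SSR reproducibility window
RECOVERY_MSD = 0.05          # per-flux mean squared deviation for recovery
PENALTY_WEIGHT = 10.0


@dataclass
class StrainData:
    """Training target for one strain: flux distribution plus the enzyme
    levels realizing the genetic condition (0 = knockout)."""

    strain_id: str
    fluxes: dict[str, tuple[float, float]]  # reaction -> (v_obs, SD)
    enzyme_levels: dict[str, float] = field(default_factory=dict)

    @property
    def reactions(self) -> list[str]:
        return list(self.fluxes)


@dataclass
class TrainingSet:
    wildtype: FluxDistribution
    strains: list[StrainData]
    excluded_reactions: list[str] = field(default_factory=list)

    def __post_init__(self):
        for s in self.strains:
            for rid, (_, sd) in s.fluxes.items():
                if sd < SD_FLOOR - 1e-12:
                    raise ModelError(
                        f"strain {s.strain_id}: SD for {rid} below the "
                        f"{SD_FLOOR} floor"
                    )

    @property
    def n_residuals(self) -> int:
        return sum(len(s.fluxes) for s in self.strains)

    def without(self, strain_id: str) -> "TrainingSet":
        strains = [s for s in self.strains if s.strain_id != strain_id]
        if len(strains) == len(self.strains):
            raise ModelError(f"strain {strain_id} not in training set")
        return TrainingSet(self.wildtype, strains, list(self.excluded_reactions))

    def strain(self, strain_id: str) -> StrainData:
        for s in self.strains:
            if s.strain_id == strain_id:
                return s
        raise ModelError(f"strain {strain_id} not in training set")


def apply_sd_floor(v: float, sd_mfa: float) -> float:
    """Weighting SD: max(1.0, 5% of the flux, the 13C-MFA SD)."""
    return max(SD_FLOOR, SD_REL * abs(v), sd_mfa)


def prepare_training(
    mfa_results: dict[str, "object"],
    uptakes: dict[str, float],
    wildtype_strain: str = "wildtype",
    knockouts: dict[str, dict[str, float]] | None = None,
    excluded_reactions: list[str] | None = None,
) -> TrainingSet:
    """Assemble a training set from per-strain MFA fits.

    ``mfa_results`` maps strain id to an accepted MFA result (or bare
    :class:`FluxDistribution`); ``uptakes`` gives each strain's absolute
    glucose uptake rate.  Mutant fluxes (and SDs) are rescaled by the
    ratio of absolute mutant to wild-type uptake so all strains share the
    wild-type 100-unit basis, then the SD floor rule is applied.
    """
    knockouts = knockouts or {}
    excluded = list(excluded_reactions or [])
    if wildtype_strain not in mfa_results:
        raise ModelError(f"no wild-type entry {wildtype_strain!r}")
    if wildtype_strain not in uptakes:
        raise ModelError("missing wild-type uptake rate")

    def flux_dist(res) -> FluxDistribution:
        return res if isinstance(res, FluxDistribution) else res.flux_distribution

    wt = flux_dist(mfa_results[wildtype_strain])
    strains = []
    for sid, res in mfa_results.items():
        if sid == wildtype_strain:
            continue
        if sid not in uptakes:
            raise ModelError(f"missing absolute uptake for strain {sid}")
        fd = flux_dist(res)
        scale = uptakes[sid] / uptakes[wildtype_strain]
        fluxes = {}
        for i, rid in enumerate(fd.reactions):
            if rid in excluded:
                continue
            v = float(fd.v[i]) * scale
            sd_mfa = float(fd.sd[i]) * scale if fd.sd is not None else 0.0
            fluxes[rid] = (v, apply_sd_floor(v, sd_mfa))
        strains.append(StrainData(sid, fluxes, dict(knockouts.get(sid, {}))))
    return TrainingSet(wt, strains, excluded)


def compute_ssr(
    predictions: dict[str, SteadyState], train: TrainingSet
) -> tuple[float, dict[str, float], np.ndarray]:
    """Variance-weighted SSR, per-strain shares, and the residual vector."""
    res = []
    shares: dict[str, float] = {}
    for s in train.strains:
        if s.strain_id not in predictions:
            raise ModelError(f"no prediction for strain {s.strain_id}")
        st = predictions[s.strain_id]
        pred = st.as_flux_dict()
        r = np.array([
            (pred.get(rid, 0.0) - vobs) / sd
            for rid, (vobs, sd) in s.fluxes.items()
        ])
        shares[s.strain_id] = float(r @ r)
        res.append(r)
    r_all = np.concatenate(res) if res else np.zeros(0)
    return float(r_all @ r_all), shares, r_all


# ---------------------------------------------------------------------------
# parameter transform

class ParameterTransform:
    """Map unconstrained optimizer variables to (e, v_r).

    Enzyme-complex fractions use per-mechanism softmax logits (last
    complex gauged to 0); reverse elementary fluxes use ``v_r = v_min +
    exp(w)`` where ``v_min = max(0, -v_net)`` keeps forward fluxes
    positive for reactions with negative wild-type net flux.
    """

    def __init__(self, net: ElementaryNetwork, wt_fluxes: dict[str, float]):
        self.net = net
        self.n_mech = len(net.mechanisms)
        self.mech_complexes = [
            np.flatnonzero(net.complex_mechanism == i) for i in range(self.n_mech)
        ]
        self.logit_slices = []
        pos = 0
        for cxs in self.mech_complexes:
            k = len(cxs) - 1
            self.logit_slices.append(slice(pos, pos + k))
            pos += k
        self.n_logits = pos
        self.ns = net.n_steps
        self.n_params = self.n_logits + self.ns
        self.vr_min = np.zeros(self.ns)
        for s in net.steps:
            v_net = wt_fluxes.get(s.reaction_id, 0.0) if s.is_main_path else 0.0
            self.vr_min[s.index] = max(0.0, -v_net)
        self.v_net = np.array([
            wt_fluxes.get(s.reaction_id, 0.0) if s.is_main_path else 0.0
            for s in net.steps
        ])

    def theta_from(self, e: np.ndarray, v_r: np.ndarray) -> np.ndarray:
        z = np.zeros(self.n_params)
        for cxs, sl in zip(self.mech_complexes, self.logit_slices):
            ee = np.maximum(e[cxs], 1e-12)
            z[sl] = np.log(ee[:-1]) - np.log(ee[-1])
        w = np.log(np.maximum(v_r - self.vr_min, 1e-12))
        z[self.n_logits:] = w
        return z

    def unpack(self, theta: np.ndarray):
        e = np.zeros(self.net.n_complexes)
        for cxs, sl in zip(self.mech_complexes, self.logit_slices):
            logits = np.concatenate([theta[sl], [0.0]])
            logits -= logits.max()
            ex = np.exp(logits)
            e[cxs] = ex / ex.sum()
        w = theta[self.n_logits:]
        v_r = self.vr_min + np.exp(w)
        return e, v_r

    def k_and_grads(self, theta: np.ndarray):
        """Rate constants and their Jacobians w.r.t. theta."""
        e, v_r = self.unpack(theta)
        net = self.net
        ns = self.ns
        kf = np.empty(ns)
        kr = np.empty(ns)
        in_cx = np.array([s.complex_in for s in net.steps])
        out_cx = np.array([s.complex_out for s in net.steps])
        v_fwd = self.v_net + v_r
        kf = v_fwd / e[in_cx]
        kr = v_r / e[out_cx]

        dkf = np.zeros((ns, self.n_params))
        dkr = np.zeros((ns, self.n_params))
        expw = np.exp(theta[self.n_logits:])
        idx = np.arange(ns)
        dkf[idx, self.n_logits + idx] = expw / e[in_cx]
        dkr[idx, self.n_logits + idx] = expw / e[out_cx]
        # de/dz per mechanism: softmax Jacobian e_i (delta_ij - e_j)
        for im, (cxs, sl) in enumerate(zip(self.mech_complexes, self.logit_slices)):
            k = sl.stop - sl.start
            if k == 0:
                continue
            ee = e[cxs]
            Dz = np.zeros((len(cxs), k))
            for j in range(k):
                Dz[:, j] = -ee * ee[j]
                Dz[j, j] += ee[j]
            local = {int(c): row for c, row in zip(cxs, range(len(cxs)))}
            for s in net.steps:
                if int(s.complex_in) in local:
                    row = Dz[local[int(s.complex_in)]]
                    dkf[s.index, sl] += -kf[s.index] / e[s.complex_in] * row
                if int(s.complex_out) in local:
                    row = Dz[local[int(s.complex_out)]]
                    dkr[s.index, sl] += -kr[s.index] / e[s.complex_out] * row
        return e, v_r, kf, kr, dkf, dkr

    def sample(self, rng: np.random.Generator,
               vr_log_range: tuple[float, float] = (0.0, 2.5)) -> np.ndarray:
        """Random start: flat Dirichlet enzyme fractions truncated to
        (1e-3, 1); reverse fluxes log-uniform over ``vr_log_range``
        decades (default spanning the net-flux scale of the 100-unit
        basis; pass ``(-3, 4)`` to draw across the full parameter
        bounds)."""
        e = np.zeros(self.net.n_complexes)
        for cxs in self.mech_complexes:
            d = rng.dirichlet(np.ones(len(cxs)))
            d = np.maximum(d, E_LOWER)
            e[cxs] = d / d.sum()
        v_r = self.vr_min + 10 ** rng.uniform(*vr_log_range, size=self.ns)
        return self.theta_from(e, v_r)


# ---------------------------------------------------------------------------
# fit results

@dataclass
class LocalFit:
    start_index: int
    theta: np.ndarray
    ssr: float
    converged: bool
    params: KineticParameterization
    predictions: dict[str, SteadyState]
    n_iter: int = 0

    def to_json_dict(self) -> dict:
        d = self.params.to_json_dict()
        d.update({"ssr": self.ssr, "start_index": self.start_index,
                  "converged": self.converged})
        return d


@dataclass
class ModelSelection:
    best: LocalFit
    neighbors_within_10pct: int
    recovery_rate: float
    accepted: bool
    stability_verdicts: dict[str, bool] = field(default_factory=dict)


@dataclass
class CVResult:
    held_out_strain: str
    fit_ssr: float
    held_out_ssr: float
    n_starts_used: int
    recovery_rate: float
    predicted_uptake: float
    observed_uptake: float
    results: "KineticResults"


class KineticResults:
    """Multi-start fit outcome: local minima sorted by SSR plus the
    acceptance verdict and diagnostics for the best model."""

    def __init__(self, model: "KineticModel", fits: list[LocalFit],
                 n_starts: int, seed: int):
        if not fits:
            raise ModelError("zero kinetic fit starts converged")
        self.model_ = model
        self.fits = sorted(fits, key=lambda f: f.ssr)
        self.n_starts = n_starts
        self.seed = seed
        self.selection: ModelSelection | None = None

    @property
    def best(self) -> LocalFit:
        return self.fits[0]

    @property
    def ssr(self) -> float:
        return self.best.ssr

    @property
    def params(self) -> KineticParameterization:
        return self.best.params

    @property
    def predictions(self) -> dict[str, SteadyState]:
        return self.best.predictions

    def per_strain_ssr(self) -> dict[str, float]:
        _, shares, _ = compute_ssr(self.best.predictions, self.model_.training)
        return shares

    def residuals(self) -> np.ndarray:
        _, _, r = compute_ssr(self.best.predictions, self.model_.training)
        return r

    def accept(self, validation_perturbations: list[dict[str, float]] | None = None
               ) -> ModelSelection:
        self.selection = accept_models(
            self, validation_perturbations=validation_perturbations)
        return self.selection

    def sensitivity(self):
        from kfitlab.analysis import sensitivity

        return sensitivity(self, self.model_.training)

    def summary(self) -> str:
        shares = self.per_strain_ssr()
        n_res = self.model_.training.n_residuals
        lines = [
            "Kinetic parameterization",
            f"  starts {self.n_starts}  converged {len(self.fits)}  "
            f"best SSR {self.ssr:.4g}  "
            f"mean weighted squared residual {self.ssr / max(n_res, 1):.3g}",
            "  per-strain SSR share:",
        ]
        for sid, share in shares.items():
            lines.append(f"    {sid:>12s}  {share:9.3g}  "
                         f"({share / max(self.ssr, 1e-300):.0%})")
        if self.selection is not None:
            sel = self.selection
            lines.append(
                f"  acceptance: neighbors within 10% = "
                f"{sel.neighbors_within_10pct}, recovery rate "
                f"{sel.recovery_rate:.1%}, accepted={sel.accepted}")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "n_starts": self.n_starts,
            "seed": self.seed,
            "ssrs": [f.ssr for f in self.fits],
            "best": self.best.to_json_dict(),
        }


# ---------------------------------------------------------------------------
# the model

class KineticModel:
    """Kinetic parameterization problem for a metabolic model.

    Parameters
    ----------
    model:
        Metabolic model with enzyme assignments (and regulations).
    training:
        Training set; the wild-type distribution anchors the parameters.
    orders:
        Optional binding/release order overrides for the decomposition.
    """

    def __init__(self, model: MetabolicModel, training: TrainingSet,
                 orders=None, net: ElementaryNetwork | None = None):
        self.model = model
        self.training = training
        self.net = net if net is not None else decompose(model, orders)
        wt = training.wildtype.as_dict()
        self.transform = ParameterTransform(self.net, wt)
        self.wt_fluxes = wt
        self._fit_targets = []
        for s in training.strains:
            rids = [r for r in s.fluxes if r not in training.excluded_reactions]
            v_obs = np.array([s.fluxes[r][0] for r in rids])
            sds = np.array([s.fluxes[r][1] for r in rids])
            mech_pos = np.array(
                [self.net.mechanisms.index(r) if r in self.net.mechanisms else -1
                 for r in rids], dtype=int)
            self._fit_targets.append((s, rids, v_obs, sds, mech_pos))

    # -- residual / jacobian evaluation -----------------------------------
    def _anchored(self, theta: np.ndarray):
        e, v_r, kf, kr, dkf, dkr = self.transform.k_and_grads(theta)
        params = KineticParameterization(
            self.net, e, v_r, kf, kr, dict(self.wt_fluxes))
        return params, dkf, dkr

    def _penalties(self, theta, params, dkf, dkr, with_jac: bool):
        """Soft hinge penalties keeping e, v_r and k inside their bounds."""
        rows, jrows = [], []
        tr = self.transform
        # e lower bound (1e-3) as a log-scale hinge
        e = params.e
        under = np.log(np.maximum(E_LOWER / np.maximum(e, 1e-300), 1e-300))
        act_e = under > 0
        if np.any(act_e):
            rows.append(PENALTY_WEIGHT * under[act_e])
            if with_jac:
                J = np.zeros((int(act_e.sum()), tr.n_params))
                for row_i, ci in enumerate(np.flatnonzero(act_e)):
                    im = int(self.net.complex_mechanism[ci])
                    cxs = tr.mech_complexes[im]
                    sl = tr.logit_slices[im]
                    k = sl.stop - sl.start
                    if k == 0:
                        continue
                    ee = e[cxs]
                    pos = int(np.flatnonzero(cxs == ci)[0])
                    # d log e_pos / dz_j = delta_{pos j} - e_j
                    dlog = -ee[:k].copy()
                    if pos < k:
                        dlog[pos] += 1.0
                    J[row_i, sl] = -PENALTY_WEIGHT * dlog
                jrows.append(J)
        # v_r upper bound (log-scale hinge)
        w = theta[tr.n_logits:]
        vr = params.v_r
        over = np.log(np.maximum(vr / VR_UPPER, 1e-300))
        act = over > 0
        if np.any(act):
            rows.append(PENALTY_WEIGHT * over[act])
            if with_jac:
                J = np.zeros((int(act.sum()), tr.n_params))
                idx = np.flatnonzero(act)
                J[np.arange(len(idx)), tr.n_logits + idx] = (
                    PENALTY_WEIGHT * np.exp(w[idx]) / vr[idx])
                jrows.append(J)
        # k upper bounds
        for kvec, dk in ((params.k_fwd, dkf), (params.k_rev, dkr)):
            over = np.log(np.maximum(kvec / K_UPPER, 1e-300))
            act = over > 0
            if np.any(act):
                rows.append(PENALTY_WEIGHT * over[act])
                if with_jac:
                    idx = np.flatnonzero(act)
                    jrows.append(PENALTY_WEIGHT * dk[idx] / kvec[idx, None])
        if not rows:
            z = np.zeros(0)
            return z, (np.zeros((0, tr.n_params)) if with_jac else None)
        r = np.concatenate(rows)
        return r, (np.vstack(jrows) if with_jac else None)

    def residuals(self, theta: np.ndarray, with_jac: bool = False,
                  warm: dict | None = None):
        """Weighted residual vector (and Jacobian) at theta.

        Raises NonConvergentError/UnstableError when any training strain's
        steady state cannot be evaluated.
        """
        params, dkf, dkr = self._anchored(theta)
        mach = machine_for(self.net)
        res_blocks, jac_blocks = [], []
        predictions: dict[str, SteadyState] = {}
        for s, rids, v_obs, sds, mech_pos in self._fit_targets:
            init = None if warm is None else warm.get(s.strain_id)
            st = steady_state(self.net, params, s.enzyme_levels, init=init,
                              max_iter=400)
            if warm is not None:
                warm[s.strain_id] = st.c[mach.free_idx]
            predictions[s.strain_id] = st
            pred = st.as_flux_dict()
            v_pred = np.array([pred.get(r, 0.0) for r in rids])
            res_blocks.append((v_pred - v_obs) / sds)
            if with_jac:
                u = np.log(np.maximum(st.c, 1e-300))
                a, b = mach.rate_factors(u, params.k_fwd, params.k_rev)
                dv = mach.flux_sensitivities(u, st.x, a, b, params.k_fwd,
                                             params.k_rev, dkf, dkr)
                J = np.zeros((len(rids), self.transform.n_params))
                for i, mp in enumerate(mech_pos):
                    if mp >= 0:
                        J[i] = dv[mp] / sds[i]
                jac_blocks.append(J)
        rp, jp = self._penalties(theta, params, dkf, dkr, with_jac)
        r = np.concatenate(res_blocks + [rp])
        if with_jac:
            J = np.vstack(jac_blocks + [jp])
            return r, J, params, predictions
        return r, None, params, predictions

    def ssr_components(self, theta: np.ndarray):
        r, _, params, predictions = self.residuals(theta)
        return float(r @ r), params, predictions

    # -- Levenberg-Marquardt local search ----------------------------------
    def _local_fit(self, theta0: np.ndarray, start_index: int,
                   max_iter: int = 400, ftol: float = 1e-8,
                   gtol: float = 1e-6, max_resets: int = 8,
                   step_cap: float = 10.0) -> LocalFit | None:
        warm: dict = {}
        try:
            r, J, params, preds = self.residuals(theta0, with_jac=True,
                                                 warm=warm)
        except (NonConvergentError, UnstableError):
            return None
        theta = theta0.copy()
        ssr = float(r @ r)
        lam = 1e-3
        converged = False
        stall = 0
        resets = 0
        ssr_at_reset = np.inf
        it = 0
        for it in range(max_iter):
            g = J.T @ r
            if np.max(np.abs(g)) < gtol or ssr < 1e-12:
                converged = True
                break
            JTJ = J.T @ J
            accepted_step = False
            for _ in range(25):
                A = JTJ + lam * (np.diag(np.diag(JTJ)) + 1e-10 * np.eye(len(theta)))
                try:
                    dtheta = np.linalg.solve(A, -g)
                except np.linalg.LinAlgError:
                    lam *= 10
                    continue
                dtheta = np.clip(dtheta, -step_cap, step_cap)
                try:
                    r_t, J_t, params_t, preds_t = self.residuals(
                        theta + dtheta, with_jac=True, warm=dict(warm))
                except (NonConvergentError, UnstableError):
                    lam *= 10
                    continue
                ssr_t = float(r_t @ r_t)
                if np.isfinite(ssr_t) and ssr_t < ssr:
                    rel = (ssr - ssr_t) / max(ssr, 1e-300)
                    theta = theta + dtheta
                    r, J, params, preds = r_t, J_t, params_t, preds_t
                    ssr = ssr_t
                    lam = max(lam * 0.3, 1e-12)
                    accepted_step = True
                    stall = stall + 1 if rel < ftol else 0
                    break
                lam *= 10
            if not accepted_step or stall >= 3:
                # damping reset: re-enter the loop from the current point
                # as long as the previous round made progress
                if resets < max_resets and ssr < ssr_at_reset * (1.0 - 1e-6):
                    ssr_at_reset = ssr
                    lam = 1e-3
                    stall = 0
                    resets += 1
                    continue
                converged = True  # local minimum within tolerance
                break
        return LocalFit(start_index, theta, ssr, converged, params, preds,
                        n_iter=it + 1)

    # -- public API --------------------------------------------------------
    def fit(self, n_starts: int = 500, seed: int = 0) -> KineticResults:
        """Randomly initialized multi-start parameterization."""
        fits = []
        for istart in range(n_starts):
            rng = np.random.default_rng([seed, istart])
            theta0 = self.transform.sample(rng)
            local = self._local_fit(theta0, istart)
            if local is not None and local.converged:
                fits.append(local)
        return KineticResults(self, fits, n_starts, seed)

    def fit_from(self, e: np.ndarray, v_r: np.ndarray) -> LocalFit:
        """Single local fit from an explicit parameter point."""
        theta0 = self.transform.theta_from(e, v_r)
        local = self._local_fit(theta0, -1)
        if local is None:
            raise NonConvergentError("initial point not evaluable")
        return local

    def evaluate(self, e: np.ndarray, v_r: np.ndarray):
        """Anchor and evaluate SSR at an explicit parameter point."""
        theta = self.transform.theta_from(e, v_r)
        return self.ssr_components(theta)


# ---------------------------------------------------------------------------
# acceptance and cross-validation

def _prediction_msd(a: LocalFit, b: LocalFit) -> float:
    """Mean squared deviation between two fits' predicted fluxes."""
    num, den = 0.0, 0
    for sid, st in a.predictions.items():
        other = b.predictions.get(sid)
        if other is None:
            continue
        d = st.v - other.v
        num += float(d @ d)
        den += len(d)
    return num / max(den, 1)


def accept_models(
    results: KineticResults,
    validation_perturbations: list[dict[str, float]] | None = None,
) -> ModelSelection:
    """Apply the model-acceptance rules to a multi-start outcome."""
    best = results.best
    neighbors = sum(
        1 for f in results.fits[1:] if f.ssr <= (1.0 + NEIGHBOR_TOL) * best.ssr
    )
    recovered = sum(
        1 for f in results.fits if _prediction_msd(f, best) <= RECOVERY_MSD
    )
    recovery_rate = recovered / results.n_starts
    verdicts: dict[str, bool] = {}
    stable_all = True
    for i, levels in enumerate(validation_perturbations or []):
        name = f"perturbation_{i}"
        try:
            st = steady_state(results.model_.net, best.params, levels,
                              max_iter=400)
            ok, _ = stability_check(results.model_.net, best.params, st)
        except (NonConvergentError, UnstableError):
            ok = False
        verdicts[name] = ok
        stable_all = stable_all and ok
    accepted = neighbors >= 1 and stable_all
    sel = ModelSelection(best, neighbors, recovery_rate, accepted, verdicts)
    results.selection = sel
    return sel


def cross_validate(
    kmodel: KineticModel,
    held_out_strain: str,
    seed: int = 0,
    max_starts: int = 50,
    reference: KineticResults | None = None,
) -> CVResult:
    """Leave-one-out cross-validation for one strain.

    A new model is parameterized on the training set without the strain;
    starts accumulate until the SSR drops below the full-fit best SSR or
    the recovery rate falls below the full-fit recovery rate (when a
    reference fit is supplied), up to ``max_starts``.  The refit model
    then predicts the held-out strain.
    """
    held = kmodel.training.strain(held_out_strain)
    sub = KineticModel(kmodel.model, kmodel.training.without(held_out_strain),
                       net=kmodel.net)
    ref_ssr = reference.ssr if reference is not None else None
    ref_recovery = (reference.selection.recovery_rate
                    if reference is not None and reference.selection is not None
                    else None)
    fits: list[LocalFit] = []
    n_used = 0
    for istart in range(max_starts):
        n_used = istart + 1
        rng = np.random.default_rng([seed, istart])
        local = sub._local_fit(sub.transform.sample(rng), istart)
        if local is not None and local.converged:
            fits.append(local)
        if not fits:
            continue
        best = min(fits, key=lambda f: f.ssr)
        if ref_ssr is not None and best.ssr < ref_ssr:
            break
        if ref_recovery is not None and len(fits) >= 2:
            rec = sum(1 for f in fits
                      if _prediction_msd(f, best) <= RECOVERY_MSD) / n_used
            if rec < ref_recovery:
                break
    if not fits:
        raise ModelError("cross-validation: no start converged")
    results = KineticResults(sub, fits, n_used, seed)
    best = results.best
    recovered = sum(1 for f in fits
                    if _prediction_msd(f, best) <= RECOVERY_MSD)
    # predict the held-out strain
    st = steady_state(sub.net, best.params, held.enzyme_levels, max_iter=400)
    pred = st.as_flux_dict()
    r = np.array([
        (pred.get(rid, 0.0) - vobs) / sd
        for rid, (vobs, sd) in held.fluxes.items()
    ])
    upt_rxn = kmodel.model.uptake_reaction_id
    observed_upt = held.fluxes.get(upt_rxn, (np.nan, 1.0))[0] if upt_rxn else np.nan
    predicted_upt = pred.get(upt_rxn, np.nan) if upt_rxn else np.nan
    return CVResult(
        held_out_strain=held_out_strain,
        fit_ssr=best.ssr,
        held_out_ssr=float(r @ r),
        n_starts_used=n_used,
        recovery_rate=recovered / n_used,
        predicted_uptake=float(predicted_upt),
        observed_uptake=float(observed_upt),
        results=results,
    )
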