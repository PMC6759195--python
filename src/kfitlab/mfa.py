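"""13C-MFA flux elucidation: multi-start variance-weighted fitting of
simulated to measured mass isotopomer distributions, profile-likelihood
confidence intervals, and cross-network flux projection.

The flux space is parameterized by a null-space basis of the internal
stoichiometric matrix with the glucose uptake pinned to the 100-unit
basis; reversible reactions additionally carry a bounded exchange flux.
The objective is the variance-weighted SSR between measured and simulated
MIDs plus measured-rate residuals.  A fit is *accepted* only when at
least half of the random multi-starts converge to the best solution
(two optima count as the same solution when every net flux agrees within
``max(0.1 unit, 1%)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy.stats import chi2, norm

from kfitlab.core import FluxDistribution, MetabolicModel, ModelError
from kfitlab.emu import EMUNetwork, MIDSet, TracerSpec, build_emu_network, simulate_mids

__all__ = ["MFAModel", "MFAResults", "RateConstraint", "project_fluxes"]

FLUX_CAP = 1000.0
EXCHANGE_CAP = 200.0


@dataclass
class RateConstraint:
    reaction_id: str
    value: float
    sd: float


def _solution_match(v1: np.ndarray, v2: np.ndarray) -> bool:
    tol = np.maximum(0.1, 0.01 * np.abs(v1))
    return bool(np.all(np.abs(v1 - v2) <= tol))


@dataclass
class MFAResults:
    """Best-SSR flux distribution with convergence diagnostics."""

    model_: "MFAModel"
    flux_distribution: FluxDistribution
    ssr: float
    dof: int
    free_flux_vector: np.ndarray
    n_starts: int
    convergence_fraction: float
    accepted: bool
    start_ssrs: list[float] = field(default_factory=list)
    ci_failures: list[str] = field(default_factory=list)

    @property
    def exchange(self) -> dict[str, float]:
        return self.model_._exchange_from_params(self.free_flux_vector)

    def conf_int(self, alpha: float = 0.05) -> FluxDistribution:
        """Profile-likelihood confidence intervals per reaction: extreme
        fluxes subject to SSR <= SSR* + chi2(1, 1-alpha)."""
        fd = self.model_._profile_cis(self, alpha)
        self.flux_distribution = fd
        return fd

    def predict_mids(self) -> MIDSet:
        return self.model_._simulate(self.free_flux_vector)

    def summary(self) -> str:
        lines = [
            "13C-MFA fit" + (f" [{self.flux_distribution.strain_id}]" if
                             self.flux_distribution.strain_id else ""),
            f"  SSR {self.ssr:.4g}   DOF {self.dof}   "
            f"starts {self.n_starts}   convergence {self.convergence_fraction:.0%}   "
            f"accepted {self.accepted}",
            self.flux_distribution.to_frame().to_string(index=False),
        ]
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "strain": self.flux_distribution.strain_id,
            "ssr": self.ssr,
            "dof": self.dof,
            "n_starts": self.n_starts,
            "convergence_fraction": self.convergence_fraction,
            "accepted": self.accepted,
            "reactions": self.flux_distribution.reactions,
            "v": self.flux_distribution.v.tolist(),
        }


class MFAModel:
    """Flux elucidation problem for one strain.

    Parameters
    ----------
    model:
        Validated metabolic model with atom maps.
    mids:
        Measured MIDs (with per-entry SDs) for a set of fragments.
    tracer:
        Substrate labeling, e.g. ``{"glc_ext": [(1.0, frozenset({1, 2}))]}``
        for 100% [1,2-13C]glucose.
    rate_constraints:
        Measured extracellular rates (uptake, growth, secretion) as
        value +/- SD on the 100-unit basis.
    basis_uptake:
        The uptake flux is pinned to this value (100 by convention).
    """

    def __init__(
        self,
        model: MetabolicModel,
        mids: MIDSet,
        tracer: TracerSpec,
        rate_constraints: list[RateConstraint] | None = None,
        strain_id: str = "",
        knockouts: list[str] | None = None,
        basis_uptake: float = 100.0,
        default_mid_sd: float = 0.003,
    ):
        self.model = model
        self.mids = mids
        self.tracer = tracer
        self.rate_constraints = list(rate_constraints or [])
        self.strain_id = strain_id or mids.strain_id
        self.basis_uptake = basis_uptake
        self.knockouts = list(knockouts or [])
        self.default_mid_sd = default_mid_sd

        self.reactions = list(model.reactions)
        self.fragments = list(mids.mids)
        self.emu_net: EMUNetwork = build_emu_network(model, self.fragments)
        self._build_parameterization()
        self._build_measurements()

    # -- flux-space parameterization ------------------------------------
    def _build_parameterization(self) -> None:
        model = self.model
        S = model.stoichiometric_matrix(internal_only=True).to_numpy()
        n = len(self.reactions)
        rows = [S]
        rhs = [np.zeros(S.shape[0])]
        if model.uptake_reaction_id is not None:
            e = np.zeros((1, n))
            e[0, self.reactions.index(model.uptake_reaction_id)] = 1.0
            rows.append(e)
            rhs.append(np.array([self.basis_uptake]))
        for rid in self.knockouts:
            e = np.zeros((1, n))
            e[0, self.reactions.index(rid)] = 1.0
            rows.append(e)
            rhs.append(np.array([0.0]))
        A = np.vstack(rows)
        b = np.concatenate(rhs)
        v0, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ v0 - b)) > 1e-6:
            raise ModelError("infeasible constraints: no steady-state flux "
                             "satisfies uptake/knockout equalities")
        self.v_particular = v0
        self.basis = scipy.linalg.null_space(A)
        self.n_free = self.basis.shape[1]
        self.reversible = [r for r in self.reactions
                           if model.reactions[r].reversible]
        self.n_exchange = len(self.reversible)
        self.irrev_rows = np.array(
            [i for i, r in enumerate(self.reactions)
             if not model.reactions[r].reversible],
            dtype=int,
        )

    def _build_measurements(self) -> None:
        meas, sds = [], []
        for key in self.fragments:
            m = self.mids.mids[key]
            sd = None if self.mids.sds is None else self.mids.sds.get(key)
            if sd is None:
                sd = np.full_like(m, self.default_mid_sd)
            meas.append(np.asarray(m, float))
            sds.append(np.asarray(sd, float))
        self._mid_meas = meas
        self._mid_sds = sds
        self.n_measurements = sum(len(m) for m in meas) + len(self.rate_constraints)
        self.dof = self.n_measurements - (self.n_free + self.n_exchange)

    # -- helpers ---------------------------------------------------------
    def _net_fluxes(self, params: np.ndarray) -> np.ndarray:
        alpha = params[: self.n_free]
        return self.v_particular + self.basis @ alpha

    def _exchange_from_params(self, params: np.ndarray) -> dict[str, float]:
        xi = params[self.n_free:]
        return dict(zip(self.reversible, xi))

    def _simulate(self, params: np.ndarray) -> MIDSet:
        v = self._net_fluxes(params)
        net = dict(zip(self.reactions, v))
        return simulate_mids(self.emu_net, net, self.tracer,
                             exchange=self._exchange_from_params(params))

    def residuals(self, params: np.ndarray) -> np.ndarray:
        try:
            sim = self._simulate(params)
        except (ModelError, np.linalg.LinAlgError):
            return np.full(self.n_measurements, 1e3)
        res = []
        for key, meas, sd in zip(self.fragments, self._mid_meas, self._mid_sds):
            res.append((sim.mids[key] - meas) / sd)
        v = self._net_fluxes(params)
        for rc in self.rate_constraints:
            res.append(
                np.atleast_1d(
                    (v[self.reactions.index(rc.reaction_id)] - rc.value) / rc.sd
                )
            )
        return np.concatenate(res)

    def ssr(self, params: np.ndarray) -> float:
        r = self.residuals(params)
        return float(r @ r)

    def _constraints(self):
        cons = []
        if len(self.irrev_rows):
            def irrev(params):
                return self._net_fluxes(params)[self.irrev_rows]
            cons.append({"type": "ineq", "fun": irrev})

        def cap(params):
            v = self._net_fluxes(params)
            return FLUX_CAP - np.abs(v)
        cons.append({"type": "ineq", "fun": cap})
        return cons

    def _param_bounds(self):
        return [(-FLUX_CAP, FLUX_CAP)] * self.n_free + \
               [(0.0, EXCHANGE_CAP)] * self.n_exchange

    def _feasible(self, params: np.ndarray, tol: float = 1e-7) -> bool:
        v = self._net_fluxes(params)
        if len(self.irrev_rows) and np.min(v[self.irrev_rows]) < -tol:
            return False
        return bool(np.max(np.abs(v)) <= FLUX_CAP + tol)

    def sample_start(self, rng: np.random.Generator,
                     max_tries: int = 200) -> np.ndarray:
        """Uniformly sample a feasible free-flux vector within bounds."""
        box = self._alpha_box()
        for _ in range(max_tries):
            alpha = rng.uniform(box[:, 0], box[:, 1])
            xi = 10 ** rng.uniform(-2, 1, size=self.n_exchange)
            params = np.concatenate([alpha, xi])
            if self._feasible(params):
                return params
        # fall back to the least-squares particular point
        return np.concatenate([np.zeros(self.n_free),
                               np.ones(self.n_exchange)])

    def _alpha_box(self) -> np.ndarray:
        if getattr(self, "_alpha_box_cache", None) is not None:
            return self._alpha_box_cache
        n = self.n_free
        box = np.zeros((n, 2))
        A_ub, b_ub = self._lp_constraints()
        for i in range(n):
            c = np.zeros(n)
            for j, sign in ((0, 1.0), (1, -1.0)):
                c[i] = sign
                res = scipy.optimize.linprog(
                    c, A_ub=A_ub, b_ub=b_ub, bounds=[(None, None)] * n,
                    method="highs")
                box[i, j] = (res.x[i] if res.status == 0
                             else -FLUX_CAP if j == 0 else FLUX_CAP)
        self._alpha_box_cache = box
        return box

    def _lp_constraints(self):
        # -N alpha <= v0 for irreversible rows; |v| <= cap for all rows
        N, v0 = self.basis, self.v_particular
        A_ub = np.vstack([-N[self.irrev_rows], N, -N])
        b_ub = np.concatenate([
            v0[self.irrev_rows],
            FLUX_CAP - v0,
            FLUX_CAP + v0,
        ])
        return A_ub, b_ub

    # -- fitting ----------------------------------------------------------
    def fit(self, n_starts: int = 100, seed: int = 0,
            require_acceptance: bool = False) -> MFAResults:
        """Multi-start flux fitting; returns the best-SSR solution."""
        solutions = []
        for istart in range(n_starts):
            rng = np.random.default_rng([seed, istart])
            x0 = self.sample_start(rng)
            res = scipy.optimize.minimize(
                self.ssr, x0, method="SLSQP", bounds=self._param_bounds(),
                constraints=self._constraints(),
                options={"maxiter": 300, "ftol": 1e-10},
            )
            if np.isfinite(res.fun):
                solutions.append((float(res.fun), res.x))
        if not solutions:
            raise ModelError("no 13C-MFA start converged")
        solutions.sort(key=lambda t: t[0])
        best_ssr, best_x = solutions[0]
        best_v = self._net_fluxes(best_x)
        n_match = sum(
            1 for s, x in solutions
            if _solution_match(best_v, self._net_fluxes(x))
        )
        frac = n_match / n_starts
        accepted = frac >= 0.5
        if require_acceptance and not accepted:
            raise ModelError(
                f"best solution recovered in only {frac:.0%} of starts")
        fd = FluxDistribution(
            strain_id=self.strain_id, reactions=self.reactions, v=best_v,
            basis_uptake=self.basis_uptake,
        )
        return MFAResults(
            model_=self, flux_distribution=fd, ssr=best_ssr, dof=self.dof,
            free_flux_vector=best_x, n_starts=n_starts,
            convergence_fraction=frac, accepted=accepted,
            start_ssrs=[s for s, _ in solutions],
        )

    # -- profile confidence intervals -------------------------------------
    def _profile_cis(self, fit: MFAResults, alpha: float) -> FluxDistribution:
        thr = fit.ssr + chi2.ppf(1.0 - alpha, df=1)
        x_best = fit.free_flux_vector
        v_best = self._net_fluxes(x_best)
        lo = np.empty_like(v_best)
        hi = np.empty_like(v_best)
        failures = []
        cons = self._constraints() + [
            {"type": "ineq", "fun": lambda p: thr - self.ssr(p)}
        ]
        for j, rid in enumerate(self.reactions):
            row = self.basis[j]
            for sign, store in ((1.0, hi), (-1.0, lo)):
                if np.max(np.abs(row)) < 1e-12:
                    store[j] = v_best[j]  # fully determined flux
                    continue

                def obj(p, _row=row, _s=sign, _j=j):
                    return -_s * self._net_fluxes(p)[_j]

                res = scipy.optimize.minimize(
                    obj, x_best, method="SLSQP", bounds=self._param_bounds(),
                    constraints=cons, options={"maxiter": 200, "ftol": 1e-8},
                )
                if res.success or np.isfinite(res.fun):
                    store[j] = self._net_fluxes(res.x)[j]
                else:
                    store[j] = sign * FLUX_CAP
                    failures.append(rid)
        lo2 = np.minimum(lo, v_best)
        hi2 = np.maximum(hi, v_best)
        z = -norm.ppf(alpha / 2.0)
        sd = (hi2 - lo2) / (2.0 * z)
        fd = FluxDistribution(
            strain_id=self.strain_id, reactions=self.reactions, v=v_best,
            sd=sd, ci_lo=lo2, ci_hi=hi2, basis_uptake=self.basis_uptake,
        )
        fit.ci_failures = failures
        return fd


# ---------------------------------------------------------------------------
# cross-network flux projection

def project_fluxes(
    source: FluxDistribution,
    target: MetabolicModel,
    mapping: dict[str, str] | None = None,
    pinned: dict[str, float] | None = None,
) -> tuple[FluxDistribution, float]:
    """Project confidence intervals elucidated on one network onto another.

    Finds a steady-state distribution on ``target`` minimizing the total
    absolute excursion outside the source ``[ci_lo, ci_hi]`` intervals of
    mapped reactions.  ``mapping`` sends source reaction ids to target
    reaction ids (identity by default).  Returns the projected
    distribution and the total violation (flux units).
    """
    if source.ci_lo is None or source.ci_hi is None:
        raise ModelError("source distribution has no confidence intervals")
    mapping = mapping or {r: r for r in source.reactions
                          if r in target.reactions}
    reactions = list(target.reactions)
    n = len(reactions)
    S = target.stoichiometric_matrix(internal_only=True).to_numpy()

    mapped = [(reactions.index(mapping[r]), i)
              for i, r in enumerate(source.reactions) if r in mapping]
    m = len(mapped)
    # variables: v (n), slack s (m) with s_k >= violation of interval k
    c = np.concatenate([np.zeros(n), np.ones(m)])
    A_eq = np.hstack([S, np.zeros((S.shape[0], m))])
    b_eq = np.zeros(S.shape[0])
    rows_ub, rhs_ub = [], []
    for k, (j, i) in enumerate(mapped):
        row = np.zeros(n + m)
        row[j], row[n + k] = 1.0, -1.0  # v_j - s_k <= hi
        rows_ub.append(row.copy())
        rhs_ub.append(float(source.ci_hi[i]))
        row = np.zeros(n + m)
        row[j], row[n + k] = -1.0, -1.0  # -v_j - s_k <= -lo
        rows_ub.append(row)
        rhs_ub.append(-float(source.ci_lo[i]))
    A_ub = np.vstack(rows_ub) if rows_ub else None
    b_ub = np.array(rhs_ub) if rows_ub else None

    bounds = []
    for rid in reactions:
        rxn = target.reactions[rid]
        lo = -FLUX_CAP if rxn.reversible else 0.0
        bounds.append((lo, FLUX_CAP))
    bounds += [(0.0, None)] * m
    pinned = pinned or {}
    for rid, val in pinned.items():
        bounds[reactions.index(rid)] = (val, val)

    res = scipy.optimize.linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq,
                                 b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        raise ModelError(f"no steady-state distribution on target network: "
                         f"{res.message}")
    v = res.x[:n]
    violation = float(res.x[n:].sum())
    fd = FluxDistribution(strain_id=source.strain_id, reactions=reactions,
                          v=v, basis_uptake=source.basis_uptake)
    return fd, violation
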