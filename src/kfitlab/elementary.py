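"""Elementary decomposition of enzymatic reactions and steady-state
evaluation of the resulting mass-action kinetic model.

Every enzyme-assigned reaction is rewritten as an ordered-sequential
mechanism: substrates bind one at a time in the declared binding order,
a conversion step interconverts the fully loaded complex (releasing the
first product), and the remaining products are released in the declared
release order.  A reversible uni-uni reaction therefore becomes
``E + A <=> EA <=> E + P`` (2 steps, 4 rate constants, 2 complexes).
Substrate-level inhibitions add dead-end inhibitor-binding steps:
competitive inhibitors bind free enzyme, uncompetitive inhibitors bind the
terminal substrate-loaded complex, noncompetitive inhibitors bind both.

The free parameters of the kinetic model are the wild-type fractional
abundances ``e`` of every enzyme complex (summing to 1 per enzyme) and
the reverse elementary flux ``v_r`` of every step at the wild-type steady
state.  With wild-type concentrations scaled to 1, each step's forward
flux is the reaction net flux plus ``v_r`` (inhibitor steps carry zero
net flux), which fixes both elementary rate constants — so the wild-type
state is an *exact* steady state by construction (anchoring).

Mutant steady states are found by an iterative decomposition: at fixed
metabolite concentrations each enzyme's complex-balance system is linear
and solved exactly; a damped Newton update (with an analytic Jacobian
obtained by implicit differentiation of those linear systems) then moves
the metabolite concentrations toward closure of the mass balances.  A
state is converged when every metabolite balance residual is below 1e-6
flux units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

from kfitlab.core import FluxDistribution, MetabolicModel, ModelError

__all__ = [
    "ElementaryStep", "ElementaryNetwork", "KineticParameterization",
    "SteadyState", "NonConvergentError", "UnstableError",
    "decompose", "anchor_wildtype", "steady_state", "stability_check",
    "ode_steady_state",
]

E_LOWER, E_UPPER = 1e-3, 1.0          # bounds on complex fractional abundance
VR_LOWER, VR_UPPER = 0.0, 1e4        # bounds on reverse elementary flux
K_UPPER = 1e6                        # bound on elementary rate constants
CONC_CAP = 1e9                       # divergence guard on concentrations
SS_TOL = 1e-6                        # steady-state residual threshold (flux units)


class NonConvergentError(RuntimeError):
    """Steady-state iteration did not converge within budget."""


class UnstableError(RuntimeError):
    """Concentrations diverged during steady-state evaluation."""


@dataclass
class ElementaryStep:
    index: int
    reaction_id: str
    kind: str  # binding | conversion | release | inhibitor_binding
    complex_in: int
    complex_out: int
    mets_in: tuple[str, ...]   # metabolites consumed (forward direction)
    mets_out: tuple[str, ...]  # metabolites produced (forward direction)

    @property
    def is_main_path(self) -> bool:
        return self.kind != "inhibitor_binding"


@dataclass
class ElementaryNetwork:
    """Elementary-step network grouped into per-reaction mechanisms."""

    model: MetabolicModel
    complexes: list[str]
    complex_mechanism: np.ndarray          # mechanism index per complex
    mechanisms: list[str]                  # reaction id per mechanism
    enzyme_of_mechanism: list[str]
    free_complex: dict[str, int]           # reaction id -> free-E complex index
    steps: list[ElementaryStep]
    conversion_step: dict[str, int]        # reaction id -> conversion step index
    kinetic_metabolites: list[str]         # species entering mass-action rates
    inhibitor_steps: dict[int, tuple[str, str, str]] = field(default_factory=dict)
    # step index -> (reaction, inhibitor metabolite, mode)

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def n_complexes(self) -> int:
        return len(self.complexes)

    @property
    def n_elementary_constants(self) -> int:
        """Rate constants on the main catalytic paths (2 per step)."""
        return 2 * sum(1 for s in self.steps if s.is_main_path)

    @property
    def n_inhibitor_constants(self) -> int:
        """Rate constants on inhibitor-binding steps (2 per step; a
        noncompetitive regulation contributes two steps)."""
        return 2 * sum(1 for s in self.steps if not s.is_main_path)

    def counts(self) -> dict[str, int]:
        return {
            "reactions": len(self.mechanisms),
            "complexes": self.n_complexes,
            "steps": self.n_steps,
            "elementary_constants": self.n_elementary_constants,
            "inhibitor_constants": self.n_inhibitor_constants,
        }


@dataclass
class KineticParameterization:
    """Wild-type anchoring variables and the derived rate constants."""

    net: ElementaryNetwork
    e: np.ndarray       # complex fractional abundance at wild type
    v_r: np.ndarray     # reverse elementary flux per step at wild type
    k_fwd: np.ndarray
    k_rev: np.ndarray
    wt_fluxes: dict[str, float]

    def to_json_dict(self) -> dict:
        return {
            "complexes": self.net.complexes,
            "e": self.e.tolist(),
            "steps": [
                {"reaction": s.reaction_id, "kind": s.kind,
                 "complex_in": self.net.complexes[s.complex_in],
                 "complex_out": self.net.complexes[s.complex_out]}
                for s in self.net.steps
            ],
            "v_r": self.v_r.tolist(),
            "k_fwd": self.k_fwd.tolist(),
            "k_rev": self.k_rev.tolist(),
            "wt_fluxes": self.wt_fluxes,
        }


@dataclass
class SteadyState:
    """Converged kinetic state on the wild-type-scaled basis."""

    reactions: list[str]
    v: np.ndarray                      # net flux per reaction
    metabolites: list[str]
    c: np.ndarray                      # concentrations (wild type == 1)
    x: np.ndarray                      # complex abundances
    max_dcdt: float
    converged: bool
    enzyme_levels: dict[str, float] = field(default_factory=dict)
    flagged_metabolites: list[str] = field(default_factory=list)
    stable: bool | None = None

    def flux(self, reaction_id: str) -> float:
        return float(self.v[self.reactions.index(reaction_id)])

    def conc(self, metabolite_id: str) -> float:
        return float(self.c[self.metabolites.index(metabolite_id)])

    def as_flux_dict(self) -> dict[str, float]:
        return dict(zip(self.reactions, self.v))

    def to_json_dict(self) -> dict:
        return {
            "reactions": self.reactions, "v": self.v.tolist(),
            "metabolites": self.metabolites, "c": self.c.tolist(),
            "max_dcdt": self.max_dcdt, "converged": self.converged,
            "stable": self.stable,
            "flagged_metabolites": self.flagged_metabolites,
        }


# ---------------------------------------------------------------------------
# decomposition

def _int_multiplicity(rxn, met) -> int:
    c = abs(rxn.stoichiometry[met])
    if c != int(c):
        raise ModelError(
            f"reaction {rxn.id}: non-integer coefficient for {met} cannot be "
            "decomposed into elementary steps"
        )
    return int(c)


def decompose(model: MetabolicModel,
              orders: dict[str, tuple[list[str], list[str]]] | None = None
              ) -> ElementaryNetwork:
    """Decompose every enzyme-assigned reaction into an ordered-sequential
    mechanism.  ``orders`` optionally overrides binding/release orders per
    reaction; otherwise the reaction's declared orders (or stoichiometry
    declaration order) are used."""
    orders = orders or {}
    complexes: list[str] = []
    complex_mech: list[int] = []
    mechanisms: list[str] = []
    enzyme_of_mechanism: list[str] = []
    free_complex: dict[str, int] = {}
    steps: list[ElementaryStep] = []
    conversion_step: dict[str, int] = {}
    inhibitor_steps: dict[int, tuple[str, str, str]] = {}

    regs_by_rxn: dict[str, list] = {}
    for reg in model.regulations:
        rxn = model.reactions[reg.reaction_id]
        if rxn.enzyme_id is None:
            raise ModelError(
                f"regulation on {reg.reaction_id} which has no enzyme"
            )
        regs_by_rxn.setdefault(reg.reaction_id, []).append(reg)

    for rxn in model.reactions.values():
        if rxn.enzyme_id is None:
            continue
        imech = len(mechanisms)
        mechanisms.append(rxn.id)
        enzyme_of_mechanism.append(rxn.enzyme_id)

        if rxn.id in orders:
            binding, release = orders[rxn.id]
        else:
            binding = rxn.binding_order or [
                m for m in rxn.substrates for _ in range(_int_multiplicity(rxn, m))
            ]
            release = rxn.release_order or [
                m for m in rxn.products for _ in range(_int_multiplicity(rxn, m))
            ]

        def add_complex(name: str) -> int:
            complexes.append(name)
            complex_mech.append(imech)
            return len(complexes) - 1

        free = add_complex(f"E_{rxn.id}")
        free_complex[rxn.id] = free

        def add_step(kind, cin, cout, mets_in=(), mets_out=()):
            steps.append(ElementaryStep(len(steps), rxn.id, kind, cin, cout,
                                        tuple(mets_in), tuple(mets_out)))
            return len(steps) - 1

        # substrate binding chain
        cur = free
        bound: list[str] = []
        for s in binding:
            bound.append(s)
            nxt = add_complex(f"E_{rxn.id}:" + ":".join(bound))
            add_step("binding", cur, nxt, mets_in=(s,))
            cur = nxt
        terminal = cur

        # conversion (releases the first product) + remaining releases
        if release:
            first, rest = release[0], release[1:]
            # chain_idx[j] = complex still holding the last j products
            chain_idx = [free]
            for j in range(1, len(rest) + 1):
                chain_idx.append(
                    add_complex(f"E_{rxn.id}*" + ":".join(release[len(release) - j:]))
                )
            # conversion: terminal -> most-loaded product complex (+ first product)
            conv_target = chain_idx[-1] if rest else free
            conversion_step[rxn.id] = add_step(
                "conversion", terminal, conv_target, mets_out=(first,))
            # releases walk back toward free E
            for j, p in enumerate(rest):
                cin = chain_idx[len(rest) - j]
                cout = chain_idx[len(rest) - j - 1]
                add_step("release", cin, cout, mets_out=(p,))
        else:  # pure drain (biomass sink): terminal complex reverts to free E
            conversion_step[rxn.id] = add_step("conversion", terminal, free)

        # inhibitor binding
        for reg in regs_by_rxn.get(rxn.id, []):
            inh = reg.inhibitor_metabolite_id
            if reg.mode in ("competitive", "noncompetitive"):
                cx = add_complex(f"E_{rxn.id}~{inh}")
                idx = add_step("inhibitor_binding", free, cx, mets_in=(inh,))
                inhibitor_steps[idx] = (rxn.id, inh, reg.mode)
            if reg.mode in ("uncompetitive", "noncompetitive"):
                cx = add_complex(f"{complexes[terminal]}~{inh}")
                idx = add_step("inhibitor_binding", terminal, cx, mets_in=(inh,))
                inhibitor_steps[idx] = (rxn.id, inh, reg.mode)

    kin_mets = sorted({m for s in steps for m in s.mets_in + s.mets_out})
    return ElementaryNetwork(
        model=model, complexes=complexes,
        complex_mechanism=np.array(complex_mech, dtype=int),
        mechanisms=mechanisms, enzyme_of_mechanism=enzyme_of_mechanism,
        free_complex=free_complex, steps=steps,
        conversion_step=conversion_step, kinetic_metabolites=kin_mets,
        inhibitor_steps=inhibitor_steps,
    )


# ---------------------------------------------------------------------------
# anchoring

def anchor_wildtype(
    net: ElementaryNetwork,
    wt: FluxDistribution | dict[str, float],
    e: np.ndarray,
    v_r: np.ndarray,
) -> KineticParameterization:
    """Solve rate constants so the wild-type state (all concentrations 1,
    complex abundances ``e``) is an exact steady state.

    Every main-path step carries the reaction's net flux; its forward flux
    is net + ``v_r``.  Inhibitor steps carry zero net flux.
    """
    wt_fluxes = wt.as_dict() if hasattr(wt, "as_dict") else dict(wt)
    e = np.asarray(e, float)
    v_r = np.asarray(v_r, float)
    if e.shape != (net.n_complexes,):
        raise ModelError("e has wrong length")
    if v_r.shape != (net.n_steps,):
        raise ModelError("v_r has wrong length")
    sums = np.zeros(len(net.mechanisms))
    np.add.at(sums, net.complex_mechanism, e)
    if np.max(np.abs(sums - 1.0)) > 1e-9:
        raise ModelError("complex fractions do not sum to 1 per enzyme")

    k_fwd = np.empty(net.n_steps)
    k_rev = np.empty(net.n_steps)
    for s in net.steps:
        v_net = wt_fluxes.get(s.reaction_id, 0.0) if s.is_main_path else 0.0
        v_fwd = v_net + v_r[s.index]
        if v_fwd <= 0:
            raise ModelError(
                f"step {s.index} of {s.reaction_id}: reverse flux "
                f"{v_r[s.index]} inconsistent with net flux {v_net} "
                "(forward flux would be non-positive)"
            )
        k_fwd[s.index] = v_fwd / e[s.complex_in]
        k_rev[s.index] = v_r[s.index] / e[s.complex_out]
    return KineticParameterization(net, e.copy(), v_r.copy(), k_fwd, k_rev,
                                   wt_fluxes)


# ---------------------------------------------------------------------------
# vectorized mass-action machine

class KineticMachine:
    """Precomputed index structure for fast steady-state evaluation.

    State layout: ``u = log c`` over ``kinetic_metabolites`` (boundary
    species held fixed), ``x`` over complexes.  Rates:
    ``rate_s = kf_s * x[in_s] * exp(Ein_s . u) - kr_s * x[out_s] * exp(Eout_s . u)``.
    """

    def __init__(self, net: ElementaryNetwork):
        self.net = net
        model = net.model
        self.mets = net.kinetic_metabolites
        self.nm = len(self.mets)
        met_idx = {m: i for i, m in enumerate(self.mets)}
        self.free_mask = np.array(
            [not model.metabolites[m].is_extracellular for m in self.mets]
        )
        self.free_idx = np.flatnonzero(self.free_mask)
        ns, nx = net.n_steps, net.n_complexes
        self.ns, self.nx = ns, nx
        self.in_cx = np.array([s.complex_in for s in net.steps], dtype=int)
        self.out_cx = np.array([s.complex_out for s in net.steps], dtype=int)
        self.Ein = np.zeros((ns, self.nm))
        self.Eout = np.zeros((ns, self.nm))
        self.N = np.zeros((self.nm, ns))  # met production stoich in rates
        for s in net.steps:
            for m in s.mets_in:
                self.Ein[s.index, met_idx[m]] += 1.0
                self.N[met_idx[m], s.index] -= 1.0
            for m in s.mets_out:
                self.Eout[s.index, met_idx[m]] += 1.0
                self.N[met_idx[m], s.index] += 1.0
        self.Nfree = self.N[self.free_idx]
        # complex incidence: +1 into out complex, -1 out of in complex
        self.C = np.zeros((nx, ns))
        for s in net.steps:
            self.C[s.complex_out, s.index] += 1.0
            self.C[s.complex_in, s.index] -= 1.0
        # conservation bookkeeping: replace the free-E row of each mechanism
        self.n_mech = len(net.mechanisms)
        self.cons_rows = np.array(
            [net.free_complex[r] for r in net.mechanisms], dtype=int)
        self.Crepl = self.C.copy()
        self.Crepl[self.cons_rows, :] = 0.0
        self.cons_mat = np.zeros((self.n_mech, nx))
        for i in range(nx):
            self.cons_mat[net.complex_mechanism[i], i] = 1.0
        self.conv_steps = np.array(
            [net.conversion_step[r] for r in net.mechanisms], dtype=int)

    # -- mechanism levels -------------------------------------------------
    def levels_vector(self, enzyme_levels: dict[str, float] | None) -> np.ndarray:
        enzyme_levels = enzyme_levels or {}
        out = np.ones(self.n_mech)
        for i, enz in enumerate(self.net.enzyme_of_mechanism):
            out[i] = enzyme_levels.get(enz, 1.0)
        if np.any(out < 0):
            raise ModelError("negative enzyme level")
        return out

    # -- core evaluations -------------------------------------------------
    def rate_factors(self, u: np.ndarray, kf, kr):
        pin = np.exp(self.Ein @ u)
        pout = np.exp(self.Eout @ u)
        return kf * pin, kr * pout  # pseudo-first-order a, b per step

    def solve_complexes(self, u: np.ndarray, kf, kr, levels: np.ndarray):
        """Exact linear solve of every mechanism's complex balances at
        fixed concentrations.  Returns (x, a, b, M_repl)."""
        a, b = self.rate_factors(u, kf, kr)
        nx = self.nx
        M = np.zeros((nx, nx))
        # balance rows: dx/dt = C @ rate, rate linear in x
        np.add.at(M, (self.out_cx, self.in_cx), a)
        np.add.at(M, (self.out_cx, self.out_cx), -b)
        np.add.at(M, (self.in_cx, self.in_cx), -a)
        np.add.at(M, (self.in_cx, self.out_cx), b)
        M[self.cons_rows, :] = self.cons_mat
        rhs = np.zeros(nx)
        rhs[self.cons_rows] = levels
        try:
            x = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError as exc:
            raise NonConvergentError("singular complex-balance system") from exc
        return x, a, b, M

    def rates(self, x, a, b):
        return a * x[self.in_cx] - b * x[self.out_cx]

    def met_residual(self, u, kf, kr, levels):
        x, a, b, M = self.solve_complexes(u, kf, kr, levels)
        r = self.rates(x, a, b)
        return self.Nfree @ r, x, a, b, M

    def drate_du(self, x, a, b):
        """d rate / d u at fixed x (ns x nm)."""
        return (a * x[self.in_cx])[:, None] * self.Ein \
            - (b * x[self.out_cx])[:, None] * self.Eout

    def drate_dx(self, a, b):
        """Sparse columns: returns (a, b) usage is via index arrays."""
        D = np.zeros((self.ns, self.nx))
        np.add.at(D, (np.arange(self.ns), self.in_cx), a)
        np.add.at(D, (np.arange(self.ns), self.out_cx), -b)
        return D

    def residual_jacobian(self, u, kf, kr, levels):
        """Analytic Jacobian of the free-metabolite residual w.r.t. the
        free components of u, via implicit differentiation of the
        complex-balance solves."""
        F, x, a, b, M = self.met_residual(u, kf, kr, levels)
        dr_du = self.drate_du(x, a, b)          # ns x nm
        dr_dx = self.drate_dx(a, b)             # ns x nx
        # complex balances: Crepl @ rate + conservation = 0
        rhs = -(self.Crepl @ dr_du)             # nx x nm
        dx_du = np.linalg.solve(M, rhs)
        J = self.Nfree @ (dr_du + dr_dx @ dx_du)
        return F, J[:, self.free_idx], x, a, b, M

    def reaction_fluxes(self, x, a, b):
        return self.rates(x, a, b)[self.conv_steps]

    # -- dynamic system (for stability and the ODE reference) -------------
    def dynamic_rhs(self, y, kf, kr):
        """y = [c_free, x]; returns [dc_free/dt, dx/dt]."""
        nfree = len(self.free_idx)
        c = np.ones(self.nm)
        c[self.free_idx] = y[:nfree]
        x = y[nfree:]
        logc = np.log(np.maximum(c, 1e-300))
        a, b = self.rate_factors(logc, kf, kr)
        r = self.rates(x, a, b)
        return np.concatenate([self.Nfree @ r, self.C @ r])

    def dynamic_jacobian(self, y, kf, kr):
        nfree = len(self.free_idx)
        c = np.ones(self.nm)
        c[self.free_idx] = y[:nfree]
        x = y[nfree:]
        logc = np.log(np.maximum(c, 1e-300))
        a, b = self.rate_factors(logc, kf, kr)
        dr_du = self.drate_du(x, a, b)
        dr_dc = dr_du[:, self.free_idx] / c[self.free_idx][None, :]
        dr_dx = self.drate_dx(a, b)
        top = np.hstack([self.Nfree @ dr_dc, self.Nfree @ dr_dx])
        bot = np.hstack([self.C @ dr_dc, self.C @ dr_dx])
        return np.vstack([top, bot])

    # -- algebraic system Jacobians (for sensitivities) --------------------
    def system_jacobian(self, u, x, a, b):
        """Jacobian of G(y) = [met residuals; complex balances with the
        free-E row of each mechanism replaced by conservation] w.r.t.
        y = [u_free, x]."""
        dr_du = self.drate_du(x, a, b)[:, self.free_idx]
        dr_dx = self.drate_dx(a, b)
        top = np.hstack([self.Nfree @ dr_du, self.Nfree @ dr_dx])
        bot = np.hstack([self.Crepl @ dr_du, self.Crepl @ dr_dx])
        bot[self.cons_rows - 0, :] = 0.0  # conservation rows
        nfree = len(self.free_idx)
        for im, row in enumerate(self.cons_rows):
            bot[row, nfree:] = self.cons_mat[im]
        return np.vstack([top, bot])

    def system_dG_dk(self, u, x):
        """dG/d[kf; kr] (ny x 2 ns)."""
        pin = np.exp(self.Ein @ u)
        pout = np.exp(self.Eout @ u)
        dr_dkf = x[self.in_cx] * pin      # diagonal, per step
        dr_dkr = -x[self.out_cx] * pout
        ny = len(self.free_idx) + self.nx
        out = np.zeros((ny, 2 * self.ns))
        top_f = self.Nfree * dr_dkf[None, :]
        top_r = self.Nfree * dr_dkr[None, :]
        bot_f = self.Crepl * dr_dkf[None, :]
        bot_r = self.Crepl * dr_dkr[None, :]
        out[: len(self.free_idx), : self.ns] = top_f
        out[: len(self.free_idx), self.ns:] = top_r
        out[len(self.free_idx):, : self.ns] = bot_f
        out[len(self.free_idx):, self.ns:] = bot_r
        return out

    def flux_sensitivities(self, u, x, a, b, kf, kr,
                           dkf_dtheta: np.ndarray, dkr_dtheta: np.ndarray
                           ) -> np.ndarray:
        """d(net reaction fluxes)/d(theta) at a converged steady state via
        the implicit function theorem.  ``dkf_dtheta``/``dkr_dtheta`` are
        (ns x ntheta)."""
        JG = self.system_jacobian(u, x, a, b)
        dG_dk = self.system_dG_dk(u, x)
        dk = np.vstack([dkf_dtheta, dkr_dtheta])       # 2ns x ntheta
        rhs = -(dG_dk @ dk)
        dy = np.linalg.solve(JG, rhs)                  # ny x ntheta
        nfree = len(self.free_idx)
        du_free = dy[:nfree]
        dx = dy[nfree:]
        conv = self.conv_steps
        # dv = d rate[conv] via u, x and k
        dr_du = self.drate_du(x, a, b)[conv][:, self.free_idx]
        dr_dx = self.drate_dx(a, b)[conv]
        pin = np.exp(self.Ein @ u)[conv]
        pout = np.exp(self.Eout @ u)[conv]
        dv = dr_du @ du_free + dr_dx @ dx
        dv += (x[self.in_cx][conv] * pin)[:, None] * dkf_dtheta[conv]
        dv -= (x[self.out_cx][conv] * pout)[:, None] * dkr_dtheta[conv]
        return dv


# ---------------------------------------------------------------------------
# steady-state solver

_MACHINES: dict[int, KineticMachine] = {}


def machine_for(net: ElementaryNetwork) -> KineticMachine:
    key = id(net)
    if key not in _MACHINES:
        _MACHINES[key] = KineticMachine(net)
    return _MACHINES[key]


def steady_state(
    net: ElementaryNetwork,
    params: KineticParameterization,
    enzyme_levels: dict[str, float] | None = None,
    init: np.ndarray | None = None,
    max_iter: int = 10_000,
    tol: float = SS_TOL,
    flag_threshold: float = 1e4,
) -> SteadyState:
    """Evaluate the steady state for given relative enzyme levels.

    Raises :class:`NonConvergentError` or :class:`UnstableError` when no
    state with every metabolite balance below ``tol`` is reached — both
    signal that the parameter set (or start) should be discarded.
    """
    mach = machine_for(net)
    kf, kr = params.k_fwd, params.k_rev
    levels = mach.levels_vector(enzyme_levels)

    u = np.zeros(mach.nm)
    if init is not None:
        u[mach.free_idx] = np.log(np.clip(init, 1e-300, CONC_CAP))

    F, J, x, a, b, M = mach.residual_jacobian(u, kf, kr, levels)
    fnorm = np.max(np.abs(F))
    for _ in range(max_iter):
        if fnorm < tol:
            break
        try:
            du = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            du = np.linalg.lstsq(J, -F, rcond=None)[0]
        step_cap = 5.0  # limit log-concentration moves per iteration
        scale = min(1.0, step_cap / max(np.max(np.abs(du)), 1e-300))
        du = du * scale
        damp = 1.0
        improved = False
        for _halve in range(40):
            u_try = u.copy()
            u_try[mach.free_idx] += damp * du
            if np.max(u_try) > np.log(CONC_CAP):
                raise UnstableError("concentration diverged beyond cap")
            try:
                F_t, J_t, x_t, a_t, b_t, M_t = mach.residual_jacobian(
                    u_try, kf, kr, levels)
            except (NonConvergentError, FloatingPointError):
                damp *= 0.5
                continue
            f_t = np.max(np.abs(F_t))
            if np.isfinite(f_t) and f_t < fnorm:
                u, F, J, x, a, b = u_try, F_t, J_t, x_t, a_t, b_t
                fnorm = f_t
                improved = True
                break
            damp *= 0.5
        if not improved:
            raise NonConvergentError(
                f"damped Newton stalled at residual {fnorm:.3g}")
    else:
        raise NonConvergentError(
            f"no steady state within {max_iter} iterations "
            f"(residual {fnorm:.3g})")

    c_full = np.exp(u)
    v = mach.reaction_fluxes(x, a, b)
    v_by_rxn = dict(zip(net.mechanisms, v))
    reactions = list(net.model.reactions)
    v_all = np.array([v_by_rxn.get(r, 0.0) for r in reactions])
    flagged = [m for i, (m, ci) in enumerate(zip(mach.mets, c_full))
               if mach.free_mask[i] and ci > flag_threshold]
    return SteadyState(
        reactions=reactions, v=v_all,
        metabolites=list(mach.mets), c=c_full, x=x,
        max_dcdt=float(fnorm), converged=True,
        enzyme_levels=dict(enzyme_levels or {}),
        flagged_metabolites=flagged,
    )


def stability_check(
    net: ElementaryNetwork,
    params: KineticParameterization,
    state: SteadyState,
    tol: float = 1e-9,
) -> tuple[bool, float]:
    """Local stability of a converged state: all eigenvalues of the
    linearized dynamics restricted to the non-conserved subspace must
    have real part below ``tol``.  Returns (stable, leading real part)."""
    mach = machine_for(net)
    nfree = len(mach.free_idx)
    y = np.concatenate([state.c[mach.free_idx], state.x])
    J = mach.dynamic_jacobian(y, params.k_fwd, params.k_rev)
    # conservation left-null vectors: per-mechanism sums over x coordinates
    C = np.zeros((mach.n_mech, nfree + mach.nx))
    C[:, nfree:] = mach.cons_mat
    Q = null_space(C)
    Jr = Q.T @ J @ Q
    eig = np.linalg.eigvals(Jr)
    lead = float(np.max(eig.real)) if len(eig) else -np.inf
    state.stable = bool(lead < tol)
    return state.stable, lead


def ode_steady_state(
    net: ElementaryNetwork,
    params: KineticParameterization,
    enzyme_levels: dict[str, float] | None = None,
    t_end: float = 1e6,
    init: SteadyState | None = None,
    tol: float = 1e-8,
    max_chunks: int = 40,
) -> SteadyState:
    """Reference steady state by long-time stiff ODE integration of the
    full mass-action system (independent of the Newton decomposition).

    Integration starts from unit concentrations with complexes
    pre-equilibrated at that state (the same point the Newton iteration
    starts from) and continues in chunks of ``t_end`` until the largest
    balance residual drops below ``tol``.
    """
    mach = machine_for(net)
    kf, kr = params.k_fwd, params.k_rev
    levels = mach.levels_vector(enzyme_levels)
    nfree = len(mach.free_idx)
    if init is not None:
        c0 = init.c[mach.free_idx]
        x0 = init.x.copy()
    else:
        c0 = np.ones(nfree)
        x0, _, _, _ = mach.solve_complexes(np.zeros(mach.nm), kf, kr, levels)
    y0 = np.concatenate([c0, x0])

    def rhs(_t, y):
        return mach.dynamic_rhs(np.maximum(y, 0.0), kf, kr)

    def jac(_t, y):
        return mach.dynamic_jacobian(np.maximum(y, 1e-300), kf, kr)

    y = y0
    for _chunk in range(max_chunks):
        sol = solve_ivp(rhs, (0.0, t_end), y, method="BDF", jac=jac,
                        rtol=1e-8, atol=1e-11)
        if not sol.success:
            raise NonConvergentError(f"ODE integration failed: {sol.message}")
        y = sol.y[:, -1]
        if np.max(np.abs(mach.dynamic_rhs(np.maximum(y, 0.0), kf, kr))) < tol:
            break
    else:
        raise NonConvergentError(
            f"ODE integration did not reach steady state within "
            f"{max_chunks} chunks of t={t_end}")
    c = np.ones(mach.nm)
    c[mach.free_idx] = y[:nfree]
    x = y[nfree:]
    logc = np.log(np.maximum(c, 1e-300))
    a, b = mach.rate_factors(logc, kf, kr)
    r = mach.rates(x, a, b)
    F = mach.Nfree @ r
    v = mach.reaction_fluxes(x, a, b)
    v_by_rxn = dict(zip(net.mechanisms, v))
    reactions = list(net.model.reactions)
    return SteadyState(
        reactions=reactions,
        v=np.array([v_by_rxn.get(rid, 0.0) for rid in reactions]),
        metabolites=list(mach.mets), c=c, x=x,
        max_dcdt=float(np.max(np.abs(F))), converged=True,
        enzyme_levels=dict(enzyme_levels or {}),
    )
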