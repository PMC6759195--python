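"""Brute-force full-isotopomer labeling simulation.

Reference simulator used to validate the EMU route: the complete
2**n-dimensional positional-isotopomer state of every internal carbon
metabolite is integrated to steady state (stiff ODE, unit pool sizes),
then polished by fixed-point iteration of the steady-state balances.
Exponential in metabolite carbon count — only viable for toy networks
(<= ~6 carbons per metabolite), which is exactly its role.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from kfitlab.core import MetabolicModel, ModelError
from kfitlab.emu import MIDSet, TracerSpec, directional_fluxes, _direction_maps


def _tracer_isotopomers(n: int, spec) -> np.ndarray:
    x = np.zeros(2**n)
    for frac, labeled in spec:
        idx = sum(1 << (p - 1) for p in labeled)
        x[idx] += frac
    return x


def isotopomer_mids(
    model: MetabolicModel,
    fluxes: dict[str, float],
    tracer: TracerSpec,
    fragments: list[tuple[str, tuple[int, ...]]],
    exchange: dict[str, float] | None = None,
    t_end: float = 1e5,
    polish_iters: int = 200000,
    polish_tol: float = 1e-14,
) -> MIDSet:
    """Simulate fragment MIDs by full isotopomer enumeration."""
    if hasattr(fluxes, "as_dict"):
        fluxes = fluxes.as_dict()
    dflux = directional_fluxes(model, fluxes, exchange)

    carbons = {m.id: m.carbon_count for m in model.metabolites.values()}
    internal = [
        m.id
        for m in model.metabolites.values()
        if not m.is_extracellular and m.carbon_count > 0
    ]
    offsets: dict[str, int] = {}
    total = 0
    for mid_ in internal:
        offsets[mid_] = total
        total += 2 ** carbons[mid_]

    fixed: dict[str, np.ndarray] = {}
    for m in model.metabolites.values():
        if m.is_extracellular and m.carbon_count > 0:
            if m.id in tracer:
                fixed[m.id] = _tracer_isotopomers(m.carbon_count, tracer[m.id])

    # (flux, substrate occurrences, product occurrences) with atom strings
    routes = []
    for rid, d, variants in _direction_maps(model):
        f = dflux.get((rid, d), 0.0)
        if f == 0.0:
            continue
        for w, subs, prods in variants:
            routes.append((f * w, subs, prods))

    consumption = np.zeros(total)
    for f, subs, _ in routes:
        for smet, _s in subs:
            if smet in offsets:
                n = carbons[smet]
                consumption[offsets[smet]: offsets[smet] + 2**n] += f

    def met_state(y: np.ndarray, met: str) -> np.ndarray:
        if met in fixed:
            return fixed[met]
        n = carbons[met]
        return y[offsets[met]: offsets[met] + 2**n]

    def production(y: np.ndarray) -> np.ndarray:
        """Total isotopomer production rate of every internal metabolite."""
        prod = np.zeros(total)
        for f, subs, prods in routes:
            # joint distribution over all substrate atom letters
            # dict letter-pattern -> probability, built substrate by substrate
            joint: dict[frozenset, float] = {frozenset(): 1.0}
            for smet, sstr in subs:
                x = met_state(y, smet)
                n = carbons[smet]
                new: dict[frozenset, float] = {}
                for idx in range(2**n):
                    p = x[idx]
                    if p == 0.0:
                        continue
                    letters = frozenset(
                        sstr[j] for j in range(n) if idx >> j & 1
                    )
                    for pat, q in joint.items():
                        new_pat = pat | letters
                        new[new_pat] = new.get(new_pat, 0.0) + p * q
                joint = new
            for pmet, pstr in prods:
                if pmet not in offsets:
                    continue
                n = carbons[pmet]
                base = offsets[pmet]
                for pat, q in joint.items():
                    if q == 0.0:
                        continue
                    idx = 0
                    for j in range(n):
                        if pstr[j] in pat:
                            idx |= 1 << j
                    prod[base + idx] += f * q
        return prod

    def rhs(_t, y):
        return production(y) - consumption * y

    # unlabeled start
    y0 = np.zeros(total)
    for met in internal:
        y0[offsets[met]] = 1.0

    sol = solve_ivp(rhs, (0.0, t_end), y0, method="BDF", rtol=1e-9, atol=1e-12)
    if not sol.success:
        raise ModelError(f"isotopomer ODE integration failed: {sol.message}")
    y = sol.y[:, -1]

    # fixed-point polish of the steady-state balances
    safe_cons = np.where(consumption > 0, consumption, 1.0)
    for _ in range(polish_iters):
        y_new = production(y) / safe_cons
        y_new[consumption == 0] = y[consumption == 0]
        if np.max(np.abs(y_new - y)) < polish_tol:
            y = y_new
            break
        y = y_new

    out = {}
    for met, atoms in fragments:
        atoms = tuple(sorted(atoms))
        n = carbons[met]
        x = fixed[met] if met in fixed else y[offsets[met]: offsets[met] + 2**n]
        mid = np.zeros(len(atoms) + 1)
        for idx in range(2**n):
            k = sum(1 for a in atoms if idx >> (a - 1) & 1)
            mid[k] += x[idx]
        s = mid.sum()
        if s <= 0:
            raise ModelError(f"empty isotopomer pool for fragment {met}{atoms}")
        out[(met, atoms)] = mid / s
    return MIDSet("isotopomer-reference", out)
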