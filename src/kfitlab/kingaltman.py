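"""King-Altman derivation of steady-state rate laws from elementary steps.

The steady-state fraction of each enzyme complex is proportional to the
sum, over all spanning trees of the complex graph, of the product of the
rate constants along the tree's edges directed toward that complex
(pseudo-first-order constants: binding edges carry their metabolite
concentration).  The net reaction rate follows from the conversion step,
giving a rate law of Michaelis-Menten form whose denominator is a
polynomial in the concentrations.  Following the convention used for
elementary-decomposition models, *each distinct denominator term* (after
normalizing the coefficient of the full substrate monomial to 1) is
reported as one Km parameter, and the forward Vmax comes from the
numerator with total enzyme.  Inhibitor complexes participate as
spanning-tree nodes, so dead-end inhibitions appear as additional
denominator terms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import sympy as sp

from kfitlab.core import ModelError
from kfitlab.elementary import ElementaryNetwork

__all__ = ["MMParameter", "MMRateLaw", "king_altman"]


@dataclass
class MMParameter:
    reaction_id: str
    kind: str                     # "Km_term" | "Vmax"
    monomial: str                 # concentration monomial the term multiplies
    expression: sp.Expr           # in elementary rate constants
    value: float | None = None
    range: tuple[float, float] | None = None
    units: str = ""

    def __post_init__(self):
        if self.value is not None and self.value <= 0:
            raise ModelError(
                f"{self.kind} for {self.reaction_id} must be positive, "
                f"got {self.value}")


@dataclass
class MMRateLaw:
    reaction_id: str
    rate: sp.Expr                  # net rate as function of concentrations
    numerator: sp.Expr
    denominator: sp.Expr
    substrates: list[str]
    products: list[str]
    km_terms: list[MMParameter]
    vmax: MMParameter
    complex_numerators: dict[str, sp.Expr]
    conc_symbols: dict[str, sp.Symbol]
    k_symbols: tuple[dict[int, sp.Symbol], dict[int, sp.Symbol]]

    def evaluate(self, concentrations: dict[str, float],
                 k_fwd: np.ndarray, k_rev: np.ndarray,
                 enzyme_total: float = 1.0) -> float:
        """Numeric net rate at given concentrations and rate constants."""
        subs = {sym: concentrations.get(met, 1.0)
                for met, sym in self.conc_symbols.items()}
        kf_syms, kr_syms = self.k_symbols
        for idx, sym in kf_syms.items():
            subs[sym] = k_fwd[idx]
        for idx, sym in kr_syms.items():
            subs[sym] = k_rev[idx]
        return float(self.rate.subs(subs)) * enzyme_total


def _spanning_trees(nodes: list[int], edges: list[tuple[int, int, int]]):
    """Yield spanning trees as tuples of edge indices (edges carry
    (u, v, step_index); parallel edges are distinct)."""
    n = len(nodes)
    for combo in itertools.combinations(range(len(edges)), n - 1):
        parent = {v: v for v in nodes}

        def find(v):
            while parent[v] != v:
                parent[v] = parent[parent[v]]
                v = parent[v]
            return v

        ok = True
        for ei in combo:
            u, v, _ = edges[ei]
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if ok:
            yield combo


def king_altman(
    net: ElementaryNetwork,
    reaction_id: str,
    k_fwd: np.ndarray | None = None,
    k_rev: np.ndarray | None = None,
    enzyme_total: float = 1.0,
) -> MMRateLaw:
    """Derive the Michaelis-Menten-form rate law of one mechanism.

    When numeric ``k_fwd``/``k_rev`` are given, every emitted parameter
    also carries its numeric value (concentration factors evaluated at 1).
    """
    if reaction_id not in net.mechanisms:
        raise ModelError(f"no mechanism for reaction {reaction_id!r}")
    imech = net.mechanisms.index(reaction_id)
    cx_global = [i for i in range(net.n_complexes)
                 if net.complex_mechanism[i] == imech]
    steps = [s for s in net.steps if s.reaction_id == reaction_id]
    if not steps:
        raise ModelError(f"mechanism of {reaction_id} has no steps")

    conc_syms: dict[str, sp.Symbol] = {}

    def csym(met: str) -> sp.Symbol:
        if met not in conc_syms:
            conc_syms[met] = sp.Symbol(f"c_{met}", positive=True)
        return conc_syms[met]

    kf_syms = {s.index: sp.Symbol(f"kf{s.index}", positive=True) for s in steps}
    kr_syms = {s.index: sp.Symbol(f"kr{s.index}", positive=True) for s in steps}

    def fwd_weight(s):
        w = kf_syms[s.index]
        for m in s.mets_in:
            w *= csym(m)
        return w

    def rev_weight(s):
        w = kr_syms[s.index]
        for m in s.mets_out:
            w *= csym(m)
        return w

    edges = [(s.complex_in, s.complex_out, s.index) for s in steps]
    # connectivity check
    reach = {cx_global[0]}
    frontier = [cx_global[0]]
    adj: dict[int, set[int]] = {c: set() for c in cx_global}
    for u, v, _ in edges:
        adj[u].add(v)
        adj[v].add(u)
    while frontier:
        u = frontier.pop()
        for v in adj[u]:
            if v not in reach:
                reach.add(v)
                frontier.append(v)
    if reach != set(cx_global):
        raise ModelError(f"complex graph of {reaction_id} is disconnected")

    steps_by_index = {s.index: s for s in steps}
    numerators = {c: sp.Integer(0) for c in cx_global}
    for tree in _spanning_trees(cx_global, edges):
        tree_adj: dict[int, list[tuple[int, int]]] = {c: [] for c in cx_global}
        for ei in tree:
            u, v, si = edges[ei]
            tree_adj[u].append((v, si))
            tree_adj[v].append((u, si))
        for root in cx_global:
            # orient edges toward root (BFS parents)
            term = sp.Integer(1)
            seen = {root}
            queue = [root]
            while queue:
                node = queue.pop()
                for nbr, si in tree_adj[node]:
                    if nbr in seen:
                        continue
                    seen.add(nbr)
                    queue.append(nbr)
                    s = steps_by_index[si]
                    # edge nbr -> node
                    if s.complex_in == nbr and s.complex_out == node:
                        term *= fwd_weight(s)
                    else:
                        term *= rev_weight(s)
            numerators[root] += term

    denominator = sp.expand(sum(numerators.values()))
    conv = steps_by_index[net.conversion_step[reaction_id]]
    rate_num = sp.expand(
        fwd_weight(conv) * numerators[conv.complex_in]
        - rev_weight(conv) * numerators[conv.complex_out]
    )
    rate = rate_num / denominator

    # normalize: coefficient of the full forward-substrate monomial -> 1
    substrates = [m for s in steps if s.is_main_path for m in s.mets_in]
    products = [m for s in steps if s.is_main_path for m in s.mets_out]
    full_monomial = sp.Integer(1)
    for m in substrates:
        full_monomial *= csym(m)
    syms = list(conc_syms.values())
    if syms:
        poly = sp.Poly(denominator, *syms)
        target = tuple(
            sum(1 for m in substrates if conc_syms[m] == s) for s in syms
        )
        c_full = poly.coeff_monomial(
            sp.prod([s**e for s, e in zip(syms, target)]) if syms else 1)
    else:
        poly = None
        c_full = denominator
    if c_full == 0:
        raise ModelError(
            f"{reaction_id}: denominator lacks the full substrate monomial")

    def numeric(expr: sp.Expr) -> float | None:
        if k_fwd is None or k_rev is None:
            return None
        subs = {}
        for idx, sym in kf_syms.items():
            subs[sym] = float(k_fwd[idx])
        for idx, sym in kr_syms.items():
            subs[sym] = float(k_rev[idx])
        val = expr.subs(subs)
        return float(val)

    km_terms: list[MMParameter] = []
    if poly is not None:
        for mono, coeff in zip(poly.monoms(), poly.coeffs()):
            if mono == target:
                continue  # the normalized substrate term itself
            mono_expr = sp.prod([s**e for s, e in zip(syms, mono)])
            expr = sp.simplify(coeff / c_full)
            km_terms.append(MMParameter(
                reaction_id=reaction_id, kind="Km_term",
                monomial=str(mono_expr), expression=expr,
                value=numeric(expr),
                units="concentration^%d" % (sum(target) - sum(mono)),
            ))
    # forward Vmax: coefficient of the full substrate monomial in the
    # forward part of the numerator, scaled by total enzyme
    num_poly = sp.Poly(rate_num, *syms) if syms else None
    if num_poly is not None:
        n_full = num_poly.coeff_monomial(
            sp.prod([s**e for s, e in zip(syms, target)]))
    else:
        n_full = rate_num
    vmax_expr = sp.simplify(n_full / c_full)
    vmax_val = numeric(vmax_expr)
    vmax = MMParameter(
        reaction_id=reaction_id, kind="Vmax", monomial="1",
        expression=vmax_expr * sp.Symbol("E_t", positive=True),
        value=None if vmax_val is None else vmax_val * enzyme_total,
        units="flux",
    )
    return MMRateLaw(
        reaction_id=reaction_id, rate=rate, numerator=rate_num,
        denominator=denominator, substrates=substrates, products=products,
        km_terms=km_terms, vmax=vmax,
        complex_numerators={
            net.complexes[c]: numerators[c] for c in cx_global},
        conc_symbols=conc_syms, k_symbols=(kf_syms, kr_syms),
    )
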