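"""Elementary metabolite unit (EMU) decomposition and MID simulation.

An EMU is a subset of the carbon atoms of a metabolite.  Isotope
propagation through the network decomposes into cascaded *linear* balance
systems ordered by EMU size: the mass isotopomer distribution (MID) of
every EMU of size *n* is determined by fluxes and by MIDs of EMUs of size
< *n* (convolutions at condensation reactions) plus same-size EMUs.

Reversible reactions are treated as two directional fluxes
``fwd = max(v, 0) + exch`` and ``rev = max(-v, 0) + exch`` where ``v`` is
the net flux and ``exch`` the exchange flux.  MIDs are invariant under a
global rescaling of all fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from kfitlab.core import MetabolicModel, ModelError

__all__ = ["EMU", "EMUNetwork", "MIDSet", "build_emu_network", "simulate_mids",
           "TracerSpec"]


@dataclass(frozen=True)
class EMU:
    metabolite_id: str
    atoms: frozenset[int]

    def __post_init__(self):
        if not self.atoms:
            raise ModelError(f"empty EMU for {self.metabolite_id}")

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"{self.metabolite_id}[{','.join(map(str, sorted(self.atoms)))}]"

    def key(self) -> tuple[str, tuple[int, ...]]:
        return (self.metabolite_id, tuple(sorted(self.atoms)))


#: labeling spec for one substrate: list of (fraction, labeled positions)
TracerSpec = dict[str, list[tuple[float, frozenset[int]]]]


@dataclass
class Production:
    """One flux route forming a target EMU: ``flux_ref`` identifies the
    directional reaction, ``weight`` the atom-map variant weight, and
    ``sources`` the substrate EMUs (len > 1 denotes a convolution)."""

    flux_ref: tuple[str, int]  # (reaction id, +1 forward / -1 reverse)
    weight: float
    sources: tuple[EMU, ...]


@dataclass
class EMUNetwork:
    model: MetabolicModel
    fragments: list[EMU]
    productions: dict[EMU, list[Production]]
    source_emus: set[EMU]
    blocks: list[list[EMU]]
    consumption_refs: dict[str, list[tuple[tuple[str, int], float]]]

    @property
    def n_emus(self) -> int:
        return len(self.productions) + len(self.source_emus)

    def block_sizes(self) -> list[tuple[int, int]]:
        """(EMU size, number of EMUs) per balance block."""
        return [(b[0].size, len(b)) for b in self.blocks]


def _direction_maps(model: MetabolicModel):
    """Yield (reaction id, direction, variants) with variants given as
    (weight, substrate occurrences, product occurrences) in that direction."""
    for rxn in model.reactions.values():
        if rxn.atom_map is None:
            continue
        yield rxn.id, +1, rxn.atom_map
        if rxn.reversible:
            yield rxn.id, -1, [(w, p, s) for (w, s, p) in rxn.atom_map]


def build_emu_network(
    model: MetabolicModel, fragments: list[tuple[str, tuple[int, ...]]]
) -> EMUNetwork:
    """Decompose the network into the minimal EMU set needed to simulate
    the requested fragments, topologically blocked by EMU size."""
    frag_emus = []
    for met, atoms in fragments:
        if met not in model.metabolites:
            raise ModelError(f"fragment references unknown metabolite {met!r}")
        n = model.metabolites[met].carbon_count
        atoms = frozenset(atoms)
        if any(a < 1 or a > n for a in atoms):
            raise ModelError(f"fragment {met}{sorted(atoms)} exceeds carbon count {n}")
        frag_emus.append(EMU(met, atoms))

    dir_maps = list(_direction_maps(model))
    producers: dict[str, list] = {}
    for rid, d, variants in dir_maps:
        for w, subs, prods in variants:
            for met, s in prods:
                producers.setdefault(met, []).append((rid, d, w, subs, s))

    productions: dict[EMU, list[Production]] = {}
    source_emus: set[EMU] = set()
    stack = list(frag_emus)
    while stack:
        emu = stack.pop()
        if emu in productions or emu in source_emus:
            continue
        met = model.metabolites[emu.metabolite_id]
        if met.is_extracellular:
            source_emus.add(emu)
            continue
        prods: list[Production] = []
        for rid, d, w, subs, s_target in producers.get(emu.metabolite_id, []):
            letters = {s_target[i - 1] for i in emu.atoms}
            sources = []
            for smet, sstr in subs:
                pos = frozenset(
                    j + 1 for j, ch in enumerate(sstr) if ch in letters
                )
                if pos:
                    sources.append(EMU(smet, pos))
            sources.sort(key=EMU.key)
            prods.append(Production((rid, d), w, tuple(sources)))
            stack.extend(sources)
        if not prods:
            # unbalanced leaf (no producing reaction): treat as source so a
            # tracer spec may still define it, else simulation will fail
            source_emus.add(emu)
            continue
        productions[emu] = prods

    # consumption bookkeeping per metabolite (substrate-side occurrences)
    consumption_refs: dict[str, list[tuple[tuple[str, int], float]]] = {}
    for rid, d, variants in dir_maps:
        w0, subs0, _ = variants[0]
        counts: dict[str, int] = {}
        for smet, _ in subs0:
            counts[smet] = counts.get(smet, 0) + 1
        for smet, cnt in counts.items():
            consumption_refs.setdefault(smet, []).append(((rid, d), float(cnt)))

    by_size: dict[int, list[EMU]] = {}
    for emu in productions:
        by_size.setdefault(emu.size, []).append(emu)
    blocks = [sorted(by_size[k], key=EMU.key) for k in sorted(by_size)]
    return EMUNetwork(model, frag_emus, productions, source_emus, blocks,
                      consumption_refs)


# ---------------------------------------------------------------------------
# MID containers

@dataclass
class MIDSet:
    """Mass isotopomer distributions keyed by ``(metabolite, atom tuple)``."""

    strain_id: str
    mids: dict[tuple[str, tuple[int, ...]], np.ndarray]
    sds: dict[tuple[str, tuple[int, ...]], np.ndarray] | None = None

    def __getitem__(self, key) -> np.ndarray:
        if isinstance(key, EMU):
            key = key.key()
        return self.mids[key]

    def validate(self, tol: float = 1e-9) -> None:
        for key, mid in self.mids.items():
            if np.any(mid < -tol) or abs(mid.sum() - 1.0) > tol:
                raise ModelError(f"MID for {key} is not a distribution: {mid}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (met, atoms), mid in self.mids.items():
            frag = f"{met}[{','.join(map(str, atoms))}]"
            sd = None if self.sds is None else self.sds.get((met, atoms))
            for shift, value in enumerate(mid):
                rows.append(
                    {
                        "strain": self.strain_id,
                        "fragment": frag,
                        "mass_shift": shift,
                        "value": value,
                        "sd": np.nan if sd is None else sd[shift],
                    }
                )
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, strain_id: str | None = None) -> "MIDSet":
        if strain_id is not None and "strain" in df:
            df = df[df["strain"] == strain_id]
        mids: dict = {}
        sds: dict = {}
        for frag, grp in df.groupby("fragment", sort=False):
            met, rest = frag.split("[", 1)
            atoms = tuple(int(a) for a in rest.rstrip("]").split(","))
            grp = grp.sort_values("mass_shift")
            mids[(met, atoms)] = grp["value"].to_numpy(dtype=float)
            if "sd" in grp and not grp["sd"].isna().all():
                sds[(met, atoms)] = grp["sd"].to_numpy(dtype=float)
        return cls(strain_id or "", mids, sds or None)

    @classmethod
    def read(cls, path: str | Path, strain_id: str | None = None) -> "MIDSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"), strain_id)


# ---------------------------------------------------------------------------
# simulation

def directional_fluxes(
    model: MetabolicModel,
    net: dict[str, float],
    exchange: dict[str, float] | None = None,
) -> dict[tuple[str, int], float]:
    """Split net fluxes into non-negative directional fluxes."""
    exchange = exchange or {}
    out: dict[tuple[str, int], float] = {}
    for rid, rxn in model.reactions.items():
        v = float(net.get(rid, 0.0))
        ex = float(exchange.get(rid, 0.0))
        if not rxn.reversible:
            if v < -1e-9:
                raise ModelError(f"negative flux {v} through irreversible {rid}")
            out[(rid, +1)] = max(v, 0.0)
        else:
            out[(rid, +1)] = max(v, 0.0) + ex
            out[(rid, -1)] = max(-v, 0.0) + ex
    return out


def tracer_mid(emu: EMU, tracer: TracerSpec) -> np.ndarray:
    spec = tracer.get(emu.metabolite_id)
    if spec is None:
        raise ModelError(f"no tracer labeling given for source EMU {emu!r}")
    mid = np.zeros(emu.size + 1)
    for frac, labeled in spec:
        mid[len(emu.atoms & labeled)] += frac
    if abs(mid.sum() - 1.0) > 1e-9:
        raise ModelError(f"tracer fractions for {emu.metabolite_id} do not sum to 1")
    return mid


def simulate_mids(
    net: EMUNetwork,
    fluxes: dict[str, float] | "np.ndarray | object",
    tracer: TracerSpec,
    exchange: dict[str, float] | None = None,
) -> MIDSet:
    """Simulate the MIDs of the network's fragments for one flux state.

    ``fluxes`` maps reaction ids to net fluxes (a
    :class:`~kfitlab.core.FluxDistribution` is accepted too).
    """
    if hasattr(fluxes, "as_dict"):
        fluxes = fluxes.as_dict()
    dflux = directional_fluxes(net.model, fluxes, exchange)

    consumption: dict[str, float] = {}
    for met, refs in net.consumption_refs.items():
        consumption[met] = sum(dflux.get(ref, 0.0) * cnt for ref, cnt in refs)

    known: dict[EMU, np.ndarray] = {}
    dead: set[EMU] = set()
    for emu in net.source_emus:
        known[emu] = tracer_mid(emu, tracer)

    for block in net.blocks:
        size = block[0].size
        index = {emu: i for i, emu in enumerate(block)}
        nb = len(block)
        A = np.zeros((nb, nb))
        B = np.zeros((nb, size + 1))
        for emu, i in index.items():
            cons = consumption.get(emu.metabolite_id, 0.0)
            A[i, i] = cons
            inflow = 0.0
            for prod in net.productions[emu]:
                f = dflux.get(prod.flux_ref, 0.0) * prod.weight
                if f == 0.0 or any(s in dead for s in prod.sources):
                    continue
                inflow += f
                if len(prod.sources) == 1 and prod.sources[0] in index:
                    A[i, index[prod.sources[0]]] -= f
                else:
                    mid = known[prod.sources[0]]
                    for src in prod.sources[1:]:
                        mid = np.convolve(mid, known[src])
                    B[i, :] += f * mid
            if A[i, i] <= 1e-9 * max(inflow, 1.0):
                if inflow <= 1e-9:
                    # metabolite carries no flux at this state (dead branch
                    # behind a knockout): its labeling is undefined but also
                    # unused — mark it and keep a placeholder
                    dead.add(emu)
                    A[i, :] = 0.0
                    A[i, i] = 1.0
                    B[i, :] = 0.0
                    B[i, 0] = 1.0
                else:
                    raise ModelError(
                        f"singular EMU balance: no flux consumes {emu!r}"
                    )
        try:
            X = np.linalg.solve(A, B)
        except np.linalg.LinAlgError as exc:
            raise ModelError(f"singular EMU balance in size-{size} block") from exc
        for emu, i in index.items():
            mid = X[i]
            known[emu] = mid

    out = {}
    for emu in net.fragments:
        if emu in dead:
            raise ModelError(
                f"fragment {emu!r} carries no flux at this state "
                "(dead branch); no MID is defined for it"
            )
        mid = known[emu]
        s = mid.sum()
        if not np.isfinite(s) or abs(s - 1.0) > 1e-6:
            raise ModelError(f"simulated MID for {emu!r} does not sum to 1: {mid}")
        out[emu.key()] = mid / s
    return MIDSet("simulated", out)
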