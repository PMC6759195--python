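"""Metabolic model data structures, TSV workbook IO, validation and reduction.

A model workbook is a directory of plain TSV sheets mirroring the structure
of curated core-metabolism models used for 13C-MFA:

``metabolites.tsv``
    columns ``id``, ``carbon_count``, ``extracellular`` (0/1),
    ``biomass_precursor`` (0/1).
``reactions.tsv``
    columns ``id``, ``equation`` (e.g. ``A + 2 B --> C``; ``<=>`` marks a
    reversible reaction), ``enzyme`` (blank = no kinetic mechanism),
    ``role`` (``uptake``, ``sink`` or blank), ``excluded_from_fit`` (0/1).
``atom_maps.tsv``
    columns ``reaction``, ``atom_map``.  An atom map uses the lowercase
    letter convention, e.g. ``A(ab) + B(c) --> C(abc)``.  Symmetric
    metabolites are encoded as several ``;``-separated variants with
    weight prefixes, e.g. ``0.5: A(ab) --> B(ab); 0.5: A(ab) --> B(ba)``.
``regulations.tsv``
    columns ``reaction``, ``inhibitor``, ``mode`` (``competitive``,
    ``uncompetitive`` or ``noncompetitive``).
``binding_orders.tsv`` (optional)
    columns ``reaction``, ``binding_order``, ``release_order``
    (comma-separated metabolite ids).  Reactions without a row default to
    declaration order in the stoichiometry.

Fluxes are expressed throughout in mmol per 100 mmol wild-type glucose
uptake; stoichiometric coefficients are rational numbers.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

INHIBITION_MODES = ("competitive", "uncompetitive", "noncompetitive")


class ModelError(ValueError):
    """Raised for malformed or inconsistent model inputs."""


@dataclass
class Metabolite:
    id: str
    carbon_count: int = 0
    is_extracellular: bool = False
    is_biomass_precursor: bool = False

    def __post_init__(self) -> None:
        if self.carbon_count < 0:
            raise ModelError(f"metabolite {self.id}: negative carbon count")


#: one atom-map variant: (weight, [(species, atom_string), ...] substrates,
#: [(species, atom_string), ...] products)
AtomMapVariant = tuple[float, list[tuple[str, str]], list[tuple[str, str]]]


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, Fraction]
    reversible: bool = False
    atom_map: list[AtomMapVariant] | None = None
    enzyme_id: str | None = None
    binding_order: list[str] | None = None
    release_order: list[str] | None = None
    excluded_from_fit: bool = False
    role: str = ""  # "uptake", "sink" or ""

    @property
    def substrates(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    @property
    def products(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]


@dataclass
class Regulation:
    reaction_id: str
    inhibitor_metabolite_id: str
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in INHIBITION_MODES:
            raise ModelError(
                f"regulation on {self.reaction_id}: unknown mode {self.mode!r}"
            )


@dataclass
class MetabolicModel:
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    regulations: list[Regulation] = field(default_factory=list)
    uptake_reaction_id: str | None = None

    @property
    def biomass_sinks(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.role == "sink"]

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    @property
    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if not m.is_extracellular]

    def stoichiometric_matrix(self, internal_only: bool = False) -> pd.DataFrame:
        """S with one row per metabolite and one column per reaction."""
        rows = self.internal_metabolite_ids if internal_only else self.metabolite_ids
        S = pd.DataFrame(0.0, index=rows, columns=self.reaction_ids)
        for rxn in self.reactions.values():
            for met, coeff in rxn.stoichiometry.items():
                if met in S.index:
                    S.loc[met, rxn.id] = float(coeff)
        return S

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites={k: dataclasses.replace(v) for k, v in self.metabolites.items()},
            reactions={
                k: dataclasses.replace(
                    v,
                    stoichiometry=dict(v.stoichiometry),
                    atom_map=None if v.atom_map is None else [
                        (w, list(s), list(p)) for w, s, p in v.atom_map
                    ],
                    binding_order=None if v.binding_order is None else list(v.binding_order),
                    release_order=None if v.release_order is None else list(v.release_order),
                )
                for k, v in self.reactions.items()
            },
            regulations=[dataclasses.replace(r) for r in self.regulations],
            uptake_reaction_id=self.uptake_reaction_id,
        )


@dataclass
class FluxDistribution:
    """Per-reaction net fluxes on a 100-unit glucose uptake basis."""

    strain_id: str
    reactions: list[str]
    v: np.ndarray
    sd: np.ndarray | None = None
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None
    basis_uptake: float = 100.0

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        for name in ("sd", "ci_lo", "ci_hi"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, np.asarray(val, dtype=float))

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.v[self.reactions.index(reaction_id)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.reactions, self.v))

    def to_frame(self) -> pd.DataFrame:
        data = {"reaction": self.reactions, "v": self.v}
        for name in ("sd", "ci_lo", "ci_hi"):
            val = getattr(self, name)
            if val is not None:
                data[name] = val
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, strain_id: str = "",
                   basis_uptake: float = 100.0) -> "FluxDistribution":
        return cls(
            strain_id=strain_id,
            reactions=list(df["reaction"]),
            v=df["v"].to_numpy(dtype=float),
            sd=df["sd"].to_numpy(dtype=float) if "sd" in df else None,
            ci_lo=df["ci_lo"].to_numpy(dtype=float) if "ci_lo" in df else None,
            ci_hi=df["ci_hi"].to_numpy(dtype=float) if "ci_hi" in df else None,
            basis_uptake=basis_uptake,
        )


# ---------------------------------------------------------------------------
# parsing helpers

_ARROWS = ("<-->", "<=>", "-->", "->", "=")


def _parse_coeff(tok: str) -> Fraction:
    try:
        return Fraction(tok)
    except ValueError as exc:
        raise ModelError(f"bad stoichiometric coefficient {tok!r}") from exc


def parse_equation(eq: str) -> tuple[dict[str, Fraction], bool]:
    """Parse ``A + 2 B --> C`` into a signed-coefficient dict."""
    arrow = next((a for a in _ARROWS if a in eq), None)
    if arrow is None:
        raise ModelError(f"no arrow in equation {eq!r}")
    reversible = arrow in ("<-->", "<=>", "=")
    lhs, rhs = eq.split(arrow, 1)
    stoich: dict[str, Fraction] = {}

    def add_side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                coeff, met = Fraction(1), parts[0]
            elif len(parts) == 2:
                coeff, met = _parse_coeff(parts[0]), parts[1]
            else:
                raise ModelError(f"cannot parse term {term!r} in {eq!r}")
            stoich[met] = stoich.get(met, Fraction(0)) + sign * coeff
    add_side(lhs, -1)
    add_side(rhs, +1)
    return {m: c for m, c in stoich.items() if c != 0}, reversible


_SPECIES_RE = re.compile(r"^\s*([\w.\-\[\]]+)\s*\(([a-z]*)\)\s*$")


def parse_atom_map(text: str) -> list[AtomMapVariant]:
    """Parse an atom-map string into weighted variants."""
    variants: list[AtomMapVariant] = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        weight = 1.0
        m = re.match(r"^([0-9.]+|[0-9]+/[0-9]+)\s*:\s*(.*)$", chunk)
        if m:
            weight = float(Fraction(m.group(1)))
            chunk = m.group(2)
        arrow = next((a for a in _ARROWS if a in chunk), None)
        if arrow is None:
            raise ModelError(f"no arrow in atom map {text!r}")
        lhs, rhs = chunk.split(arrow, 1)

        def side(s: str) -> list[tuple[str, str]]:
            out = []
            for term in s.split("+"):
                term = term.strip()
                if not term:
                    continue
                sm = _SPECIES_RE.match(term)
                if sm is None:
                    raise ModelError(f"malformed atom-map species {term!r}")
                out.append((sm.group(1), sm.group(2)))
            return out
        variants.append((weight, side(lhs), side(rhs)))
    if not variants:
        raise ModelError(f"empty atom map {text!r}")
    return variants


def format_atom_map(variants: list[AtomMapVariant]) -> str:
    chunks = []
    for weight, subs, prods in variants:
        lhs = " + ".join(f"{m}({s})" for m, s in subs)
        rhs = " + ".join(f"{m}({s})" for m, s in prods)
        prefix = "" if weight == 1.0 else f"{weight}: "
        chunks.append(f"{prefix}{lhs} --> {rhs}")
    return "; ".join(chunks)


def format_equation(rxn: Reaction) -> str:
    def fmt(mets: list[str]) -> str:
        terms = []
        for m in mets:
            c = abs(rxn.stoichiometry[m])
            terms.append(f"{c} {m}" if c != 1 else m)
        return " + ".join(terms)
    arrow = "<=>" if rxn.reversible else "-->"
    return f"{fmt(rxn.substrates)} {arrow} {fmt(rxn.products)}"


# ---------------------------------------------------------------------------
# load / write

def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def load_model(path: str | Path) -> MetabolicModel:
    """Load a model workbook directory; cross-references are validated."""
    path = Path(path)
    for sheet in ("metabolites.tsv", "reactions.tsv"):
        if not (path / sheet).exists():
            raise ModelError(f"missing sheet {sheet} in {path}")

    mets: dict[str, Metabolite] = {}
    for _, row in _read_tsv(path / "metabolites.tsv").iterrows():
        mid = row["id"]
        if mid in mets:
            raise ModelError(f"duplicate metabolite id {mid!r}")
        mets[mid] = Metabolite(
            id=mid,
            carbon_count=int(row["carbon_count"]),
            is_extracellular=row.get("extracellular", "0") == "1",
            is_biomass_precursor=row.get("biomass_precursor", "0") == "1",
        )

    rxns: dict[str, Reaction] = {}
    uptake_id: str | None = None
    for _, row in _read_tsv(path / "reactions.tsv").iterrows():
        rid = row["id"]
        if rid in rxns:
            raise ModelError(f"duplicate reaction id {rid!r}")
        stoich, reversible = parse_equation(row["equation"])
        for met in stoich:
            if met not in mets:
                raise ModelError(
                    f"reaction {rid}: unknown metabolite {met!r} in equation "
                    f"{row['equation']!r}"
                )
        role = row.get("role", "").strip()
        rxns[rid] = Reaction(
            id=rid,
            stoichiometry=stoich,
            reversible=reversible,
            enzyme_id=row.get("enzyme", "").strip() or None,
            excluded_from_fit=row.get("excluded_from_fit", "0") == "1",
            role=role,
        )
        if role == "uptake":
            uptake_id = rid

    am_path = path / "atom_maps.tsv"
    if am_path.exists():
        for _, row in _read_tsv(am_path).iterrows():
            rid = row["reaction"]
            if rid not in rxns:
                raise ModelError(f"atom map for unknown reaction {rid!r}")
            variants = parse_atom_map(row["atom_map"])
            for _, subs, prods in variants:
                for met, s in subs + prods:
                    if met not in mets:
                        raise ModelError(
                            f"atom map of {rid}: unknown metabolite {met!r}"
                        )
                    if len(s) != mets[met].carbon_count:
                        raise ModelError(
                            f"atom map of {rid}: {met} has {mets[met].carbon_count} "
                            f"carbons but atom string {s!r}"
                        )
            rxns[rid].atom_map = variants

    reg_path = path / "regulations.tsv"
    regs: list[Regulation] = []
    if reg_path.exists():
        for _, row in _read_tsv(reg_path).iterrows():
            if row["reaction"] not in rxns:
                raise ModelError(
                    f"regulation row references unknown reaction {row['reaction']!r}"
                )
            if row["inhibitor"] not in mets:
                raise ModelError(
                    f"regulation on {row['reaction']}: unknown metabolite "
                    f"{row['inhibitor']!r}"
                )
            regs.append(Regulation(row["reaction"], row["inhibitor"], row["mode"]))

    bo_path = path / "binding_orders.tsv"
    if bo_path.exists():
        for _, row in _read_tsv(bo_path).iterrows():
            rid = row["reaction"]
            if rid not in rxns:
                raise ModelError(f"binding order for unknown reaction {rid!r}")
            if row.get("binding_order", ""):
                rxns[rid].binding_order = [
                    s.strip() for s in row["binding_order"].split(",") if s.strip()
                ]
            if row.get("release_order", ""):
                rxns[rid].release_order = [
                    s.strip() for s in row["release_order"].split(",") if s.strip()
                ]

    return MetabolicModel(mets, rxns, regs, uptake_reaction_id=uptake_id)


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model back to TSV sheets (inverse of :func:`load_model`)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "id": m.id,
                "carbon_count": m.carbon_count,
                "extracellular": int(m.is_extracellular),
                "biomass_precursor": int(m.is_biomass_precursor),
            }
            for m in model.metabolites.values()
        ]
    ).to_csv(path / "metabolites.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "id": r.id,
                "equation": format_equation(r),
                "enzyme": r.enzyme_id or "",
                "role": r.role,
                "excluded_from_fit": int(r.excluded_from_fit),
            }
            for r in model.reactions.values()
        ]
    ).to_csv(path / "reactions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"reaction": r.id, "atom_map": format_atom_map(r.atom_map)}
            for r in model.reactions.values()
            if r.atom_map is not None
        ],
        columns=["reaction", "atom_map"],
    ).to_csv(path / "atom_maps.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "reaction": g.reaction_id,
                "inhibitor": g.inhibitor_metabolite_id,
                "mode": g.mode,
            }
            for g in model.regulations
        ],
        columns=["reaction", "inhibitor", "mode"],
    ).to_csv(path / "regulations.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "reaction": r.id,
                "binding_order": ",".join(r.binding_order or []),
                "release_order": ",".join(r.release_order or []),
            }
            for r in model.reactions.values()
            if r.binding_order is not None or r.release_order is not None
        ],
        columns=["reaction", "binding_order", "release_order"],
    ).to_csv(path / "binding_orders.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# validation

@dataclass
class ValidationReport:
    findings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def __str__(self) -> str:
        if self.ok:
            return "model valid: no findings"
        return "\n".join(self.findings)


def atom_balance_ok(rxn: Reaction) -> bool:
    """True if every atom letter appears exactly once on each side in every
    atom-map variant (carbon conservation)."""
    if rxn.atom_map is None:
        return True
    for _, subs, prods in rxn.atom_map:
        lhs = "".join(s for _, s in subs)
        rhs = "".join(s for _, s in prods)
        if sorted(lhs) != sorted(rhs) and rhs:  # sinks may drop all carbon
            return False
        if len(set(lhs)) != len(lhs) or len(set(rhs)) != len(rhs):
            return False
    return True


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Report carbon-imbalanced atom maps, orphan metabolites and
    inconsistent kinetic declarations; an empty report means valid."""
    rep = ValidationReport()
    used: set[str] = set()
    for rxn in model.reactions.values():
        used.update(rxn.stoichiometry)
        if not atom_balance_ok(rxn):
            rep.findings.append(f"carbon-imbalanced atom map in reaction {rxn.id}")
        if rxn.atom_map is not None:
            for _, subs, prods in rxn.atom_map:
                for met, _ in subs:
                    if met not in rxn.substrates:
                        rep.findings.append(
                            f"reaction {rxn.id}: atom-map substrate {met} not in "
                            "stoichiometry"
                        )
                for met, _ in prods:
                    if met not in rxn.products:
                        rep.findings.append(
                            f"reaction {rxn.id}: atom-map product {met} not in "
                            "stoichiometry"
                        )
        if rxn.binding_order is not None:
            for met in rxn.binding_order:
                if met not in rxn.substrates:
                    rep.findings.append(
                        f"reaction {rxn.id}: binding order names non-substrate {met}"
                    )
        if rxn.release_order is not None:
            for met in rxn.release_order:
                if met not in rxn.products:
                    rep.findings.append(
                        f"reaction {rxn.id}: release order names non-product {met}"
                    )
    for met in model.metabolites.values():
        if met.id not in used:
            rep.findings.append(f"orphan metabolite {met.id}")
    for reg in model.regulations:
        rxn = model.reactions.get(reg.reaction_id)
        if rxn is not None and rxn.enzyme_id is None:
            rep.findings.append(
                f"regulation on {reg.reaction_id} which has no enzyme"
            )
    return rep


# ---------------------------------------------------------------------------
# network reduction

@dataclass
class ReductionRules:
    """Rules for simplifying a network prior to flux elucidation.

    ``drop_reactions`` removes reactions outright (e.g. degradation
    pathways); ``strip_metabolites`` removes species (e.g. cofactors and
    nitrogen/oxygen/sulfur carriers) from every stoichiometry;
    ``lump_carbon_only`` restricts the named reactions to the species
    appearing in their atom maps (carbon-transfer-only synthesis lumps).
    """

    drop_reactions: list[str] = field(default_factory=list)
    strip_metabolites: list[str] = field(default_factory=list)
    lump_carbon_only: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReductionRules":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            drop_reactions=list(data.get("drop_reactions", [])),
            strip_metabolites=list(data.get("strip_metabolites", [])),
            lump_carbon_only=list(data.get("lump_carbon_only", [])),
        )


def reduce_network(
    model: MetabolicModel, rules: ReductionRules
) -> tuple[MetabolicModel, dict[str, str]]:
    """Apply reduction rules; returns the reduced model and a map from
    reduced reaction ids to the full-model ids (identity here, retained so
    projections between the two networks stay explicit)."""
    for rid in rules.drop_reactions + rules.lump_carbon_only:
        if rid not in model.reactions:
            raise ModelError(f"reduction rule references absent reaction {rid!r}")
    for mid in rules.strip_metabolites:
        if mid not in model.metabolites:
            raise ModelError(f"reduction rule references absent metabolite {mid!r}")

    out = model.copy()
    for rid in rules.drop_reactions:
        del out.reactions[rid]
    for rid in rules.lump_carbon_only:
        if rid not in out.reactions:
            continue
        rxn = out.reactions[rid]
        if rxn.atom_map is None:
            raise ModelError(f"cannot lump {rid}: no atom map")
        carbon_species = {m for _, s, p in rxn.atom_map for m, _ in s + p}
        rxn.stoichiometry = {
            m: c for m, c in rxn.stoichiometry.items() if m in carbon_species
        }
    stripped = set(rules.strip_metabolites)
    for rxn in out.reactions.values():
        rxn.stoichiometry = {
            m: c for m, c in rxn.stoichiometry.items() if m not in stripped
        }
        if rxn.binding_order:
            rxn.binding_order = [m for m in rxn.binding_order if m not in stripped]
        if rxn.release_order:
            rxn.release_order = [m for m in rxn.release_order if m not in stripped]
    for mid in stripped:
        del out.metabolites[mid]
    out.regulations = [
        g
        for g in out.regulations
        if g.reaction_id in out.reactions
        and g.inhibitor_metabolite_id not in stripped
    ]
    # prune metabolites left orphaned by dropped reactions
    used = {m for r in out.reactions.values() for m in r.stoichiometry}
    out.metabolites = {k: v for k, v in out.metabolites.items() if k in used}
    mapping = {rid: rid for rid in out.reactions}
    return out, mapping


# ---------------------------------------------------------------------------
# generic result IO

def write_results(obj, path: str | Path) -> Path:
    """Write a result object to disk: flux tables as TSV, everything else
    as JSON via its ``to_json_dict``/``to_frame`` method."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, FluxDistribution):
        obj.to_frame().to_csv(path, sep="\t", index=False)
    elif hasattr(obj, "to_json_dict"):
        with open(path, "w") as fh:
            json.dump(obj.to_json_dict(), fh, indent=1)
    elif hasattr(obj, "to_frame"):
        obj.to_frame().to_csv(path, sep="\t", index=False)
    elif dataclasses.is_dataclass(obj):
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(obj), fh, indent=1, default=_json_default)
    else:
        raise TypeError(f"do not know how to write {type(obj).__name__}")
    return path


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, Fraction):
        return str(o)
    raise TypeError(type(o).__name__)


def read_flux_distribution(path: str | Path, strain_id: str = "") -> FluxDistribution:
    df = pd.read_csv(path, sep="\t")
    return FluxDistribution.from_frame(df, strain_id=strain_id)
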