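"""Metabolic model core: SBML I/O, GPR parsing, reaction classification.

The model representation is deliberately small: plain dataclasses holding
stoichiometry, bounds, GPR rule text and a pathway (subsystem) label per
reaction.  SBML (Level 3 + FBC) reading and writing is delegated to cobrapy;
pathway labels travel through the SBML groups extension.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple, Union

__all__ = [
    "SBMLParseError",
    "GPRParseError",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "GeneRef",
    "BoolOp",
    "GPRExpression",
    "parse_gpr",
    "split_compartment",
    "classify_reaction",
    "CurrencySet",
    "load_id_list",
    "default_currency",
    "default_essential_amino_acids",
    "read_sbml",
    "write_sbml",
]

logger = logging.getLogger(__name__)

EXTRACELLULAR_TAGS = frozenset({"e", "ext", "x", "extracellular"})

REACTION_CLASSES = ("metabolic", "exchange", "demand", "transport", "unassigned")

UNASSIGNED = "unassigned"


class SBMLParseError(ValueError):
    """Raised when an SBML file cannot be read or is structurally invalid."""


class GPRParseError(ValueError):
    """Raised for malformed gene-protein-reaction rule text."""


# ---------------------------------------------------------------------------
# Compartment convention: metabolite ids end in an underscore-delimited
# compartment tag ("akg_c" -> base "akg", compartment "c").
# ---------------------------------------------------------------------------

_COMPARTMENT_RE = re.compile(r"^(?P<base>.+)_(?P<comp>[A-Za-z][A-Za-z0-9]{0,2})$")


def split_compartment(met_id: str) -> Tuple[str, str]:
    """Split a metabolite id into (base id, compartment tag).

    Ids without a recognizable suffix get the empty compartment tag.
    """
    m = _COMPARTMENT_RE.match(met_id)
    if m is None:
        return met_id, ""
    return m.group("base"), m.group("comp")


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""

    @property
    def base_id(self) -> str:
        return split_compartment(self.id)[0]


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: str = ""
    pathway: str = UNASSIGNED

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0 < self.upper_bound

    def reactant_ids(self) -> List[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    def product_ids(self) -> List[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]


@dataclass
class MetabolicModel:
    id: str
    metabolites: Dict[str, Metabolite]
    reactions: Dict[str, Reaction]
    genes: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        import math

        for rxn in self.reactions.values():
            if rxn.lower_bound > rxn.upper_bound:
                raise ValueError(
                    f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} exceeds "
                    f"upper bound {rxn.upper_bound}"
                )
            for met_id, coef in rxn.stoichiometry.items():
                if met_id not in self.metabolites:
                    raise ValueError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )
                if coef == 0 or not math.isfinite(coef):
                    raise ValueError(
                        f"reaction {rxn.id!r}: invalid coefficient {coef!r} "
                        f"for {met_id!r}"
                    )

    @property
    def pathways(self) -> List[str]:
        return sorted({r.pathway for r in self.reactions.values()})

    def reactions_involving(self, met_id: str) -> List[Reaction]:
        if met_id not in self.metabolites:
            raise KeyError(f"unknown metabolite {met_id!r}")
        return [r for r in self.reactions.values() if met_id in r.stoichiometry]


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRef:
    gene: str


@dataclass(frozen=True)
class BoolOp:
    op: str  # "and" | "or"
    args: Tuple["GPRNode", ...]


GPRNode = Union[GeneRef, BoolOp]


@dataclass(frozen=True)
class GPRExpression:
    """Boolean tree over gene ids; ``root is None`` means no gene association."""

    root: Optional[GPRNode] = None

    @property
    def empty(self) -> bool:
        return self.root is None

    def genes(self) -> FrozenSet[str]:
        out: set = set()

        def walk(node: GPRNode) -> None:
            if isinstance(node, GeneRef):
                out.add(node.gene)
            else:
                for a in node.args:
                    walk(a)

        if self.root is not None:
            walk(self.root)
        return frozenset(out)

    def evaluate(self, values: Mapping[str, float], and_op, or_op,
                 missing: float = 0.0) -> Optional[float]:
        """Fold the tree with the given AND/OR reducers; None when empty."""
        if self.root is None:
            return None

        def walk(node: GPRNode) -> float:
            if isinstance(node, GeneRef):
                return float(values.get(node.gene, missing))
            scores = [walk(a) for a in node.args]
            return and_op(scores) if node.op == "and" else or_op(scores)

        return walk(self.root)


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize_gpr(text: str) -> List[str]:
    tokens: List[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append(m.group(1))
        pos = m.end()
    if text[pos:].strip():
        raise GPRParseError(f"unparseable GPR fragment: {text[pos:]!r}")
    return tokens


def parse_gpr(rule_text: str) -> GPRExpression:
    """Parse ``and``/``or``/parenthesis rule text into a :class:`GPRExpression`.

    Grammar: ``expr := term ('or' term)*``, ``term := factor ('and' factor)*``,
    ``factor := gene | '(' expr ')'``.  Empty text yields the empty expression.
    """
    tokens = _tokenize_gpr(rule_text or "")
    if not tokens:
        return GPRExpression(None)
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def keyword(tok: Optional[str]) -> Optional[str]:
        if tok is None:
            return None
        low = tok.lower()
        return low if low in ("and", "or") else None

    def parse_factor() -> GPRNode:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR rule: {rule_text!r}")
        if tok == "(":
            pos += 1
            node = parse_expr()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in GPR rule: {rule_text!r}")
            pos += 1
            return node
        if tok == ")" or keyword(tok) is not None:
            raise GPRParseError(f"unexpected token {tok!r} in GPR rule: {rule_text!r}")
        pos += 1
        return GeneRef(tok)

    def parse_term() -> GPRNode:
        nonlocal pos
        args = [parse_factor()]
        while keyword(peek()) == "and":
            pos += 1
            args.append(parse_factor())
        return args[0] if len(args) == 1 else BoolOp("and", tuple(args))

    def parse_expr() -> GPRNode:
        nonlocal pos
        args = [parse_term()]
        while keyword(peek()) == "or":
            pos += 1
            args.append(parse_term())
        return args[0] if len(args) == 1 else BoolOp("or", tuple(args))

    root = parse_expr()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in GPR rule: {rule_text!r}")
    return GPRExpression(root)


# ---------------------------------------------------------------------------
# Reaction classification
# ---------------------------------------------------------------------------

def classify_reaction(reaction: Reaction, model: MetabolicModel) -> str:
    """Classify into exchange / demand / transport / unassigned / metabolic.

    A single-metabolite boundary reaction is an exchange when the metabolite
    is extracellular and a demand (sink) otherwise.  A reaction whose consumed
    and produced base ids coincide but whose compartments differ is a
    transport; reactions mixing transport with chemistry stay metabolic.
    """
    stoich = reaction.stoichiometry
    if len(stoich) == 1:
        met_id = next(iter(stoich))
        met = model.metabolites[met_id]
        comp = met.compartment or split_compartment(met_id)[1]
        if comp.lower() in EXTRACELLULAR_TAGS:
            return "exchange"
        return "demand"

    reactant_bases = {split_compartment(m)[0] for m in reaction.reactant_ids()}
    product_bases = {split_compartment(m)[0] for m in reaction.product_ids()}
    if (
        reactant_bases
        and reactant_bases == product_bases
        and set(reaction.reactant_ids()) != set(reaction.product_ids())
    ):
        return "transport"

    if reaction.pathway == UNASSIGNED:
        return "unassigned"
    return "metabolic"


# ---------------------------------------------------------------------------
# Currency metabolites and other id lists
# ---------------------------------------------------------------------------

def load_id_list(path: Union[str, os.PathLike]) -> FrozenSet[str]:
    """Read a one-id-per-line text file; '#' starts a comment."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.add(line.lower())
    return frozenset(ids)


@dataclass(frozen=True)
class CurrencySet:
    """Compartment-agnostic metabolite id set; lookup ignores the tag."""

    base_ids: FrozenSet[str]

    def __contains__(self, met_id: str) -> bool:
        return split_compartment(met_id)[0].lower() in self.base_ids

    def __len__(self) -> int:
        return len(self.base_ids)

    @classmethod
    def from_file(cls, path: Union[str, os.PathLike]) -> "CurrencySet":
        ids = load_id_list(path)
        if not ids:
            raise ValueError(f"currency list {path!s} is empty")
        return cls(ids)


def _packaged_list(filename: str) -> FrozenSet[str]:
    ref = resources.files("mgpflux.data") / filename
    with resources.as_file(ref) as path:
        return load_id_list(path)


def default_currency() -> CurrencySet:
    return CurrencySet(_packaged_list("currency_metabolites.txt"))


def default_essential_amino_acids() -> FrozenSet[str]:
    return _packaged_list("essential_amino_acids.txt")


# ---------------------------------------------------------------------------
# SBML I/O (via cobrapy; pathway labels via the groups extension)
# ---------------------------------------------------------------------------

def read_sbml(path: Union[str, os.PathLike]) -> MetabolicModel:
    """Read an SBML (Level 3 + FBC) model file."""
    import cobra.io

    if not os.path.exists(path):
        raise SBMLParseError(f"SBML file not found: {path!s}")
    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml raises a zoo of types
        raise SBMLParseError(f"could not parse SBML file {path!s}: {exc}") from exc

    pathway_of: Dict[str, str] = {}
    for group in getattr(cmodel, "groups", []):
        label = group.name or group.id
        for member in group.members:
            pathway_of.setdefault(member.id, label)

    metabolites = {
        m.id: Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "")
        for m in cmodel.metabolites
    }
    reactions: Dict[str, Reaction] = {}
    for r in cmodel.reactions:
        if r.lower_bound is None or r.upper_bound is None:
            raise SBMLParseError(f"reaction {r.id!r} in {path!s} has missing bounds")
        pathway = (
            pathway_of.get(r.id)
            or r.subsystem
            or (r.notes or {}).get("SUBSYSTEM")
            or UNASSIGNED
        )
        reactions[r.id] = Reaction(
            id=r.id,
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            gpr=r.gene_reaction_rule or "",
            pathway=pathway,
        )
    genes = tuple(sorted(g.id for g in cmodel.genes))
    return MetabolicModel(
        id=cmodel.id or "model", metabolites=metabolites, reactions=reactions,
        genes=genes,
    )


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model.

    Pathway labels are stored in reaction notes (SUBSYSTEM) rather than SBML
    groups: cobrapy keeps group members in a set, which makes the serialized
    member order — and hence the output bytes — nondeterministic.
    """
    import cobra

    cmodel = cobra.Model(model.id)
    cmets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        for m in model.metabolites.values()
    }
    crxns = []
    for rxn in model.reactions.values():
        cr = cobra.Reaction(
            rxn.id, lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound
        )
        crxns.append(cr)
    cmodel.add_metabolites(list(cmets.values()))
    cmodel.add_reactions(crxns)
    for rxn in model.reactions.values():
        cr = cmodel.reactions.get_by_id(rxn.id)
        cr.add_metabolites({cmets[m]: c for m, c in rxn.stoichiometry.items()})
        if rxn.gpr:
            cr.gene_reaction_rule = rxn.gpr
        if rxn.pathway != UNASSIGNED:
            cr.notes = {"SUBSYSTEM": rxn.pathway}
    return cmodel


def write_sbml(model: MetabolicModel, path: Union[str, os.PathLike]) -> None:
    """Write the model as SBML Level 3 + FBC (deterministic output)."""
    import cobra.io

    logging.getLogger("cobra.io.sbml").setLevel(logging.ERROR)
    cobra.io.write_sbml_model(to_cobra(model), str(path))
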