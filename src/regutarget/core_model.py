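"""Constraint-based model container, GPR boolean rules and subunit factors.

The metabolic side of the pipeline needs three things from a model: the
stoichiometry/bounds (for the LP sweeps), the biomass and target reaction
ids, and per-reaction gene-protein-reaction (GPR) boolean rules.  GPR rules
link genes to reactions: isozymes combine with OR (any one gene suffices),
enzyme-complex subunits combine with AND (all genes are required).

The GPR *subunit factor* ``GPRf_j`` quantifies how much of a reaction's
enzyme one gene accounts for: a gene reachable from the root through OR
nodes only can form the full enzyme (factor 1); each AND node with ``c``
children divides responsibility ``c`` ways, multiplying the factor by ``c``
on the way down.  A gene's activity score for the reaction is later divided
by this factor, so genes deep inside large complexes weigh less.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

__all__ = [
    "GPRTree",
    "Reaction",
    "MetabolicModel",
    "GPRParseError",
    "ConfigurationError",
    "parse_gpr",
    "compute_gpr_factors",
    "read_sbml_model",
]


class GPRParseError(ValueError):
    """A GPR rule string could not be parsed."""


class ConfigurationError(ValueError):
    """A named reaction or option does not exist in the supplied inputs."""


# ---------------------------------------------------------------------------
# GPR trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPRTree:
    """Node of a boolean GPR expression: GENE leaf, or n-ary AND / OR.

    AND/OR nodes hold >= 2 children after normalisation; associative chains
    are flattened so ``a or b or c`` is a single 3-child OR node.
    """

    kind: str  # "GENE" | "AND" | "OR"
    children: tuple["GPRTree", ...] = ()
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind == "GENE":
            if not self.gene or self.children:
                raise ValueError("GENE node needs a gene id and no children")
        elif self.kind in ("AND", "OR"):
            if len(self.children) < 2:
                raise ValueError(f"{self.kind} node needs >= 2 children")
        else:
            raise ValueError(f"unknown GPR node kind {self.kind!r}")

    def genes(self) -> set[str]:
        """All gene ids appearing anywhere in the tree."""
        if self.kind == "GENE":
            return {self.gene}
        return set().union(*(c.genes() for c in self.children))

    def to_string(self) -> str:
        """Canonical fully-parenthesised form with lower-case and/or."""
        if self.kind == "GENE":
            return self.gene
        sep = f" {self.kind.lower()} "
        return "(" + sep.join(c.to_string() for c in self.children) + ")"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(rule: str) -> Iterator[tuple[str, int]]:
    for m in _TOKEN_RE.finditer(rule):
        yield m.group(0), m.start()


def parse_gpr(rule: str) -> Optional[GPRTree]:
    """Parse a GPR rule string into a :class:`GPRTree`.

    Grammar: ``or_expr := and_expr ("or" and_expr)*``,
    ``and_expr := atom ("and" atom)*``, ``atom := gene | "(" or_expr ")"`` —
    so ``and`` binds tighter than ``or``.  The keywords are matched
    case-insensitively; any other maximal run of non-space, non-parenthesis
    characters is a gene id.  Associative chains are flattened into one
    n-ary node.  An empty/whitespace rule returns ``None`` (no GPR).

    Raises :class:`GPRParseError` (with character position) on unbalanced
    parentheses or misplaced keywords.
    """
    tokens = list(_tokenize(rule))
    if not tokens:
        return None
    pos = 0

    def peek() -> Optional[tuple[str, int]]:
        return tokens[pos] if pos < len(tokens) else None

    def fail(msg: str, at: int) -> GPRParseError:
        return GPRParseError(f"{msg} at position {at} in GPR rule {rule!r}")

    def parse_or() -> GPRTree:
        nonlocal pos
        parts = [parse_and()]
        while (tk := peek()) is not None and tk[0].lower() == "or":
            pos += 1
            parts.append(parse_and())
        if len(parts) == 1:
            return parts[0]
        return GPRTree("OR", tuple(_flatten("OR", parts)))

    def parse_and() -> GPRTree:
        nonlocal pos
        parts = [parse_atom()]
        while (tk := peek()) is not None and tk[0].lower() == "and":
            pos += 1
            parts.append(parse_atom())
        if len(parts) == 1:
            return parts[0]
        return GPRTree("AND", tuple(_flatten("AND", parts)))

    def parse_atom() -> GPRTree:
        nonlocal pos
        tk = peek()
        if tk is None:
            raise fail("unexpected end of rule", len(rule))
        word, at = tk
        if word == "(":
            pos += 1
            inner = parse_or()
            closing = peek()
            if closing is None or closing[0] != ")":
                raise fail("unbalanced parenthesis (missing ')')", at)
            pos += 1
            return inner
        if word == ")":
            raise fail("unbalanced parenthesis (unexpected ')')", at)
        if word.lower() in ("and", "or"):
            raise fail(f"misplaced keyword {word!r}", at)
        pos += 1
        return GPRTree("GENE", gene=word)

    tree = parse_or()
    if (tk := peek()) is not None:
        raise fail(f"trailing token {tk[0]!r}", tk[1])
    return tree


def _flatten(kind: str, parts: list[GPRTree]) -> Iterator[GPRTree]:
    for p in parts:
        if p.kind == kind:
            yield from p.children
        else:
            yield p


def compute_gpr_factors(tree: GPRTree) -> dict[str, float]:
    """Subunit factor ``GPRf_j`` for every gene in a GPR tree.

    The root carries factor 1.  An OR node (isozymes) passes its factor
    unchanged to each child; an AND node with ``c`` children (complex of
    ``c`` parts) passes ``factor * c`` to each child; a GENE leaf records
    the arriving factor.  A gene appearing in several leaves keeps the
    minimum of its leaf factors — its strongest single contribution.

    Example: ``(A and (B or (C and D))) or E`` yields
    ``{E: 1, A: 2, B: 2, C: 4, D: 4}``.
    """
    if tree is None:
        raise ValueError("cannot compute GPR factors of an empty tree")
    factors: dict[str, float] = {}

    def walk(node: GPRTree, factor: float) -> None:
        if node.kind == "GENE":
            prev = factors.get(node.gene)
            factors[node.gene] = factor if prev is None else min(prev, factor)
        elif node.kind == "OR":
            for c in node.children:
                walk(c, factor)
        else:  # AND
            child_factor = factor * len(node.children)
            for c in node.children:
                walk(c, child_factor)

    walk(tree, 1.0)
    return factors


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class Reaction:
    """One reaction: signed stoichiometry, flux bounds, optional GPR."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: Optional[GPRTree] = None

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def genes(self) -> set[str]:
        return self.gpr.genes() if self.gpr is not None else set()


@dataclass
class MetabolicModel:
    """Stoichiometric model with designated biomass and target reactions.

    ``cobra_model`` keeps the underlying cobra object (when loaded from
    SBML or built by the fixture generator) so LP work can reuse it; the
    dataclass fields are the authoritative view the rest of the pipeline
    reads.
    """

    metabolites: list[str]
    reactions: list[Reaction]
    biomass_reaction: str
    target_reaction: str
    genes: list[str] = field(default_factory=list)
    cobra_model: object = None

    def __post_init__(self) -> None:
        ids = {r.id for r in self.reactions}
        if self.biomass_reaction not in ids:
            raise ConfigurationError(
                f"biomass reaction {self.biomass_reaction!r} not in model"
            )
        if self.target_reaction not in ids:
            raise ConfigurationError(
                f"target reaction {self.target_reaction!r} not in model"
            )
        declared = set(self.metabolites)
        for r in self.reactions:
            missing = set(r.stoichiometry) - declared
            if missing:
                raise ValueError(
                    f"reaction {r.id} references undeclared metabolites {sorted(missing)}"
                )
        gpr_genes = set().union(*(r.genes for r in self.reactions)) if self.reactions else set()
        if not self.genes:
            self.genes = sorted(gpr_genes)
        elif not gpr_genes <= set(self.genes):
            raise ValueError(
                f"GPR genes missing from gene list: {sorted(gpr_genes - set(self.genes))}"
            )

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def gene_associated_reactions(self) -> list[Reaction]:
        """Reactions carrying a GPR — the ones swept for flux slopes."""
        return [r for r in self.reactions if r.gpr is not None]

    def gpr_factor_table(self) -> dict[str, dict[str, float]]:
        """Per-reaction gene -> GPRf mapping (reactions without GPR omitted)."""
        return {
            r.id: compute_gpr_factors(r.gpr)
            for r in self.reactions
            if r.gpr is not None
        }


def read_sbml_model(
    path: str | Path, biomass_id: str, target_id: str
) -> MetabolicModel:
    """Load an SBML (L3/fbc or L2 with GENE_ASSOCIATION notes) model.

    ``biomass_id`` and ``target_id`` must name reactions in the document;
    a missing id raises :class:`ConfigurationError` naming it.  GPR strings
    are re-parsed with :func:`parse_gpr`, so the whole pipeline sees one
    GPR dialect regardless of the SBML flavour.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SBML model file not found: {path}")
    from cobra.io import read_sbml_model as _cobra_read

    cm = _cobra_read(str(path))
    reactions = []
    for cr in cm.reactions:
        rule = cr.gene_reaction_rule or ""
        try:
            tree = parse_gpr(rule)
        except GPRParseError as exc:
            raise GPRParseError(
                f"reaction {cr.id}: {exc}"
            ) from exc
        reactions.append(
            Reaction(
                id=cr.id,
                stoichiometry={m.id: coef for m, coef in cr.metabolites.items()},
                lower_bound=float(cr.lower_bound),
                upper_bound=float(cr.upper_bound),
                gpr=tree,
            )
        )
    return MetabolicModel(
        metabolites=[m.id for m in cm.metabolites],
        reactions=reactions,
        biomass_reaction=biomass_id,
        target_reaction=target_id,
        genes=sorted(g.id for g in cm.genes),
        cobra_model=cm,
    )
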