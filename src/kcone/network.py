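"""Metabolic network representation and the plain-text reaction-list format.

A network is an ordered collection of metabolites and reactions.  Metabolites
whose id carries the boundary suffix (default ``_ext``) are *boundary*
(external) species: they are sources/sinks outside the steady-state balance
and are never rows of the stoichiometric matrix.  Declaration order of
metabolites and reactions fixes the row/column layout of the matrix, so the
same file always produces the same matrix.

Reaction-list format (UTF-8, ``#`` comments)::

    # id: substrates -> products [tags]
    HEX: glc -> g6p genes=HK1,HK2 pathways=glycolysis
    PGI: g6p <=> f6p
    PFK: 2 f6p -> fbp + f6p_ext

``->`` is irreversible, ``<=>`` reversible.  Coefficients are rationals
(``2``, ``1/2``, ``0.5``); omitted means 1.  Trailing ``key=value`` tokens
attach gene or pathway annotations (comma-separated values).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "StoichiometricMatrix",
    "ReactionValidation",
    "ValidationReport",
    "ReactionFileError",
    "parse_reaction_file",
    "write_reaction_file",
    "split_reversible",
    "stoichiometric_matrix",
    "validate_reconstruction",
]

_ID_RE = re.compile(r"^[A-Za-z0-9_]+$")
_COEF_RE = re.compile(r"^\d+(?:/\d+|\.\d+)?$")


class ReactionFileError(ValueError):
    """Raised for malformed reaction-list input; carries the line number."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    is_boundary: bool = False
    is_measured: bool = False


@dataclass(frozen=True)
class Reaction:
    """One reaction: signed rational stoichiometry (substrates < 0)."""

    id: str
    stoich: Mapping[str, Fraction]
    reversible: bool = False
    genes: tuple[str, ...] = ()
    pathways: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.stoich:
            raise ValueError(f"reaction {self.id!r} references no metabolites")
        if any(c == 0 for c in self.stoich.values()):
            raise ValueError(f"reaction {self.id!r} has a zero coefficient")

    @property
    def substrates(self) -> tuple[str, ...]:
        return tuple(m for m, c in self.stoich.items() if c < 0)

    @property
    def products(self) -> tuple[str, ...]:
        return tuple(m for m, c in self.stoich.items() if c > 0)

    def negated(self, new_id: str) -> "Reaction":
        return Reaction(
            id=new_id,
            stoich={m: -c for m, c in self.stoich.items()},
            reversible=False,
            genes=self.genes,
            pathways=self.pathways,
        )


@dataclass(frozen=True)
class MetabolicNetwork:
    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    boundary_suffix: str = "_ext"

    def __post_init__(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ValueError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ValueError("duplicate reaction ids")
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoich) - known
            if missing:
                raise ValueError(
                    f"reaction {r.id!r} references undeclared metabolites: "
                    f"{sorted(missing)}"
                )

    @property
    def metabolite_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.metabolites)

    @property
    def internal_metabolites(self) -> tuple[Metabolite, ...]:
        return tuple(m for m in self.metabolites if not m.is_boundary)

    @property
    def internal_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.internal_metabolites)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def is_split(self) -> bool:
        return not any(r.reversible for r in self.reactions)


def _parse_coef(tok: str, lineno: int) -> Fraction:
    if not _COEF_RE.match(tok):
        raise ReactionFileError(f"line {lineno}: bad coefficient {tok!r}")
    return Fraction(tok)


def _parse_side(side: str, sign: int, stoich: dict[str, Fraction], lineno: int) -> None:
    side = side.strip()
    if not side:
        return
    for term in side.split("+"):
        toks = term.split()
        if not toks:
            raise ReactionFileError(f"line {lineno}: empty term in equation")
        if len(toks) == 1:
            coef, met = Fraction(1), toks[0]
        elif len(toks) == 2:
            coef, met = _parse_coef(toks[0], lineno), toks[1]
        else:
            raise ReactionFileError(f"line {lineno}: cannot parse term {term.strip()!r}")
        if not _ID_RE.match(met):
            raise ReactionFileError(f"line {lineno}: bad metabolite id {met!r}")
        # repeated mentions of one metabolite sum (e.g. "A + A -> B" is 2 A)
        stoich[met] = stoich.get(met, Fraction(0)) + sign * coef


def parse_reaction_file(text: str, boundary_suffix: str = "_ext") -> MetabolicNetwork:
    """Parse a reaction-list document into a :class:`MetabolicNetwork`.

    Metabolites are declared implicitly by use, in order of first mention;
    ids ending in ``boundary_suffix`` are flagged as boundary species.
    """
    reactions: list[Reaction] = []
    seen_rxn: set[str] = set()
    met_order: dict[str, None] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ReactionFileError(f"line {lineno}: missing 'ID:' prefix")
        rid, eq = line.split(":", 1)
        rid = rid.strip()
        if not _ID_RE.match(rid):
            raise ReactionFileError(f"line {lineno}: bad reaction id {rid!r}")
        if rid in seen_rxn:
            raise ReactionFileError(f"line {lineno}: duplicate reaction id {rid!r}")

        # split off trailing key=value tags
        tags: dict[str, tuple[str, ...]] = {}
        toks = eq.split()
        while toks and "=" in toks[-1] and not any(a in toks[-1] for a in ("->", "<=>")):
            key, _, val = toks.pop().partition("=")
            tags[key] = tuple(v for v in val.split(",") if v)
        eq = " ".join(toks)

        if "<=>" in eq:
            lhs, rhs = eq.split("<=>", 1)
            reversible = True
        elif "->" in eq:
            lhs, rhs = eq.split("->", 1)
            reversible = False
        else:
            raise ReactionFileError(f"line {lineno}: missing '->' or '<=>' arrow")

        stoich: dict[str, Fraction] = {}
        _parse_side(lhs, -1, stoich, lineno)
        _parse_side(rhs, +1, stoich, lineno)
        stoich = {m: c for m, c in stoich.items() if c != 0}
        if not stoich:
            raise ReactionFileError(f"line {lineno}: reaction references no metabolites")
        for m in stoich:
            met_order.setdefault(m, None)
        try:
            reactions.append(
                Reaction(
                    id=rid,
                    stoich=stoich,
                    reversible=reversible,
                    genes=tags.get("genes", ()),
                    pathways=tags.get("pathways", ()),
                )
            )
        except ValueError as exc:  # pragma: no cover - guarded above
            raise ReactionFileError(f"line {lineno}: {exc}") from exc
        seen_rxn.add(rid)

    metabolites = tuple(
        Metabolite(id=m, is_boundary=m.endswith(boundary_suffix)) for m in met_order
    )
    return MetabolicNetwork(
        metabolites=metabolites, reactions=tuple(reactions), boundary_suffix=boundary_suffix
    )


def _fmt_coef(c: Fraction) -> str:
    return "" if c == 1 else f"{c} "


def _fmt_side(items: Sequence[tuple[str, Fraction]]) -> str:
    return " + ".join(f"{_fmt_coef(abs(c))}{m}" for m, c in items)


def write_reaction_file(network: MetabolicNetwork) -> str:
    """Serialize a network; ``parse_reaction_file(write_reaction_file(n))`` == n."""
    lines = ["# reaction list: 'ID: substrates -> products key=value...'"]
    for r in network.reactions:
        subs = [(m, c) for m, c in r.stoich.items() if c < 0]
        prods = [(m, c) for m, c in r.stoich.items() if c > 0]
        arrow = "<=>" if r.reversible else "->"
        line = f"{r.id}: {_fmt_side(subs)} {arrow} {_fmt_side(prods)}".rstrip()
        if r.genes:
            line += f" genes={','.join(r.genes)}"
        if r.pathways:
            line += f" pathways={','.join(r.pathways)}"
        lines.append(line)
    return "\n".join(lines) + "\n"


def split_reversible(network: MetabolicNetwork) -> MetabolicNetwork:
    """Replace each reversible reaction by irreversible ``_fwd``/``_rev`` steps.

    Mass-action rate constants are nonnegative, so the cone constraint
    ``k >= 0`` only makes sense on irreversible steps.  Idempotent on its own
    output (a split network has no reversible reactions left).
    """
    steps: list[Reaction] = []
    for r in network.reactions:
        if r.reversible:
            steps.append(replace(r, id=f"{r.id}_fwd", reversible=False))
            steps.append(r.negated(f"{r.id}_rev"))
        else:
            steps.append(r)
    return replace(network, reactions=tuple(steps))


@dataclass(frozen=True)
class StoichiometricMatrix:
    """Internal-metabolite x reaction-step matrix with exact rational entries."""

    entries: np.ndarray  # object array of Fraction, shape (n_internal, n_steps)
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    def to_float(self) -> np.ndarray:
        return self.entries.astype(float)

    def column(self, rxn_id: str) -> np.ndarray:
        return self.entries[:, self.col_ids.index(rxn_id)]


def stoichiometric_matrix(network: MetabolicNetwork) -> StoichiometricMatrix:
    """Build S: rows are internal metabolites, columns are irreversible steps.

    The network must already be reversibility-split so that every column is a
    forward step.  Boundary species are dropped (implicit uptake/secretion).
    """
    if not network.is_split():
        raise ValueError("network contains reversible reactions; call split_reversible first")
    rows = network.internal_ids
    if not rows:
        raise ValueError("network has only boundary metabolites: no balance constraints")
    row_index = {m: i for i, m in enumerate(rows)}
    S = np.full((len(rows), len(network.reactions)), Fraction(0), dtype=object)
    for j, r in enumerate(network.reactions):
        for m, c in r.stoich.items():
            i = row_index.get(m)
            if i is not None:
                S[i, j] = c
    return StoichiometricMatrix(entries=S, row_ids=rows, col_ids=network.reaction_ids)


@dataclass(frozen=True)
class ReactionValidation:
    reaction_id: str
    measurement_class: str  # both-measured | substrates-only | products-only | neither
    connected: bool
    gap_filler: bool  # touches no measured species at all


@dataclass(frozen=True)
class ValidationReport:
    reactions: tuple[ReactionValidation, ...]
    n_components: int

    @property
    def isolated(self) -> tuple[str, ...]:
        return tuple(r.reaction_id for r in self.reactions if not r.connected)

    def to_tsv(self) -> str:
        lines = [f"# connected components: {self.n_components}",
                 "reaction\tmeasurement_class\tconnected\tgap_filler"]
        for r in self.reactions:
            lines.append(
                f"{r.reaction_id}\t{r.measurement_class}\t{r.connected}\t{r.gap_filler}"
            )
        return "\n".join(lines) + "\n"


def validate_reconstruction(
    network: MetabolicNetwork, measured_ids: Iterable[str]
) -> ValidationReport:
    """Check the curation criteria a usable reconstruction should meet.

    Each reaction is classed by whether any internal substrate and/or any
    internal product has measured concentration data; a reaction sharing no
    internal metabolite with any other reaction is flagged as disconnected.
    These checks are advisory: the report describes the network, it does not
    reject it.
    """
    measured = set(measured_ids)
    internal = set(network.internal_ids)

    graph = nx.Graph()
    for r in network.reactions:
        graph.add_node(("rxn", r.id))
        for m in r.stoich:
            if m in internal:
                graph.add_edge(("rxn", r.id), ("met", m))

    records = []
    for r in network.reactions:
        subs = [m for m in r.substrates if m in internal]
        prods = [m for m in r.products if m in internal]
        s_meas = any(m in measured for m in subs)
        p_meas = any(m in measured for m in prods)
        if s_meas and p_meas:
            klass = "both-measured"
        elif s_meas:
            klass = "substrates-only"
        elif p_meas:
            klass = "products-only"
        else:
            klass = "neither"
        shared = any(
            graph.degree(("met", m)) > 1 for m in r.stoich if m in internal
        )
        records.append(
            ReactionValidation(
                reaction_id=r.id,
                measurement_class=klass,
                connected=shared,
                gap_filler=klass == "neither",
            )
        )
    n_comp = nx.number_connected_components(graph) if graph.number_of_nodes() else 0
    return ValidationReport(reactions=tuple(records), n_components=n_comp)
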