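"""KEGG-style module definitions: parsing, completeness, and expression rollup.

A KEGG module definition describes the gene content of a metabolic module as a
small grammar over KEGG Orthology (KO) identifiers:

* a **space** separates ordered reaction *steps* (all steps required),
* a **comma** separates *alternatives* (any one suffices),
* a **plus** joins subunits of a *complex* (all required),
* a **minus** marks a non-essential (optional) component of a complex,
* parentheses group sub-expressions.

Operator precedence, tightest first: ``+``/``-``, then ``,``, then the step
separator.  A module is *complete* for a set of present KOs when every
non-optional step is satisfiable; the fraction of satisfied steps is reported
for incomplete modules.

Expression rollup sums the aggregated KO expression (TPM) of each module's
distinct leaf KOs.  A KO shared by several modules contributes fully to each of
them — module totals are therefore deliberately not a partition of the
transcriptome, and hierarchy-level sums can exceed the total expressed TPM.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DefinitionParseError",
    "Leaf",
    "OptionalPart",
    "Complex",
    "Alternative",
    "StepSequence",
    "parse_definition",
    "serialize",
    "leaf_kos",
    "is_satisfied",
    "evaluate_completeness",
    "ModuleProfile",
    "module_expression",
    "hierarchy_rollup",
    "pathway_expression",
    "taxon_split_expression",
    "ko_multiplicity",
]


class DefinitionParseError(ValueError):
    """Raised when a module definition string violates the grammar."""

    def __init__(self, message: str, position: int, module_id: str | None = None):
        self.position = position
        self.module_id = module_id
        prefix = f"module {module_id}: " if module_id else ""
        super().__init__(f"{prefix}{message} (at position {position})")


# ---------------------------------------------------------------------------
# AST node types


@dataclass(frozen=True)
class Leaf:
    ko: str


@dataclass(frozen=True)
class OptionalPart:
    """A '-'-marked component: never required, never counted as a step."""

    child: "Node"


@dataclass(frozen=True)
class Complex:
    parts: tuple


@dataclass(frozen=True)
class Alternative:
    options: tuple


@dataclass(frozen=True)
class StepSequence:
    steps: tuple


Node = Leaf | OptionalPart | Complex | Alternative | StepSequence

_ID_RE = re.compile(r"[A-Za-z0-9_.]+")


def _tokenize(s: str) -> list[tuple[str, str, int]]:
    """Return (kind, text, position) tokens. Kinds: id, op, lpar, rpar, sep."""
    tokens: list[tuple[str, str, int]] = []
    i = 0
    n = len(s)
    while i < n:
        c = s[i]
        if c == " ":
            j = i
            while j < n and s[j] == " ":
                j += 1
            tokens.append(("sep", " ", i))
            i = j
        elif c in "+-,":
            tokens.append(("op", c, i))
            i += 1
        elif c == "(":
            tokens.append(("lpar", c, i))
            i += 1
        elif c == ")":
            tokens.append(("rpar", c, i))
            i += 1
        else:
            m = _ID_RE.match(s, i)
            if not m:
                raise DefinitionParseError(f"unexpected character {c!r}", i)
            tokens.append(("id", m.group(), i))
            i = m.end()
    return tokens


class _Parser:
    def __init__(self, s: str, module_id: str | None = None):
        self.s = s
        self.module_id = module_id
        self.tokens = _tokenize(s)
        self.i = 0

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _error(self, message: str, position: int | None = None):
        if position is None:
            tok = self._peek()
            position = tok[2] if tok else len(self.s)
        raise DefinitionParseError(message, position, self.module_id)

    def parse(self) -> Node:
        if not self.tokens:
            self._error("empty definition", 0)
        node = self.parse_sequence()
        if self._peek() is not None:
            self._error(f"unexpected token {self._peek()[1]!r}")
        return node

    def parse_sequence(self) -> Node:
        steps = [self.parse_alternative()]
        while True:
            tok = self._peek()
            if tok is None or tok[0] != "sep":
                break
            self.i += 1
            if self._peek() is None or self._peek()[0] == "rpar":
                break  # trailing blank is harmless
            steps.append(self.parse_alternative())
        return steps[0] if len(steps) == 1 else StepSequence(tuple(steps))

    def parse_alternative(self) -> Node:
        options = [self.parse_complex()]
        while True:
            tok = self._peek()
            if tok is None or tok[1] != ",":
                break
            self.i += 1
            options.append(self.parse_complex())
        return options[0] if len(options) == 1 else Alternative(tuple(options))

    def parse_complex(self) -> Node:
        parts = [self.parse_unit()]
        while True:
            tok = self._peek()
            if tok is None or tok[0] != "op" or tok[1] not in "+-":
                break
            op = tok[1]
            self.i += 1
            child = self.parse_unit()
            parts.append(OptionalPart(child) if op == "-" else child)
        return parts[0] if len(parts) == 1 else Complex(tuple(parts))

    def parse_unit(self) -> Node:
        tok = self._peek()
        if tok is None:
            self._error("dangling operator at end of definition", len(self.s))
        kind, text, pos = tok
        if kind == "lpar":
            self.i += 1
            node = self.parse_sequence()
            closing = self._peek()
            if closing is None or closing[0] != "rpar":
                self._error("unbalanced parenthesis", pos)
            self.i += 1
            return node
        if kind == "id":
            self.i += 1
            return Leaf(text)
        self._error(f"unexpected token {text!r}", pos)


def parse_definition(s: str, module_id: str | None = None) -> Node:
    """Parse a module definition string into its expression tree.

    Raises :class:`DefinitionParseError` (with character position and, when
    given, the module id) on malformed input.
    """
    return _Parser(s, module_id).parse()


# ---------------------------------------------------------------------------
# Serialization (precedence-aware, minimal parentheses)


def serialize(node: Node) -> str:
    """Render an expression tree back to definition syntax.

    ``parse(serialize(parse(s)))`` is semantically identical to ``parse(s)``
    (same satisfying KO sets), though redundant parentheses in ``s`` are not
    preserved.
    """
    return _ser(node)


def _ser(node: Node) -> str:
    if isinstance(node, Leaf):
        return node.ko
    if isinstance(node, OptionalPart):
        # only meaningful inside a complex; standalone render as bare child
        return _ser_tight(node.child)
    if isinstance(node, Complex):
        out = [_ser_tight(node.parts[0])]
        for part in node.parts[1:]:
            if isinstance(part, OptionalPart):
                out.append("-" + _ser_tight(part.child))
            else:
                out.append("+" + _ser_tight(part))
        return "".join(out)
    if isinstance(node, Alternative):
        return ",".join(
            _ser(o) if not isinstance(o, (StepSequence, Alternative)) else f"({_ser(o)})"
            for o in node.options
        )
    if isinstance(node, StepSequence):
        return " ".join(
            _ser(s) if not isinstance(s, StepSequence) else f"({_ser(s)})"
            for s in node.steps
        )
    raise TypeError(f"not a definition node: {node!r}")


def _ser_tight(node: Node) -> str:
    # operand of + / - : parenthesize anything looser than a leaf
    return node.ko if isinstance(node, Leaf) else f"({_ser(node)})"


def leaf_kos(node: Node, include_optional: bool = True) -> list[str]:
    """Distinct leaf KO identifiers in first-appearance order."""
    seen: dict[str, None] = {}

    def walk(n: Node, under_opt: bool):
        if isinstance(n, Leaf):
            if include_optional or not under_opt:
                seen.setdefault(n.ko)
        elif isinstance(n, OptionalPart):
            walk(n.child, True)
        elif isinstance(n, Complex):
            for p in n.parts:
                walk(p, under_opt)
        elif isinstance(n, Alternative):
            for o in n.options:
                walk(o, under_opt)
        elif isinstance(n, StepSequence):
            for s in n.steps:
                walk(s, under_opt)

    walk(node, False)
    return list(seen)


# ---------------------------------------------------------------------------
# Completeness


def is_satisfied(node: Node, present: set[str] | frozenset[str]) -> bool:
    """Can this (sub)expression run given the KOs in ``present``?"""
    if isinstance(node, Leaf):
        return node.ko in present
    if isinstance(node, OptionalPart):
        return True
    if isinstance(node, Complex):
        return all(is_satisfied(p, present) for p in node.parts)
    if isinstance(node, Alternative):
        return any(is_satisfied(o, present) for o in node.options)
    if isinstance(node, StepSequence):
        return all(is_satisfied(s, present) for s in node.steps)
    raise TypeError(f"not a definition node: {node!r}")


def evaluate_completeness(
    node: Node, present: Iterable[str]
) -> tuple[bool, float]:
    """Evaluate a module against a set of present KOs.

    Returns ``(complete, fraction_of_steps_satisfied)``.  The steps counted are
    the top-level steps of the definition (a definition without a step
    separator is a single step); optional components are never counted.
    ``complete`` is True exactly when the fraction is 1.
    """
    present = frozenset(present)
    steps = node.steps if isinstance(node, StepSequence) else (node,)
    counted = [s for s in steps if not isinstance(s, OptionalPart)]
    if not counted:
        return True, 1.0
    satisfied = sum(is_satisfied(s, present) for s in counted)
    fraction = satisfied / len(counted)
    return satisfied == len(counted), fraction


def required_kos(node: Node) -> list[str]:
    """A KO set that is sufficient for completeness: all non-optional leaves.

    Not minimal (alternatives contribute every option) but guaranteed to
    satisfy the definition, which is what truth-planting needs.
    """
    return leaf_kos(node, include_optional=False)


# ---------------------------------------------------------------------------
# Expression rollup


@dataclass
class ModuleProfile:
    """Per-module expression, completeness, and hierarchy labels.

    Attributes
    ----------
    expression : DataFrame, modules x samples, TPM sums over distinct leaf KOs.
    atpm : Series, arithmetic mean of per-sample expression (the aTPM unit).
    complete : boolean Series per module.
    fraction_satisfied : Series, fraction of non-optional steps satisfied.
    hierarchy : DataFrame with ``name``, ``level_B``, ``level_C`` per module.
    """

    expression: pd.DataFrame
    atpm: pd.Series
    complete: pd.Series
    fraction_satisfied: pd.Series
    hierarchy: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        out = self.hierarchy.copy()
        out["atpm"] = self.atpm
        out["complete"] = self.complete
        out["fraction_satisfied"] = self.fraction_satisfied
        return out.join(self.expression)


def module_expression(
    ko_tpm: pd.DataFrame,
    catalog,
    presence_threshold: float = 0.0,
) -> ModuleProfile:
    """Roll KO expression up to modules and evaluate completeness.

    A KO is *present* when its TPM exceeds ``presence_threshold`` in at least
    one sample.  Each distinct leaf KO of a module contributes its full TPM to
    that module; KOs shared across modules count fully in every one.

    Parameters
    ----------
    ko_tpm : DataFrame, KO x samples aggregated TPM.
    catalog : ModuleCatalog (see :mod:`spongefunc.io_formats`).
    """
    present = set(ko_tpm.index[(ko_tpm > presence_threshold).any(axis=1)])
    rows = {}
    complete = {}
    fraction = {}
    for module_id, tree in catalog.trees.items():
        kos = leaf_kos(tree)
        rows[module_id] = (
            ko_tpm.reindex(kos).fillna(0.0).sum(axis=0)
        )
        ok, frac = evaluate_completeness(tree, present)
        complete[module_id] = ok
        fraction[module_id] = frac
    expression = pd.DataFrame(rows).T
    expression.index.name = "module_id"
    expression = expression.reindex(columns=ko_tpm.columns)
    hierarchy = catalog.entries.set_index("module_id")[["name", "level_B", "level_C"]]
    hierarchy = hierarchy.loc[expression.index]
    return ModuleProfile(
        expression=expression,
        atpm=expression.mean(axis=1),
        complete=pd.Series(complete).loc[expression.index],
        fraction_satisfied=pd.Series(fraction).loc[expression.index],
        hierarchy=hierarchy,
    )


def hierarchy_rollup(profile: ModuleProfile, level: str = "level_C") -> pd.DataFrame:
    """Sum module expression by a hierarchy level (``level_B`` or ``level_C``).

    Because KOs are shared between modules, these sums can exceed total TPM.
    """
    if level not in ("level_B", "level_C"):
        raise ValueError(f"unknown hierarchy level: {level!r}")
    labels = profile.hierarchy[level]
    return profile.expression.groupby(labels).sum()


def pathway_expression(ko_tpm: pd.DataFrame, pathways) -> pd.DataFrame:
    """Flat KO-membership rollup for pathways (no completeness grammar)."""
    rows = {}
    for entry in pathways.entries.itertuples():
        rows[entry.pathway_id] = (
            ko_tpm.reindex(list(entry.kos)).fillna(0.0).sum(axis=0)
        )
    out = pd.DataFrame(rows).T
    out.index.name = "pathway_id"
    return out.reindex(columns=ko_tpm.columns)


def taxon_split_expression(
    peptide_expression,
    annotation,
    catalog,
    rank: str = "phylum",
) -> pd.DataFrame:
    """Split module expression by the taxon of the contributing peptides.

    KO TPM is decomposed by the ``rank``-level taxon of each peptide before the
    module rollup; peptides with no lineage pool into ``unclassified``.  For
    every module the taxon shares sum exactly to the module total.

    Parameters
    ----------
    peptide_expression : PeptideExpression with the ``tpm`` matrix filled.
    annotation : OrfAnnotation supplying per-peptide KO and lineage.
    rank : lineage rank to split at (default phylum).

    Returns
    -------
    DataFrame indexed by (module_id, taxon) with sample columns.
    """
    from .io_formats import LINEAGE_RANKS

    if rank not in LINEAGE_RANKS:
        raise ValueError(f"unknown rank: {rank!r}")
    depth = LINEAGE_RANKS.index(rank)
    rec = annotation.records.set_index("peptide_id")
    tpm = peptide_expression.tpm
    if tpm is None:
        raise ValueError("peptide TPM not computed; run peptide_tpm first")

    def taxon_of(lineage) -> str:
        if not isinstance(lineage, str) or not lineage:
            return "unclassified"
        parts = lineage.split(";")
        return parts[depth] if depth < len(parts) and parts[depth] else "unclassified"

    info = rec.reindex(tpm.index)
    taxa = info["taxon"].map(taxon_of)
    kos = info["ko"]
    keep = kos.notna()
    ko_taxon = (
        tpm.loc[keep]
        .groupby([kos[keep], taxa[keep]])
        .sum()
    )
    ko_taxon.index.names = ["ko", "taxon"]

    rows = {}
    for module_id, tree in catalog.trees.items():
        kos_m = [k for k in leaf_kos(tree) if k in ko_taxon.index.get_level_values(0)]
        if not kos_m:
            continue
        sub = ko_taxon.loc[kos_m].groupby(level="taxon").sum()
        for taxon, row in sub.iterrows():
            rows[(module_id, taxon)] = row
    if not rows:
        return pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["module_id", "taxon"]),
            columns=tpm.columns,
        )
    out = pd.DataFrame(rows).T
    out.index.names = ["module_id", "taxon"]
    return out.reindex(columns=tpm.columns)


def ko_multiplicity(catalog, pathways=None) -> pd.DataFrame:
    """Count, per KO, how many modules (and optionally pathways) contain it.

    Returns a DataFrame with columns ``n_modules`` and ``n_pathways`` plus a
    ``multiplicity`` total; ``frac_multiple`` (fraction of KOs appearing in
    more than one container) is stored in ``DataFrame.attrs``.
    """
    counts_m: dict[str, int] = {}
    for tree in catalog.trees.values():
        for ko in leaf_kos(tree):
            counts_m[ko] = counts_m.get(ko, 0) + 1
    counts_p: dict[str, int] = {}
    if pathways is not None:
        for entry in pathways.entries.itertuples():
            for ko in dict.fromkeys(entry.kos):
                counts_p[ko] = counts_p.get(ko, 0) + 1
    kos = sorted(set(counts_m) | set(counts_p))
    out = pd.DataFrame(
        {
            "n_modules": [counts_m.get(k, 0) for k in kos],
            "n_pathways": [counts_p.get(k, 0) for k in kos],
        },
        index=pd.Index(kos, name="ko"),
    )
    out["multiplicity"] = out["n_modules"] + out["n_pathways"]
    out.attrs["frac_multiple"] = (
        float((out["multiplicity"] > 1).mean()) if len(out) else 0.0
    )
    return out
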