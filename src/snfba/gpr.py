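"""Boolean gene-protein-reaction (GPR) associations.

A GPR expression links genes to a reaction: ``and`` joins members of a
protein complex (all genes required), ``or`` joins isozymes (any gene
suffices). Expressions use gene ids, ``and`` / ``or`` (case-insensitive)
and parentheses; ``and`` binds tighter than ``or``.

A gene deletion sets that gene's literal to false everywhere; the reaction
stays enabled while its expression still evaluates true.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, Optional, Sequence, Set, Tuple, Union

__all__ = [
    "GprTree", "Gene", "And", "Or", "parse_gpr", "gpr_to_string",
    "evaluate_gpr", "gpr_genes", "reactions_disabled_by", "GprParseError",
]


class GprParseError(ValueError):
    """Malformed GPR expression; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Gene:
    """Leaf node: a single gene id."""
    gene: str


@dataclass(frozen=True)
class And:
    """Protein complex: every child must be available."""
    children: Tuple["GprTree", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("AND node needs >= 2 children")


@dataclass(frozen=True)
class Or:
    """Isozymes: any available child suffices."""
    children: Tuple["GprTree", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("OR node needs >= 2 children")


GprTree = Union[Gene, And, Or]


# -- parsing --------------------------------------------------------------

def _tokenize(text: str) -> List[Tuple[str, str, int]]:
    tokens: List[Tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append(("paren", ch, i))
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        word = text[i:j]
        low = word.lower()
        if low in ("and", "or"):
            tokens.append((low, word, i))
        else:
            tokens.append(("gene", word, i))
        i = j
    return tokens


class _Parser:
    """Recursive descent: expr := term (OR term)*; term := factor (AND factor)*."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is not None:
            self.pos += 1
        return tok

    def parse(self) -> GprTree:
        if not self.tokens:
            raise GprParseError("empty GPR expression", 0)
        tree = self.expr()
        tok = self.peek()
        if tok is not None:
            raise GprParseError(f"unexpected token {tok[1]!r}", tok[2])
        return tree

    def expr(self) -> GprTree:
        terms = [self.term()]
        while self.peek() is not None and self.peek()[0] == "or":
            self.next()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def term(self) -> GprTree:
        factors = [self.factor()]
        while self.peek() is not None and self.peek()[0] == "and":
            self.next()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def factor(self) -> GprTree:
        tok = self.next()
        if tok is None:
            raise GprParseError("empty operand", len(self.text))
        kind, value, pos = tok
        if kind == "gene":
            return Gene(value)
        if kind == "paren" and value == "(":
            try:
                inner = self.expr()
            except GprParseError:
                if self.peek() is None:  # input ended inside the group
                    raise GprParseError("unbalanced '('", pos) from None
                raise
            closing = self.next()
            if closing is None or closing[1] != ")":
                raise GprParseError("unbalanced '('", pos)
            return inner
        raise GprParseError(f"unexpected token {value!r}", pos)


def parse_gpr(text: str) -> GprTree:
    """Parse a GPR expression string into a tree.

    Raises :class:`GprParseError` (with character position) on unbalanced
    parentheses or empty operands.
    """
    return _Parser(text).parse()


def gpr_to_string(tree: GprTree, _parent: Optional[str] = None) -> str:
    """Serialise a tree back to an equivalent Boolean expression."""
    if isinstance(tree, Gene):
        return tree.gene
    op = "and" if isinstance(tree, And) else "or"
    inner = f" {op} ".join(gpr_to_string(c, op) for c in tree.children)
    # OR under AND must keep its parentheses; AND under OR keeps them too,
    # purely for readability (precedence would already be correct).
    if _parent is not None and _parent != op:
        return f"({inner})"
    return inner


def gpr_genes(tree: GprTree) -> FrozenSet[str]:
    if isinstance(tree, Gene):
        return frozenset((tree.gene,))
    out: Set[str] = set()
    for child in tree.children:
        out |= gpr_genes(child)
    return frozenset(out)


def evaluate_gpr(tree: GprTree, deleted: Set[str]) -> bool:
    """True iff the reaction remains enabled with ``deleted`` genes absent."""
    if isinstance(tree, Gene):
        return tree.gene not in deleted
    if isinstance(tree, And):
        return all(evaluate_gpr(c, deleted) for c in tree.children)
    return any(evaluate_gpr(c, deleted) for c in tree.children)


def reactions_disabled_by(model, deleted: Set[str]) -> Set[str]:
    """Reaction ids whose GPR evaluates false once ``deleted`` genes are gone.

    Reactions without a GPR are never disabled. Unknown gene ids raise
    ``KeyError`` to guard deletion screens against typos.
    """
    deleted = set(deleted)
    unknown = deleted - set(model.genes)
    if unknown:
        raise KeyError(
            f"unknown gene id(s) {sorted(unknown)} not in model {model.id!r}")
    disabled = set()
    for rxn in model.reactions:
        if rxn.gpr is not None and not evaluate_gpr(rxn.gpr, deleted):
            disabled.add(rxn.id)
    return disabled
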