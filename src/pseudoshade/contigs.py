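"""Contig extraction by color profile, length filtering, and Jaccard similarity.

A *contig* is a unitig, or a contiguous substring of a unitig, all of whose
k-mers share one color profile.  Monochromatic contigs (profile = a single
color) are sequence unique to one input; for two inputs differing by one
isolated substitution, the unique contig has length exactly 2k-1 — the
k-mers overlapping the variant base plus its conserved flanks.  At k=31 that
is 61 bp, which is why exact-61-bp filtering selects SNP contigs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .graph import ColoredGraph, Unitig, _canon, compact, reverse_complement

_TOKEN = re.compile(r"\s*(\(|\)|&+|\|+|!|AND\b|OR\b|NOT\b|[\w.:+-]+)", re.IGNORECASE)


@dataclass(frozen=True)
class Contig:
    """A maximal constant-color-profile run within a unitig."""

    sequence: str
    profile: frozenset

    def __len__(self) -> int:
        return len(self.sequence)


class ColorQuery:
    """Boolean expression over color labels, with optional exact-set semantics.

    The expression grammar supports ``&``/``AND``, ``|``/``OR``, ``!``/``NOT``
    and parentheses; atoms are color labels (file names) or integer color
    indices.  With ``exact=True`` a profile matches iff it *equals* the set of
    non-negated labels in the expression; otherwise the expression is
    evaluated with each label true iff its color is in the profile
    ("at least these colors" semantics for a plain conjunction).
    """

    def __init__(self, expression: str, exact: bool = False):
        self.expression = expression
        self.exact = exact
        self._ast, self._positives = self._parse(expression)

    @classmethod
    def exactly(cls, labels) -> "ColorQuery":
        return cls(" & ".join(str(c) for c in labels), exact=True)

    # -- tiny recursive-descent parser -> nested tuples ---------------------

    @staticmethod
    def _tokenize(expr: str) -> list[str]:
        tokens, pos = [], 0
        while pos < len(expr):
            m = _TOKEN.match(expr, pos)
            if not m:
                if expr[pos:].strip():
                    raise ValueError(f"cannot parse color query at: {expr[pos:]!r}")
                break
            tok = m.group(1)
            up = tok.upper()
            if up in ("AND",) or set(tok) == {"&"}:
                tok = "&"
            elif up in ("OR",) or set(tok) == {"|"}:
                tok = "|"
            elif up == "NOT" or tok == "!":
                tok = "!"
            tokens.append(tok)
            pos = m.end()
        return tokens

    def _parse(self, expr: str):
        tokens = self._tokenize(expr)
        if not tokens:
            raise ValueError("empty color query")
        positives: set[str] = set()
        pos = 0

        def peek():
            return tokens[pos] if pos < len(tokens) else None

        def take(expected=None):
            nonlocal pos
            tok = peek()
            if tok is None or (expected and tok != expected):
                raise ValueError(f"malformed color query: {expr!r}")
            pos += 1
            return tok

        def parse_or():
            node = parse_and()
            while peek() == "|":
                take("|")
                node = ("or", node, parse_and())
            return node

        def parse_and():
            node = parse_not()
            while peek() == "&":
                take("&")
                node = ("and", node, parse_not())
            return node

        def parse_not(negated=False):
            tok = peek()
            if tok == "!":
                take("!")
                return ("not", parse_not(negated=not negated))
            if tok == "(":
                take("(")
                node = parse_or()
                take(")")
                return node
            name = take()
            if name in ("&", "|", ")"):
                raise ValueError(f"malformed color query: {expr!r}")
            if not negated:
                positives.add(name)
            return ("name", name)

        ast = parse_or()
        if pos != len(tokens):
            raise ValueError(f"trailing tokens in color query: {expr!r}")
        return ast, positives

    # -- evaluation ----------------------------------------------------------

    def resolve(self, graph: ColoredGraph) -> "ResolvedQuery":
        positives = frozenset(graph.color_index(_maybe_int(n)) for n in self._positives)
        return ResolvedQuery(self, graph, positives)


def _maybe_int(tok: str):
    return int(tok) if tok.lstrip("-").isdigit() else tok


class ResolvedQuery:
    def __init__(self, query: ColorQuery, graph: ColoredGraph, positives: frozenset):
        self.query = query
        self.graph = graph
        self.positives = positives

    def matches(self, profile: frozenset) -> bool:
        canon = frozenset(c for c in profile if isinstance(c, int))
        if self.query.exact:
            return canon == self.positives
        return self._eval(self.query._ast, canon)

    def _eval(self, node, profile) -> bool:
        op = node[0]
        if op == "name":
            return self.graph.color_index(_maybe_int(node[1])) in profile
        if op == "not":
            return not self._eval(node[1], profile)
        if op == "and":
            return self._eval(node[1], profile) and self._eval(node[2], profile)
        return self._eval(node[1], profile) or self._eval(node[2], profile)


def contig_profile_runs(graph: ColoredGraph, unitig: Unitig) -> list[Contig]:
    """Split one unitig into maximal runs of k-mers sharing a color profile."""
    k = graph.k
    seq = unitig.sequence
    n = len(seq) - k + 1
    runs: list[Contig] = []
    start = 0
    prev = frozenset(graph.table[_canon(seq[0:k])])
    for i in range(1, n):
        prof = frozenset(graph.table[_canon(seq[i : i + k])])
        if prof != prev:
            runs.append(_make_contig(seq[start : i - 1 + k], prev))
            start, prev = i, prof
    runs.append(_make_contig(seq[start : n - 1 + k], prev))
    return runs


def _make_contig(seq: str, profile: frozenset) -> Contig:
    rc = reverse_complement(seq)
    return Contig(sequence=min(seq, rc), profile=profile)


def extract_contigs(graph: ColoredGraph, query: ColorQuery) -> list[Contig]:
    """All maximal constant-profile runs (within unitigs) matching ``query``.

    Contig sequences are reported in canonical orientation and sorted, so
    output is deterministic.
    """
    resolved = query.resolve(graph)
    out = []
    for unitig in compact(graph):
        for contig in contig_profile_runs(graph, unitig):
            if resolved.matches(contig.profile):
                out.append(contig)
    return sorted(out, key=lambda c: c.sequence)


def filter_by_length(contigs: list[Contig], length: int) -> list[Contig]:
    """Keep contigs whose length equals ``length`` exactly (the SNP rule:
    2k-1, i.e. 61 bp at k=31)."""
    return [c for c in contigs if len(c.sequence) == length]


def jaccard(graph: ColoredGraph, color_a: str | int, color_b: str | int) -> float:
    """Jaccard index of the two colors' canonical k-mer sets (0/0 -> 0)."""
    ia, ib = graph.color_index(color_a), graph.color_index(color_b)
    inter = union = 0
    for colors in graph.table.values():
        has_a, has_b = ia in colors, ib in colors
        if has_a and has_b:
            inter += 1
        if has_a or has_b:
            union += 1
    return inter / union if union else 0.0


def jaccard_matrix(graph: ColoredGraph):
    """All-pairs Jaccard as a pandas DataFrame (colors x colors)."""
    import pandas as pd

    n = graph.n_colors
    mat = [[jaccard(graph, i, j) for j in range(n)] for i in range(n)]
    return pd.DataFrame(mat, index=graph.color_names, columns=graph.color_names)


def write_contigs_fasta(path: str | Path, contigs: list[Contig],
                        graph: ColoredGraph) -> None:
    """Write contigs with headers encoding the color profile."""
    with open(path, "w") as fh:
        for serial, contig in enumerate(contigs):
            labels = ",".join(
                graph.color_names[c] for c in sorted(
                    c for c in contig.profile if isinstance(c, int))
            )
            fh.write(f">contig_{serial} colors={labels}\n{contig.sequence}\n")
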