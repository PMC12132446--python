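"""Colored de Bruijn graph over canonical k-mers.

The graph ``G = (V, E, C)`` maps each canonical k-mer (the lexicographic
minimum of a k-mer and its reverse complement) to the set of colors — input
files, or later reference targets — in which it occurs.  Edges are implicit:
``(v, w)`` exists whenever a (k-1)-suffix of one k-mer (in some orientation)
equals a (k-1)-prefix of the other (bidirected convention).  Odd k is
enforced so no k-mer equals its own reverse complement.

Colors are small integers indexing ``color_names``; after shading (see
:mod:`pseudoshade.ornament`) color sets may additionally contain string shade
identifiers.  Only presence/absence per color is stored, not multiplicity.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from . import io as psio

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT_SPLIT = re.compile(r"[^ACGT]+")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(seq: str) -> str:
    """Canonical (strand-agnostic) form of a k-mer: min(seq, revcomp(seq)).

    Raises ``ValueError`` for non-ACGT characters or even length (an even-k
    k-mer can be its own reverse complement, making canonicalization
    ambiguous).
    """
    if len(seq) % 2 == 0:
        raise ValueError(f"k must be odd, got k={len(seq)}")
    if _ACGT_SPLIT.search(seq):
        raise ValueError(f"k-mer contains non-ACGT characters: {seq!r}")
    rc = seq.translate(_COMPLEMENT)[::-1]
    return seq if seq <= rc else rc


def _canon(seq: str) -> str:
    # Internal fast path: no validation.
    rc = seq.translate(_COMPLEMENT)[::-1]
    return seq if seq <= rc else rc


def iter_canonical_kmers(seq: str, k: int) -> Iterator[str]:
    """Canonical k-mers of ``seq``, splitting at non-ACGT characters."""
    for frag in _ACGT_SPLIT.split(seq.upper()):
        for i in range(len(frag) - k + 1):
            yield _canon(frag[i : i + k])


@dataclass
class Unitig:
    """A maximal non-branching path, spelled as one sequence (length >= k)."""

    sequence: str

    def kmer_count(self, k: int) -> int:
        return len(self.sequence) - k + 1


@dataclass
class ColoredGraph:
    k: int
    color_names: list[str]
    table: dict[str, set] = field(default_factory=dict)

    @property
    def n_colors(self) -> int:
        return len(self.color_names)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.table

    def __len__(self) -> int:
        return len(self.table)

    def colors_of(self, kmer: str) -> set:
        return self.table[kmer]

    def color_index(self, label: str | int) -> int:
        if isinstance(label, int):
            if not 0 <= label < self.n_colors:
                raise KeyError(f"color index {label} out of range")
            return label
        try:
            return self.color_names.index(label)
        except ValueError:
            raise KeyError(f"unknown color {label!r}") from None

    def add_sequence(self, seq: str, color: int) -> None:
        for kmer in iter_canonical_kmers(seq, self.k):
            self.table.setdefault(kmer, set()).add(color)

    def kmers_with_color(self, color: int) -> set[str]:
        return {x for x, cs in self.table.items() if color in cs}

    # -- serialization: one-line JSON header, then "kmer TAB color,color" ----

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"k": self.k, "color_names": self.color_names}) + "\n")
            for kmer in sorted(self.table):
                toks = sorted(self.table[kmer], key=lambda c: (isinstance(c, str), c))
                fh.write(kmer + "\t" + ",".join(str(c) for c in toks) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ColoredGraph":
        with open(path) as fh:
            header = json.loads(fh.readline())
            graph = cls(k=header["k"], color_names=header["color_names"])
            for line in fh:
                kmer, _, colors = line.rstrip("\n").partition("\t")
                graph.table[kmer] = {
                    int(tok) if tok.lstrip("-").isdigit() else tok
                    for tok in colors.split(",")
                }
        return graph


def build_graph(files: Iterable[str | Path], k: int) -> ColoredGraph:
    """Build a colored de Bruijn graph; each input file gets one color.

    A k-mer carries color ``i`` iff it occurs, in either orientation, in file
    ``i``.  Sequences are split at non-ACGT characters before k-mer
    extraction.
    """
    files = [Path(f) for f in files]
    if not files:
        raise ValueError("at least one input file is required")
    if k % 2 == 0 or not 1 < k <= 63:
        raise ValueError(f"k must be odd and in (1, 63], got {k}")
    graph = ColoredGraph(k=k, color_names=[f.name for f in files])
    for color, path in enumerate(files):
        n_records = 0
        try:
            for _, seq in psio.read_sequences(path):
                n_records += 1
                graph.add_sequence(seq, color)
        except (OSError, ValueError) as exc:
            raise ValueError(f"cannot read sequence file {path}: {exc}") from exc
        if n_records == 0:
            raise ValueError(f"sequence file {path} contains no records")
    return graph


def build_graph_from_records(record_sets: list[list[tuple[str, str]]], k: int,
                             color_names: list[str] | None = None) -> ColoredGraph:
    """Like :func:`build_graph` but from in-memory ``(name, seq)`` record lists."""
    if k % 2 == 0 or not 1 < k <= 63:
        raise ValueError(f"k must be odd and in (1, 63], got {k}")
    names = color_names or [f"color{i}" for i in range(len(record_sets))]
    graph = ColoredGraph(k=k, color_names=list(names))
    for color, records in enumerate(record_sets):
        for _, seq in records:
            graph.add_sequence(seq, color)
    return graph


def _forward_extensions(graph: ColoredGraph, oriented: str) -> list[str]:
    suffix = oriented[1:]
    out = []
    for base in "ACGT":
        nxt = suffix + base
        if _canon(nxt) in graph.table:
            out.append(nxt)
    return out


def _backward_extensions(graph: ColoredGraph, oriented: str) -> list[str]:
    prefix = oriented[:-1]
    out = []
    for base in "ACGT":
        prv = base + prefix
        if _canon(prv) in graph.table:
            out.append(prv)
    return out


def compact(graph: ColoredGraph) -> list[Unitig]:
    """Compact the graph into unitigs (maximal non-branching paths).

    Maximality is judged on the union (color-blind) bidirected graph: color
    changes do not break unitigs.  Self-loop edges (an extension whose
    canonical k-mer equals the current vertex) do not count toward branching.
    Every canonical k-mer of the graph is spelled by exactly one unitig.
    """
    visited: set[str] = set()
    unitigs: list[Unitig] = []
    for start in sorted(graph.table):
        if start in visited:
            continue
        visited.add(start)
        seq = start
        # extend to the right
        cur = start
        while True:
            outs = [s for s in _forward_extensions(graph, cur) if _canon(s) != _canon(cur)]
            if len(outs) != 1:
                break
            nxt = outs[0]
            nxt_canon = _canon(nxt)
            if nxt_canon in visited:
                break
            back = [s for s in _backward_extensions(graph, nxt) if _canon(s) != nxt_canon]
            if len(back) != 1:
                break
            seq += nxt[-1]
            visited.add(nxt_canon)
            cur = nxt
        # extend to the left
        cur = start
        while True:
            ins = [s for s in _backward_extensions(graph, cur) if _canon(s) != _canon(cur)]
            if len(ins) != 1:
                break
            prv = ins[0]
            prv_canon = _canon(prv)
            if prv_canon in visited:
                break
            fwd = [s for s in _forward_extensions(graph, prv) if _canon(s) != prv_canon]
            if len(fwd) != 1:
                break
            seq = prv[0] + seq
            visited.add(prv_canon)
            cur = prv
        unitigs.append(Unitig(sequence=seq))
    return unitigs
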