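"""Ornamental de Bruijn graph: reference targets plus variant shades.

A *shade* is an auxiliary color minted for one (variant contig, reference
target) pair.  The parent function pi maps each shade to exactly one
canonical target color, and the structure maintains *parent inclusion*: a
shade never appears on a k-mer without its parent color.  Variant contigs
are mapped to targets by sharing at least one canonical k-mer at a smaller
inner order ``k_map`` (default 29 under k=31 contigs), so SNP contigs attach
to the reference allele via their conserved flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from . import io as psio
from .contigs import Contig
from .graph import ColoredGraph, iter_canonical_kmers


class KmerTargetIndex:
    """Inverted index: canonical k_map-mer -> set of target color indices."""

    def __init__(self, targets: list[tuple[str, str]], k_map: int):
        if k_map % 2 == 0:
            raise ValueError(f"k_map must be odd, got {k_map}")
        self.k_map = k_map
        self.target_names = [name for name, _ in targets]
        self.index: dict[str, set[int]] = {}
        for tid, (_, seq) in enumerate(targets):
            for kmer in iter_canonical_kmers(seq, k_map):
                self.index.setdefault(kmer, set()).add(tid)


def map_contig_to_targets(contig: Contig | str, index: KmerTargetIndex) -> list[int]:
    """Target indices sharing >= 1 canonical ``k_map``-mer with the contig.

    A contig shorter than ``k_map`` maps nowhere (empty list, not an error).
    Output is sorted for determinism.
    """
    seq = contig.sequence if isinstance(contig, Contig) else contig
    hits: set[int] = set()
    for kmer in iter_canonical_kmers(seq, index.k_map):
        hits.update(index.index.get(kmer, ()))
    return sorted(hits)


@dataclass
class ShadeRegistry:
    """Shade identifiers with the parent function pi: S -> [n].

    Shade ids are strings ``<target_id>::shade<j>`` so the parent is
    recoverable by eye, but this mapping stays authoritative.
    """

    parent: dict[str, int] = field(default_factory=dict)
    provenance: dict[str, tuple[str, str]] = field(default_factory=dict)
    _per_target_serial: dict[int, int] = field(default_factory=dict)

    @property
    def shades(self) -> set[str]:
        return set(self.parent)

    def new_shade(self, parent_color: int, target_name: str, contig_id: str) -> str:
        serial = self._per_target_serial.get(parent_color, 0)
        self._per_target_serial[parent_color] = serial + 1
        shade = f"{target_name}::shade{serial}"
        self.parent[shade] = parent_color
        self.provenance[shade] = (contig_id, target_name)
        return shade

    def pi(self, shade: str) -> int:
        return self.parent[shade]


@dataclass
class OrnamentalGraph:
    """A colored graph whose color sets may include shades, plus the frozen
    pre-shade graph (``original``) used by the shade-insertion rule."""

    graph: ColoredGraph
    registry: ShadeRegistry
    original: dict[str, frozenset]
    unmapped_contigs: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.graph.k

    @property
    def n_colors(self) -> int:
        return self.graph.n_colors

    @property
    def target_names(self) -> list[str]:
        return self.graph.color_names

    def check_parent_inclusion(self) -> bool:
        """Verify the invariant: a shade never appears without its parent."""
        for colors in self.graph.table.values():
            for c in colors:
                if isinstance(c, str) and self.registry.pi(c) not in colors:
                    return False
        return True


def add_shade(orn: OrnamentalGraph, contig_kmers: Iterable[str], shade: str) -> OrnamentalGraph:
    """Insert a contig's k-mers under ``shade``, preserving parent inclusion.

    Per k-mer x:
      * x in the original graph, parent already a color of x  -> unchanged
        (the k-mer is reference sequence of the parent; no shade needed);
      * x in the original graph, parent absent                -> add both the
        parent color and the shade;
      * x novel                                               -> new vertex
        carrying the parent color and the shade.

    Idempotent: re-adding the same contig under the same shade is a no-op.
    """
    if shade not in orn.registry.parent:
        raise KeyError(f"shade {shade!r} is not registered")
    parent = orn.registry.pi(shade)
    table = orn.graph.table
    for x in contig_kmers:
        if x in orn.original:
            if parent not in orn.original[x]:
                table[x].update((parent, shade))
        else:
            table.setdefault(x, set()).update((parent, shade))
    return orn


def ornament_index(
    variant_contigs: str | Path | list[tuple[str, str]],
    targets: str | Path | list[tuple[str, str]],
    k: int = 31,
    k_map: int = 29,
    max_targets: int | None = None,
) -> OrnamentalGraph:
    """Build the shaded reference graph.

    The reference graph is built at order ``k`` with one canonical color per
    target sequence; each contig is mapped to targets at the smaller order
    ``k_map`` and, per mapped target, gets its own shade whose k-mers (at
    order ``k``) are inserted by :func:`add_shade`.  Contigs mapping to no
    target are recorded in ``unmapped_contigs`` and skipped.
    """
    target_records = _as_records(targets)
    contig_records = _as_records(variant_contigs)
    if not target_records:
        raise ValueError("targets file contains no sequences")
    graph = ColoredGraph(k=k, color_names=[name for name, _ in target_records])
    for tid, (_, seq) in enumerate(target_records):
        graph.add_sequence(seq, tid)
    original = {x: frozenset(cs) for x, cs in graph.table.items()}
    orn = OrnamentalGraph(graph=graph, registry=ShadeRegistry(), original=original)

    index = KmerTargetIndex(target_records, k_map)
    for contig_id, seq in contig_records:
        hit_targets = map_contig_to_targets(seq, index)
        if max_targets is not None and len(hit_targets) > max_targets:
            hit_targets = hit_targets[:max_targets]
        if not hit_targets:
            orn.unmapped_contigs.append(contig_id)
            continue
        kmers = set(iter_canonical_kmers(seq, k))
        for tid in hit_targets:
            shade = orn.registry.new_shade(tid, target_records[tid][0], contig_id)
            add_shade(orn, kmers, shade)
    return orn


def plain_index(targets: str | Path | list[tuple[str, str]], k: int = 31) -> OrnamentalGraph:
    """An ornamental graph with no shades (standard pseudoalignment index)."""
    return ornament_index([], targets, k=k)


def _as_records(source) -> list[tuple[str, str]]:
    if isinstance(source, (str, Path)):
        return list(psio.read_sequences(source))
    return [(name, seq.upper()) for name, seq in source]
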