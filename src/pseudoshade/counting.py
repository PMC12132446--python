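"""Shade-aware pseudoalignment and single-cell UMI counting.

A read's equivalence class (EC) is the intersection of the canonical
(target) colors over its graph-present k-mers, unioned with every shade
seen on those k-mers whose parent survives the intersection.  Reads are
counted per (barcode, UMI, EC) triple — deduplicating UMIs converts reads
into molecule counts — yielding a sparse cell-by-EC matrix (transcript
compatibility counts).

By default k-mers absent from the graph (sequencing errors, uncovered
sequence) are skipped; ``literal=True`` intersects over *all* read k-mers,
so any novel k-mer unmaps the read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import scipy.sparse as sp

from . import io as psio
from .graph import iter_canonical_kmers
from .ornament import OrnamentalGraph


@dataclass(frozen=True)
class EquivalenceClass:
    canon: frozenset
    shades: frozenset

    def key(self) -> tuple:
        return (tuple(sorted(self.canon)), tuple(sorted(self.shades)))


class ECRegistry:
    """Assigns serial ids to equivalence classes in first-seen order."""

    def __init__(self):
        self._ids: dict[tuple, int] = {}
        self.classes: list[EquivalenceClass] = []

    def __len__(self) -> int:
        return len(self.classes)

    def get_id(self, ec: EquivalenceClass) -> int:
        key = ec.key()
        if key not in self._ids:
            self._ids[key] = len(self.classes)
            self.classes.append(ec)
        return self._ids[key]


def assign_equivalence_class(
    read: str, orn: OrnamentalGraph, literal: bool = False
) -> EquivalenceClass | None:
    """Pseudoalign one read; ``None`` means unmapped.

    Canonical colors are intersected across the read's k-mers; shades are
    unioned and kept only when their parent color is in the intersection.
    """
    k = orn.k
    if len(read) < k:
        return None
    table = orn.graph.table
    canon: set | None = None
    shades: set = set()
    any_present = False
    for kmer in iter_canonical_kmers(read, k):
        colors = table.get(kmer)
        if colors is None:
            if literal:
                return None
            continue
        any_present = True
        kmer_canon = set()
        for c in colors:
            if isinstance(c, int):
                kmer_canon.add(c)
            else:
                shades.add(c)
        canon = kmer_canon if canon is None else (canon & kmer_canon)
        if not canon:
            return None
    if not any_present or not canon:
        return None
    pi = orn.registry.parent
    valid_shades = frozenset(s for s in shades if pi[s] in canon)
    return EquivalenceClass(canon=frozenset(canon), shades=valid_shades)


@dataclass
class CellEcMatrix:
    """Sparse cell-by-EC matrix of deduplicated UMI counts."""

    barcodes: list[str]
    registry: ECRegistry
    counts: sp.csr_matrix
    color_names: list[str]
    qc: dict = field(default_factory=dict)

    @property
    def ecs(self) -> list[EquivalenceClass]:
        return self.registry.classes

    def presence(self) -> sp.csr_matrix:
        """Boolean cell-by-EC matrix: count >= 1."""
        return (self.counts > 0).tocsr()

    def cells_with_ec(self, ec_id: int) -> int:
        return int((self.counts[:, ec_id] > 0).sum())

    # -- on-disk layout: matrix.mtx + barcodes.tsv + ec.tsv ------------------

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from scipy.io import mmwrite

        mmwrite(str(outdir / "matrix.mtx"), self.counts.tocoo())
        (outdir / "barcodes.tsv").write_text("".join(b + "\n" for b in self.barcodes))
        with open(outdir / "ec.tsv", "w") as fh:
            for ec_id, ec in enumerate(self.ecs):
                canon = ":".join(str(c) for c in sorted(ec.canon))
                shades = ":".join(sorted(ec.shades))
                fh.write(f"{ec_id}\t{canon}\t{shades}\n")
        (outdir / "colors.tsv").write_text(
            "".join(f"{i}\t{n}\n" for i, n in enumerate(self.color_names))
        )


def make_cell_ec_matrix(
    triples: Iterable[tuple[str, str, int]],
    registry: ECRegistry,
    color_names: list[str],
    qc: dict | None = None,
) -> CellEcMatrix:
    """Assemble the matrix from unique (barcode, UMI, EC id) triples."""
    unique = set(triples)
    barcodes = sorted({bc for bc, _, _ in unique})
    bc_index = {bc: i for i, bc in enumerate(barcodes)}
    rows, cols = [], []
    for bc, _, ec_id in unique:
        rows.append(bc_index[bc])
        cols.append(ec_id)
    counts = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(barcodes), max(len(registry), 1)),
    ).tocsr()
    return CellEcMatrix(
        barcodes=barcodes,
        registry=registry,
        counts=counts,
        color_names=list(color_names),
        qc=qc or {},
    )


def count_cells(
    reads: Iterable[tuple[str, str, str]],
    orn: OrnamentalGraph,
    literal: bool = False,
) -> CellEcMatrix:
    """Count (barcode, UMI, cDNA) records into a cell-by-EC matrix.

    Each distinct (barcode, UMI, EC) triple contributes one count; unmapped
    reads are dropped.  Malformed records (empty barcode/UMI/sequence) are
    skipped and tallied in the QC summary.
    """
    registry = ECRegistry()
    triples: set[tuple[str, str, int]] = set()
    qc = {"n_reads": 0, "n_unmapped": 0, "n_malformed": 0}
    for rec in reads:
        qc["n_reads"] += 1
        try:
            barcode, umi, seq = rec
        except (TypeError, ValueError):
            qc["n_malformed"] += 1
            continue
        if not barcode or not umi or not seq:
            qc["n_malformed"] += 1
            continue
        ec = assign_equivalence_class(seq, orn, literal=literal)
        if ec is None:
            qc["n_unmapped"] += 1
            continue
        triples.add((barcode, umi, registry.get_id(ec)))
    return make_cell_ec_matrix(triples, registry, orn.target_names, qc)


# -- read layouts ------------------------------------------------------------

def iter_barcoded_reads(
    r1: str | Path,
    r2: str | Path | None = None,
    technology: str = "10xv2",
) -> Iterator[tuple[str, str, str]]:
    """Yield (barcode, UMI, cDNA) from FASTQ input.

    ``10xv2``: 16-bp barcode + 10-bp UMI at the start of R1, cDNA from R2.
    ``header``: barcode and UMI are the last two ``_``-separated fields of
    the read name; the read's own sequence is the cDNA (fixture layout).
    """
    if technology == "10xv2":
        if r2 is None:
            raise ValueError("technology 10xv2 requires a paired R2 file")
        for (_, seq1), (_, seq2) in zip(
            psio.read_sequences(r1), psio.read_sequences(r2), strict=True
        ):
            yield seq1[:16], seq1[16:26], seq2
    elif technology == "header":
        for name, seq in psio.read_sequences(r1):
            parts = name.split("_")
            if len(parts) < 3:
                yield ("", "", seq)  # malformed; counted by count_cells
            else:
                yield parts[-2], parts[-1], seq
    else:
        raise ValueError(f"unknown technology {technology!r}")


# -- strain demultiplexing ---------------------------------------------------

def demultiplex(
    matrix: CellEcMatrix, color_groups: dict
) -> dict[str, str]:
    """Assign each barcode to a strain by argmax of informative UMI counts.

    ``color_groups`` maps every canonical color (index or name) to a strain
    label.  An EC is informative for a strain when all its canonical colors
    belong to that strain's group; UMIs of ECs spanning strains are ignored.
    Exact ties and zero totals give ``"ambiguous"``.
    """
    idx_group: dict[int, str] = {}
    for color, group in color_groups.items():
        if isinstance(color, int):
            idx = color
            if not 0 <= idx < len(matrix.color_names):
                raise KeyError(f"color index {color} out of range")
        else:
            try:
                idx = matrix.color_names.index(color)
            except ValueError:
                raise KeyError(f"unknown color {color!r}") from None
        idx_group[idx] = group
    missing = set(range(len(matrix.color_names))) - set(idx_group)
    if missing:
        raise KeyError(f"colors without a strain group: {sorted(missing)}")

    ec_strain: list[str | None] = []
    for ec in matrix.ecs:
        groups = {idx_group[c] for c in ec.canon}
        ec_strain.append(groups.pop() if len(groups) == 1 else None)

    strains = sorted(set(idx_group.values()))
    totals = np.zeros((len(matrix.barcodes), len(strains)), dtype=np.int64)
    coo = matrix.counts.tocoo()
    strain_pos = {s: j for j, s in enumerate(strains)}
    for i, j, v in zip(coo.row, coo.col, coo.data):
        s = ec_strain[j]
        if s is not None:
            totals[i, strain_pos[s]] += v

    out: dict[str, str] = {}
    for i, bc in enumerate(matrix.barcodes):
        row = totals[i]
        best = row.max()
        if best == 0 or (row == best).sum() > 1:
            out[bc] = "ambiguous"
        else:
            out[bc] = strains[int(row.argmax())]
    return out


def informative_umis(matrix: CellEcMatrix, color_groups: dict) -> dict[str, int]:
    """Per-barcode count of UMIs attributable to a single strain."""
    idx_group = {}
    for color, group in color_groups.items():
        idx = color if isinstance(color, int) else matrix.color_names.index(color)
        idx_group[idx] = group
    ec_informative = [
        len({idx_group.get(c) for c in ec.canon}) == 1 for ec in matrix.ecs
    ]
    coo = matrix.counts.tocoo()
    out = {bc: 0 for bc in matrix.barcodes}
    for i, j, v in zip(coo.row, coo.col, coo.data):
        if ec_informative[j]:
            out[matrix.barcodes[i]] += int(v)
    return out
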