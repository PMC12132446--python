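"""Cluster-specificity testing of shade-containing equivalence classes.

For each testable shade EC and each cell cluster a 2x2 presence table is
built::

                       in cluster   outside cluster
    shade EC (gene g)      a              b
    regular ECs of g       c              d

where a..d count *cells* with at least one UMI, not UMIs.  Specificity is
the odds ratio ad/bc; significance is a two-sided Fisher exact test, with
Benjamini-Hochberg adjustment across all (EC, cluster) tests in a run.

``fisher_exact`` here enumerates the hypergeometric distribution in exact
integer arithmetic (two-sided by the minimum-likelihood rule), so there are
no floating-point tie ambiguities; results are cached per margin triple.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .counting import CellEcMatrix
from .ornament import ShadeRegistry

logger = logging.getLogger(__name__)


class ContingencyTable(NamedTuple):
    a: int
    b: int
    c: int
    d: int


def odds_ratio(t: ContingencyTable) -> float:
    """ad/bc with boundary sentinels: +inf when bc=0 < ad, NaN when both are 0."""
    a, b, c, d = t
    ad, bc = a * d, b * c
    if bc == 0:
        return math.inf if ad > 0 else math.nan
    return ad / bc


def haldane_anscombe_or(t: ContingencyTable) -> float:
    """+0.5-smoothed odds ratio, for plotting only (never used in tests)."""
    a, b, c, d = t
    return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))


@lru_cache(maxsize=None)
def _hypergeom_weights(n_total: int, row1: int, col1: int) -> tuple[int, list[int], int]:
    """Integer hypergeometric weights over the support of table cell ``a``.

    Returns (a_min, weights, total) with weight[i] = C(row1, a) * C(n-row1,
    col1-a) for a = a_min + i; total = C(n_total, col1).
    """
    a_min = max(0, col1 - (n_total - row1))
    a_max = min(row1, col1)
    weights = [
        math.comb(row1, a) * math.comb(n_total - row1, col1 - a)
        for a in range(a_min, a_max + 1)
    ]
    return a_min, weights, math.comb(n_total, col1)


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    tables with the observed margins no more probable than the observed one.

    Computed in exact integer arithmetic, so equal-probability ties are
    exact, not float-approximate.
    """
    a, b, c, d = t
    n_total = a + b + c + d
    if n_total == 0:
        return 1.0
    a_min, weights, total = _hypergeom_weights(n_total, a + b, a + c)
    observed = weights[a - a_min]
    return sum(w for w in weights if w <= observed) / total


@dataclass
class ShadeTestResult:
    ec_id: int
    gene: str
    cluster: str
    table: ContingencyTable
    odds_ratio: float
    p: float
    p_adj: float = math.nan


def _is_pseudogene(biotype: str) -> bool:
    return "pseudogene" in str(biotype).lower()


def _is_annotated(gene) -> bool:
    return not (pd.isna(gene) or str(gene).strip() in ("", "NA", "nan", "None"))


def read_t2g(path: str | Path) -> pd.DataFrame:
    """Read a target-to-gene map: TSV with columns target, gene, biotype."""
    t2g = pd.read_csv(
        path, sep="\t", header=None, names=["target", "gene", "biotype"],
        dtype=str,
    )
    return t2g


def _gene_of_targets(target_names, t2g: pd.DataFrame):
    lookup = dict(zip(t2g["target"], zip(t2g["gene"], t2g["biotype"])))
    genes = {}
    for name in target_names:
        if name not in lookup:
            raise KeyError(f"target {name!r} missing from the target-to-gene map")
        genes[name] = lookup[name]
    return genes


def filter_ecs(
    matrix: CellEcMatrix,
    registry: ShadeRegistry,
    t2g: pd.DataFrame,
    min_cells: int = 10,
) -> list[int]:
    """Testable EC ids: shade-containing, present in >= ``min_cells`` cells,
    and resolving to exactly one annotated, non-pseudogene gene."""
    gene_info = _gene_of_targets(matrix.color_names, t2g)
    cells_per_ec = np.asarray((matrix.counts > 0).sum(axis=0)).ravel()
    keep = []
    for ec_id, ec in enumerate(matrix.ecs):
        if not ec.shades:
            continue
        if cells_per_ec[ec_id] < min_cells:
            continue
        genes = {gene_info[matrix.color_names[c]][0] for c in ec.canon}
        if len(genes) != 1:
            continue
        gene = genes.pop()
        biotypes = {gene_info[matrix.color_names[c]][1] for c in ec.canon}
        if not _is_annotated(gene) or any(_is_pseudogene(b) for b in biotypes):
            continue
        keep.append(ec_id)
    return keep


def build_table(
    matrix: CellEcMatrix,
    ec: int,
    cluster: set[str],
    gene_ecs: list[int],
) -> ContingencyTable:
    """2x2 cell-presence table for one (shade EC, cluster) pair.

    a/b: cells in/outside the cluster with the shade EC present; c/d: cells
    in/outside with any regular (shade-free) EC of the same gene present.
    A cell counts at most once per row.
    """
    if not cluster:
        raise ValueError("cluster must contain at least one barcode")
    unknown = cluster - set(matrix.barcodes)
    if unknown:
        raise ValueError(f"cluster barcodes not in matrix: {sorted(unknown)[:3]}")
    in_cluster = np.array([bc in cluster for bc in matrix.barcodes])
    presence = matrix.presence()
    ec_present = np.asarray(presence[:, ec].todense()).ravel().astype(bool)
    if gene_ecs:
        gene_present = (
            np.asarray(presence[:, gene_ecs].sum(axis=1)).ravel() > 0
        )
    else:
        gene_present = np.zeros(len(matrix.barcodes), dtype=bool)
    a = int((ec_present & in_cluster).sum())
    b = int((ec_present & ~in_cluster).sum())
    c = int((gene_present & in_cluster).sum())
    d = int((gene_present & ~in_cluster).sum())
    return ContingencyTable(a, b, c, d)


def regular_ecs_by_gene(matrix: CellEcMatrix, t2g: pd.DataFrame) -> dict[str, list[int]]:
    """Shade-free ECs resolving to a single gene, grouped by gene."""
    gene_info = _gene_of_targets(matrix.color_names, t2g)
    out: dict[str, list[int]] = {}
    for ec_id, ec in enumerate(matrix.ecs):
        if ec.shades:
            continue
        genes = {gene_info[matrix.color_names[c]][0] for c in ec.canon}
        if len(genes) == 1:
            out.setdefault(genes.pop(), []).append(ec_id)
    return out


def shade_de(
    matrix: CellEcMatrix,
    registry: ShadeRegistry,
    t2g: pd.DataFrame,
    clusters: dict[str, str],
    min_cells: int = 10,
    per_cluster_family: bool = False,
) -> list[ShadeTestResult]:
    """Test every (testable shade EC, cluster) pair for cluster specificity.

    ``clusters`` maps barcode -> cluster label and must cover the matrix's
    barcodes.  BH adjustment spans all tests in the run (or each cluster
    separately with ``per_cluster_family=True``); results are sorted by
    adjusted p, then odds ratio descending.
    """
    labels = sorted(set(clusters.values()))
    uncovered = set(matrix.barcodes) - set(clusters)
    if uncovered:
        raise ValueError(f"barcodes without a cluster label: {sorted(uncovered)[:3]}")
    testable = filter_ecs(matrix, registry, t2g, min_cells=min_cells)
    if not testable:
        logger.warning("no testable shade-containing equivalence classes")
        return []
    gene_info = _gene_of_targets(matrix.color_names, t2g)
    by_gene = regular_ecs_by_gene(matrix, t2g)

    results: list[ShadeTestResult] = []
    for label in labels:
        cluster_bcs = {bc for bc in matrix.barcodes if clusters[bc] == label}
        if not cluster_bcs:
            continue
        for ec_id in testable:
            ec = matrix.ecs[ec_id]
            gene = {gene_info[matrix.color_names[c]][0] for c in ec.canon}.pop()
            table = build_table(matrix, ec_id, cluster_bcs, by_gene.get(gene, []))
            results.append(
                ShadeTestResult(
                    ec_id=ec_id,
                    gene=gene,
                    cluster=label,
                    table=table,
                    odds_ratio=odds_ratio(table),
                    p=fisher_exact(table),
                )
            )

    if per_cluster_family:
        for label in labels:
            fam = [r for r in results if r.cluster == label]
            _apply_bh(fam)
    else:
        _apply_bh(results)
    results.sort(key=lambda r: (r.p_adj, -_or_sort_key(r.odds_ratio)))
    return results


def _or_sort_key(value: float) -> float:
    if math.isnan(value):
        return -1.0
    return value


def _apply_bh(results: list[ShadeTestResult]) -> None:
    if not results:
        return
    pvals = [r.p for r in results]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    for r, q in zip(results, p_adj):
        r.p_adj = float(q)


def results_frame(results: list[ShadeTestResult]) -> pd.DataFrame:
    """Volcano-ready table: one row per (EC, cluster) test."""
    return pd.DataFrame(
        {
            "ec_id": [r.ec_id for r in results],
            "gene": [r.gene for r in results],
            "cluster": [r.cluster for r in results],
            "a": [r.table.a for r in results],
            "b": [r.table.b for r in results],
            "c": [r.table.c for r in results],
            "d": [r.table.d for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p": [r.p for r in results],
            "p_adj": [r.p_adj for r in results],
        }
    )
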