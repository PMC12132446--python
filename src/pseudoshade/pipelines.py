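"""End-to-end pipeline runners used by the examples and the test harness.

Each runner wires the library stages together on synthetic inputs: simulate
-> colored graph -> contig extraction -> ornamental index -> shade-aware
counting -> statistics, and reports what the run recovered against ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass

from .counting import count_cells, demultiplex, informative_umis
from .ornament import ornament_index, plain_index
from .simulate import (
    SimConfig,
    melanoma_variant_contigs,
    preset_melanoma,
    preset_snp_pair,
    preset_strain_mix,
)
from .stats import ShadeTestResult, shade_de


def snp_contig_lengths(seed: int, genome_length: int = 200, n_snps: int = 1,
                       k: int = 31, positions: list[int] | None = None) -> dict[str, list[int]]:
    """Lengths of strain-unique contigs for a simulated genome pair.

    With isolated SNPs every unique contig has length 2k-1 (61 bp at k=31).
    """
    _, _, _, unique = preset_snp_pair(
        seed, genome_length=genome_length, n_snps=n_snps, k=k, positions=positions
    )
    return {name: [len(c.sequence) for c in contigs] for name, contigs in unique.items()}


@dataclass
class MelanomaRun:
    results: list[ShadeTestResult]
    planted_cluster: str
    planted_shade_ecs: set[int]
    n_cells: int

    @property
    def top_hit_is_planted(self) -> bool:
        """True when the smallest-p_adj test is the planted EC in its home
        cluster with odds ratio > 1."""
        if not self.results:
            return False
        top = self.results[0]
        return (
            top.ec_id in self.planted_shade_ecs
            and top.cluster == self.planted_cluster
            and top.odds_ratio > 1
        )


def run_melanoma_replicate(seed: int, cfg: SimConfig | None = None,
                           min_cells: int = 10) -> MelanomaRun:
    """One full planted-variant replicate: simulate reads with one
    cluster-specific variant, extract its 61-bp contig, ornament the
    transcriptome, count cells, and test shades per cluster."""
    cfg, targets, t2g, reads, truth = preset_melanoma(seed, cfg)
    contig_records = melanoma_variant_contigs(cfg, targets, truth)
    orn = ornament_index(contig_records, targets, k=cfg.k, k_map=29)
    matrix = count_cells(reads, orn)
    results = shade_de(matrix, orn.registry, t2g, truth.cell_cluster,
                       min_cells=min_cells)
    planted_gene, planted_cluster, _ = cfg.planted[0]
    planted_target = truth.variants[planted_gene][0]
    planted_shades = {
        s for s, (_, tname) in orn.registry.provenance.items() if tname == planted_target
    }
    planted_ecs = {
        ec_id
        for ec_id, ec in enumerate(matrix.ecs)
        if ec.shades & planted_shades
    }
    return MelanomaRun(
        results=results,
        planted_cluster=planted_cluster,
        planted_shade_ecs=planted_ecs,
        n_cells=len(matrix.barcodes),
    )


@dataclass
class DemuxRun:
    assignments: dict[str, str]
    truth: dict[str, str]
    informative: dict[str, int]

    def accuracy(self, min_umis: int = 20) -> tuple[float, int]:
        """(accuracy, n) over barcodes with >= min_umis informative UMIs."""
        eligible = [bc for bc, n in self.informative.items() if n >= min_umis]
        if not eligible:
            return 0.0, 0
        correct = sum(self.assignments[bc] == self.truth[bc] for bc in eligible)
        return correct / len(eligible), len(eligible)


def run_strain_mix(seed: int, **preset_kwargs) -> DemuxRun:
    """Strain demultiplexing on the strain-mix preset: pseudoalign reads to
    the per-strain SNP contigs and assign each barcode by argmax UMIs."""
    _, genomes, contig_records, reads, truth = preset_strain_mix(seed, **preset_kwargs)
    orn = plain_index(contig_records, k=31)
    matrix = count_cells(reads, orn)
    groups = {name: name.split(":")[0] for name in orn.target_names}
    assignments = demultiplex(matrix, groups)
    informative = informative_umis(matrix, groups)
    return DemuxRun(assignments=assignments, truth=truth.cell_strain,
                    informative=informative)
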