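"""Deterministic synthetic data: genomes with planted SNPs, transcriptomes,
barcoded single-cell reads, and matrix-level null data.

Every generator consumes a single ``numpy.random.Generator`` seeded once, in
a fixed documented order (genome -> SNP placement -> alleles -> cells ->
reads), so identical seeds give byte-identical outputs.  Ground truth is
recorded alongside, sufficient to predict every expected output exactly:
SNP positions/alleles, per-cell strain and cluster, and which cells carry a
planted variant.

The generators emulate the tool's study conditions: strain genome pairs
differing at isolated SNPs (spacing >= 2k guarantees each SNP yields one
unique 2k-1 bp contig per strain), a small transcriptome with one transcript
per gene, and 10x-style reads with a 16-bp barcode and 10-bp UMI.  They do
not model transcript-abundance variation, PCR duplication, or quality
scores.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as psio
from .contigs import ColorQuery, extract_contigs, filter_by_length
from .counting import CellEcMatrix, ECRegistry, EquivalenceClass, make_cell_ec_matrix
from .graph import build_graph_from_records, reverse_complement
from .ornament import ShadeRegistry, ornament_index

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    ``min_snp_spacing`` must be at least 2k so every planted SNP is isolated
    and yields exactly one strain-unique contig of length 2k-1.  ``planted``
    lists (gene, cluster, fraction-of-cells-expressing-the-variant).
    """

    seed: int = 0
    k: int = 31
    genome_length: int = 2000
    n_snps: int = 5
    min_snp_spacing: int = 120
    n_targets: int = 8
    target_length: int = 400
    read_length: int = 100
    error_rate: float = 0.005
    n_cells: int = 300
    reads_per_cell: int = 32
    clusters: list[tuple[str, int]] = field(
        default_factory=lambda: [("c0", 100), ("c1", 100), ("c2", 100)]
    )
    planted: list[tuple[str, str, float]] = field(default_factory=list)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    snps: list[tuple[int, str, str]] = field(default_factory=list)
    cell_cluster: dict[str, str] = field(default_factory=dict)
    cell_strain: dict[str, str] = field(default_factory=dict)
    variant_cells: dict[str, list[str]] = field(default_factory=dict)
    variants: dict[str, tuple[str, int, str, str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    others = [b for b in "ACGT" if b != base]
    return others[int(rng.integers(0, 3))]


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        out[i] = _mutate_base(rng, out[i])
    return "".join(out)


def _snp_positions(cfg: SimConfig, rng: np.random.Generator) -> list[int]:
    """Sorted SNP positions, pairwise >= min_snp_spacing apart and >= k from
    each genome end (so flanks of length k are intact)."""
    needed = cfg.n_snps * cfg.min_snp_spacing + 2 * cfg.k
    if cfg.genome_length <= needed:
        raise ValueError(
            f"genome_length {cfg.genome_length} too short for {cfg.n_snps} SNPs "
            f"spaced >= {cfg.min_snp_spacing} (need > {needed})"
        )
    slack = cfg.genome_length - needed
    extras = rng.multinomial(slack, np.ones(cfg.n_snps + 1) / (cfg.n_snps + 1))
    positions, cursor = [], cfg.k
    for i in range(cfg.n_snps):
        cursor += int(extras[i])
        positions.append(cursor)
        cursor += cfg.min_snp_spacing
    return positions


def sim_genomes(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    positions: list[int] | None = None,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Two genomes identical except substitutions at isolated positions.

    Returns ``[("genomeA", seqA), ("genomeB", seqB)]`` plus ground truth.
    Explicit ``positions`` (0-based) override random placement.
    """
    rng = rng or cfg.rng()
    seq_a = random_dna(rng, cfg.genome_length)
    if positions is None:
        positions = _snp_positions(cfg, rng)
    else:
        positions = sorted(positions)
        for pos in positions:
            if not cfg.k <= pos < cfg.genome_length - cfg.k:
                raise ValueError(f"SNP position {pos} leaves a flank shorter than k")
    truth = GroundTruth()
    seq_b = list(seq_a)
    for pos in positions:
        ref = seq_a[pos]
        alt = _mutate_base(rng, ref)
        seq_b[pos] = alt
        truth.snps.append((pos, ref, alt))
    return [("genomeA", seq_a), ("genomeB", "".join(seq_b))], truth


def sim_transcriptome(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[tuple[str, str]], pd.DataFrame, GroundTruth]:
    """Random transcripts (one per gene) plus variant haplotypes for planted
    genes, each with a single substitution at the transcript midpoint."""
    rng = rng or cfg.rng()
    targets = [
        (f"t{i}", random_dna(rng, cfg.target_length)) for i in range(cfg.n_targets)
    ]
    t2g = pd.DataFrame(
        {
            "target": [name for name, _ in targets],
            "gene": [f"gene{i}" for i in range(cfg.n_targets)],
            "biotype": ["protein_coding"] * cfg.n_targets,
        }
    )
    truth = GroundTruth()
    gene_to_target = dict(zip(t2g["gene"], t2g["target"]))
    target_seq = dict(targets)
    for gene, _, _ in cfg.planted:
        tname = gene_to_target[gene]
        pos = cfg.target_length // 2
        ref = target_seq[tname][pos]
        alt = _mutate_base(rng, ref)
        truth.variants[gene] = (tname, pos, ref, alt)
    return targets, t2g, truth


def variant_haplotype(targets: list[tuple[str, str]], variant) -> tuple[str, str]:
    """Apply one recorded (target, pos, ref, alt) variant to its transcript."""
    tname, pos, _ref, alt = variant
    seq = dict(targets)[tname]
    return (f"{tname}|variant", seq[:pos] + alt + seq[pos + 1 :])


def _assign_cells(cfg: SimConfig, rng: np.random.Generator) -> tuple[list[str], dict[str, str]]:
    n = sum(size for _, size in cfg.clusters)
    barcodes = []
    seen = set()
    while len(barcodes) < n:
        bc = random_dna(rng, 16)
        if bc not in seen:
            seen.add(bc)
            barcodes.append(bc)
    cluster_of = {}
    i = 0
    for label, size in cfg.clusters:
        for _ in range(size):
            cluster_of[barcodes[i]] = label
            i += 1
    return barcodes, cluster_of


def sim_single_cell_reads(
    cfg: SimConfig,
    targets: list[tuple[str, str]],
    t2g: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, str]], GroundTruth]:
    """Barcoded (barcode, UMI, cDNA) reads over the transcriptome.

    Cells selected for a planted (gene, cluster, fraction) draw all of that
    gene's reads from the variant haplotype; reads are strand-randomized and
    carry substitution errors at ``error_rate``.
    """
    rng = rng or cfg.rng()
    barcodes, cluster_of = _assign_cells(cfg, rng)
    truth.cell_cluster = dict(cluster_of)

    gene_of_target = dict(zip(t2g["target"], t2g["gene"]))
    variant_seq = {}
    for gene, var in truth.variants.items():
        variant_seq[gene] = variant_haplotype(targets, var)[1]

    for gene, cluster, fraction in cfg.planted:
        members = [bc for bc in barcodes if cluster_of[bc] == cluster]
        n_pick = int(round(fraction * len(members)))
        picked = list(rng.choice(members, size=n_pick, replace=False))
        truth.variant_cells[gene] = picked

    variant_cells = {g: set(v) for g, v in truth.variant_cells.items()}
    reads: list[tuple[str, str, str]] = []
    for bc in barcodes:
        for _ in range(cfg.reads_per_cell):
            tid = int(rng.integers(0, len(targets)))
            tname, tseq = targets[tid]
            gene = gene_of_target[tname]
            if gene in variant_cells and bc in variant_cells[gene]:
                tseq = variant_seq[gene]
            start = int(rng.integers(0, len(tseq) - cfg.read_length + 1))
            seq = tseq[start : start + cfg.read_length]
            seq = _apply_errors(rng, seq, cfg.error_rate)
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            umi = random_dna(rng, 10)
            reads.append((bc, umi, seq))
    return reads, truth


def sim_strain_reads(
    cfg: SimConfig,
    genomes: list[tuple[str, str]],
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, str]], GroundTruth]:
    """Reads for strain demultiplexing: each cell belongs to one strain and
    every read is drawn around a SNP of that strain's genome (informative by
    construction, before sequencing error)."""
    rng = rng or cfg.rng()
    barcodes, cluster_of = _assign_cells(cfg, rng)
    strain_names = [name for name, _ in genomes]
    truth.cell_strain = {
        bc: strain_names[i % len(strain_names)] for i, bc in enumerate(barcodes)
    }
    seqs = dict(genomes)
    positions = [pos for pos, _, _ in truth.snps]
    half = cfg.read_length // 2
    jitter_max = max(half - cfg.k, 0)
    reads = []
    for bc in barcodes:
        gseq = seqs[truth.cell_strain[bc]]
        for _ in range(cfg.reads_per_cell):
            snp = positions[int(rng.integers(0, len(positions)))]
            jitter = int(rng.integers(-jitter_max, jitter_max + 1)) if jitter_max else 0
            start = min(max(snp - half + jitter, 0), len(gseq) - cfg.read_length)
            seq = gseq[start : start + cfg.read_length]
            seq = _apply_errors(rng, seq, cfg.error_rate)
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            reads.append((bc, random_dna(rng, 10), seq))
    return reads, truth


# -- presets -----------------------------------------------------------------

def preset_snp_pair(
    seed: int,
    genome_length: int = 200,
    n_snps: int = 1,
    k: int = 31,
    positions: list[int] | None = None,
):
    """Two sequences differing at isolated SNPs, plus the colored graph's
    strain-unique contigs per color."""
    cfg = SimConfig(
        seed=seed, k=k, genome_length=genome_length, n_snps=n_snps,
        min_snp_spacing=2 * k + 5,
    )
    if positions is None and genome_length <= n_snps * cfg.min_snp_spacing + 2 * k:
        positions = [genome_length // 2]  # single centered SNP on short genomes
    genomes, truth = sim_genomes(cfg, positions=positions)
    graph = build_graph_from_records(
        [[genomes[0]], [genomes[1]]], k, color_names=[g[0] for g in genomes]
    )
    unique = {
        name: extract_contigs(graph, ColorQuery.exactly([name]))
        for name, _ in genomes
    }
    return genomes, truth, graph, unique


def preset_melanoma(seed: int, cfg: SimConfig | None = None):
    """Full single-cell pipeline inputs with one planted cluster-specific
    variant (gene3 in cluster c0, 30% of cells)."""
    if cfg is None:
        cfg = SimConfig(seed=seed, planted=[("gene3", "c0", 0.3)])
    else:
        cfg.seed = seed
    rng = cfg.rng()
    targets, t2g, truth = sim_transcriptome(cfg, rng)
    reads, truth = sim_single_cell_reads(cfg, targets, t2g, truth, rng)
    return cfg, targets, t2g, reads, truth


def melanoma_variant_contigs(cfg: SimConfig, targets, truth: GroundTruth):
    """Extract the variant-unique 61-bp contigs exactly as the tool would:
    color 0 = reference transcripts, color 1 = variant haplotypes."""
    variant_records = [
        variant_haplotype(targets, var) for var in truth.variants.values()
    ]
    graph = build_graph_from_records(
        [targets, variant_records], cfg.k, color_names=["reference", "variant"]
    )
    contigs = extract_contigs(graph, ColorQuery.exactly(["variant"]))
    contigs = filter_by_length(contigs, 2 * cfg.k - 1)
    return [(f"contig_{i}", c.sequence) for i, c in enumerate(contigs)]


def preset_strain_mix(
    seed: int,
    genome_length: int = 6000,
    n_snps: int = 40,
    n_cells: int = 150,
    reads_per_cell: int = 30,
    error_rate: float = 0.01,
    k: int = 31,
):
    """Strain-mix demultiplexing inputs: two genomes, per-strain 61-bp SNP
    contigs, and barcoded reads drawn around SNPs at 1% error."""
    cfg = SimConfig(
        seed=seed, k=k, genome_length=genome_length, n_snps=n_snps,
        min_snp_spacing=120, read_length=100, error_rate=error_rate,
        reads_per_cell=reads_per_cell,
        clusters=[("cells", n_cells)],
    )
    rng = cfg.rng()
    genomes, truth = sim_genomes(cfg, rng)
    graph = build_graph_from_records(
        [[genomes[0]], [genomes[1]]], k, color_names=["genomeA", "genomeB"]
    )
    contig_records = []
    for name, _ in genomes:
        contigs = filter_by_length(
            extract_contigs(graph, ColorQuery.exactly([name])), 2 * k - 1
        )
        contig_records.extend(
            (f"{name}:contig_{i}", c.sequence) for i, c in enumerate(contigs)
        )
    reads, truth = sim_strain_reads(cfg, genomes, truth, rng)
    return cfg, genomes, contig_records, reads, truth


def preset_null(
    seed: int,
    n_ecs: int = 200,
    n_cells: int = 200,
    n_clusters: int = 2,
    shade_rate: float = 0.15,
    gene_rate: float = 0.6,
):
    """Matrix-level null: per gene one shade EC and one regular EC, presence
    drawn independently of cluster — no planted effect."""
    rng = np.random.default_rng(seed)
    color_names = [f"t{i}" for i in range(n_ecs)]
    registry = ShadeRegistry()
    ec_registry = ECRegistry()
    shade_ec_ids, regular_ec_ids = [], []
    for i in range(n_ecs):
        shade = registry.new_shade(i, color_names[i], f"contig_{i}")
        shade_ec_ids.append(
            ec_registry.get_id(
                EquivalenceClass(canon=frozenset({i}), shades=frozenset({shade}))
            )
        )
        regular_ec_ids.append(
            ec_registry.get_id(
                EquivalenceClass(canon=frozenset({i}), shades=frozenset())
            )
        )
    barcodes = [f"cell{i:04d}" for i in range(n_cells)]
    clusters = {bc: f"c{i % n_clusters}" for i, bc in enumerate(barcodes)}
    triples = set()
    for ec_ids, rate in ((shade_ec_ids, shade_rate), (regular_ec_ids, gene_rate)):
        for ec_id in ec_ids:
            present = rng.random(n_cells) < rate
            for i in np.flatnonzero(present):
                triples.add((barcodes[i], f"umi{ec_id}", ec_id))
    matrix = make_cell_ec_matrix(triples, ec_registry, color_names)
    t2g = pd.DataFrame(
        {
            "target": color_names,
            "gene": [f"gene{i}" for i in range(n_ecs)],
            "biotype": ["protein_coding"] * n_ecs,
        }
    )
    return matrix, registry, t2g, clusters


# -- file output (CLI / examples) -------------------------------------------

def write_preset_files(outdir: str | Path, preset: str, seed: int) -> None:
    """Materialize a preset as FASTA/FASTQ/TSV files plus ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if preset == "snp-pair":
        genomes, truth, _, _ = preset_snp_pair(seed)
        psio.write_fasta(outdir / "genomeA.fa", [genomes[0]])
        psio.write_fasta(outdir / "genomeB.fa", [genomes[1]])
        truth.to_json(outdir / "ground_truth.json")
    elif preset == "melanoma":
        cfg, targets, t2g, reads, truth = preset_melanoma(seed)
        psio.write_fasta(outdir / "targets.fa", targets)
        contig_records = melanoma_variant_contigs(cfg, targets, truth)
        psio.write_fasta(outdir / "variant_contigs.fa", contig_records)
        t2g.to_csv(outdir / "t2g.tsv", sep="\t", header=False, index=False)
        psio.write_fastq(
            outdir / "reads.fq",
            [(f"r{i}_{bc}_{umi}", seq) for i, (bc, umi, seq) in enumerate(reads)],
        )
        pd.Series(truth.cell_cluster).rename("cluster").to_csv(
            outdir / "clusters.tsv", sep="\t", header=False
        )
        truth.to_json(outdir / "ground_truth.json")
    elif preset == "strain-mix":
        cfg, genomes, contig_records, reads, truth = preset_strain_mix(seed)
        psio.write_fasta(outdir / "genomeA.fa", [genomes[0]])
        psio.write_fasta(outdir / "genomeB.fa", [genomes[1]])
        psio.write_fasta(outdir / "strain_contigs.fa", contig_records)
        psio.write_fastq(
            outdir / "reads.fq",
            [(f"r{i}_{bc}_{umi}", seq) for i, (bc, umi, seq) in enumerate(reads)],
        )
        pd.Series(truth.cell_strain).rename("strain").to_csv(
            outdir / "strains.tsv", sep="\t", header=False
        )
        with open(outdir / "groups.tsv", "w") as fh:
            for name, _ in contig_records:
                fh.write(f"{name}\t{name.split(':')[0]}\n")
        truth.to_json(outdir / "ground_truth.json")
    else:
        raise ValueError(f"unknown preset {preset!r}")
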