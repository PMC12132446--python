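"""Extract strain-unique SNP contigs from a colored de Bruijn graph.

Simulates two 200-bp genome sequences that differ by one substitution,
builds a colored graph at k=31 (one color per genome), and extracts the
contigs whose color profile is exactly one color.  Because the SNP is
isolated — at least k matching bases flank it on each side — each genome's
unique contig is exactly 2k-1 = 61 bp long: the 31 k-mers that overlap the
variant base, plus the conserved flanks they span.
"""

from pseudoshade import ColorQuery, extract_contigs, jaccard
from pseudoshade.simulate import preset_snp_pair

genomes, truth, graph, unique = preset_snp_pair(
    seed=1, genome_length=200, n_snps=1, positions=[99]
)

pos, ref, alt = truth.snps[0]
print(f"planted SNP: position {pos} (0-based), {ref}->{alt}")
print(f"graph: {len(graph)} canonical 31-mers, colors = {graph.color_names}")
for name, contigs in unique.items():
    for c in contigs:
        print(f"unique to {name}: {len(c.sequence)} bp contig")
print(f"k-mer Jaccard between the genomes: {jaccard(graph, 0, 1):.3f}")

# The 61-bp length identifies single-nucleotide differences: longer unique
# contigs would indicate indels or diverged regions, shorter ones cannot
# exist (every contig carries at least one full k-mer).
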