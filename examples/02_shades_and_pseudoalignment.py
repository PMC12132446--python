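"""Attach a variant contig to a reference target as a shade, then
pseudoalign reads.

A 61-bp variant contig is mapped to a 300-bp reference transcript by shared
29-mers (its conserved flanks), minted a shade whose parent is the target's
color, and inserted into the reference graph.  A read that spans the
variant then lands in an equivalence class containing both the parent
target and the shade; a read from the reference allele gets the parent
only.  The shade never appears without its parent (parent inclusion).
"""

import numpy as np

from pseudoshade import assign_equivalence_class, ornament_index
from pseudoshade.simulate import random_dna

rng = np.random.default_rng(7)
target = ("ENST_demo", random_dna(rng, 300))

# one substitution at position 150 and the 61-bp contig around it
pos = 150
alt = [b for b in "ACGT" if b != target[1][pos]][0]
mutated = target[1][:pos] + alt + target[1][pos + 1 :]
contig = mutated[pos - 30 : pos + 31]

orn = ornament_index([("variant_contig", contig)], [target], k=31, k_map=29)
shade = next(iter(orn.registry.shades))
print(f"minted shade {shade!r} with parent color {orn.registry.pi(shade)}")
print(f"parent inclusion holds: {orn.check_parent_inclusion()}")

for label, read in [
    ("reference-allele read", target[1][100:200]),
    ("variant-allele read  ", mutated[100:200]),
    ("unrelated read       ", random_dna(rng, 100)),
]:
    ec = assign_equivalence_class(read, orn)
    if ec is None:
        print(f"{label}: unmapped")
    else:
        print(f"{label}: EC canon={sorted(ec.canon)} shades={sorted(ec.shades)}")

# The variant read's EC records compatibility with the target AND the
# variant — reference-free evidence that the read carries the mutation.
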