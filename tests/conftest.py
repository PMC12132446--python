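"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results from first principles
(naive k-mer enumeration, literal transcriptions of the shade-insertion and
equivalence-class rules, integer hypergeometric enumeration) so that the
package's optimized paths are checked against code that shares nothing with
them.
"""

from __future__ import annotations

import math
import re

import numpy as np
import pytest

_COMP = str.maketrans("ACGT", "TGCA")
_SPLIT = re.compile(r"[^ACGT]+")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canon(seq: str) -> str:
    r = rc(seq)
    return seq if seq <= r else r


def naive_kmer_color_map(record_sets, k):
    """Oracle for build_graph: enumerate every k-mer of every file,
    canonicalize, union file indices."""
    table = {}
    for color, records in enumerate(record_sets):
        for _, seq in records:
            for frag in _SPLIT.split(seq.upper()):
                for i in range(len(frag) - k + 1):
                    table.setdefault(canon(frag[i : i + k]), set()).add(color)
    return table


def spelled_kmers(sequence, k):
    return [canon(sequence[i : i + k]) for i in range(len(sequence) - k + 1)]


def naive_profile_runs(unitig_seq, kmer_colors, k):
    """Oracle for contig extraction: label each k-mer of a unitig with its
    profile and merge adjacent equal-profile k-mers."""
    kmers = spelled_kmers(unitig_seq, k)
    runs = []
    start = 0
    for i in range(1, len(kmers)):
        if kmer_colors[kmers[i]] != kmer_colors[kmers[start]]:
            runs.append((unitig_seq[start : i - 1 + k], frozenset(kmer_colors[kmers[start]])))
            start = i
    runs.append((unitig_seq[start:], frozenset(kmer_colors[kmers[start]])))
    return runs


def add_shade_literal(u, s, table, original, pi):
    """Literal transcription of the shade-insertion rule."""
    for x in u:
        if x in original:
            if pi[s] not in original[x]:
                table[x] = table[x] | {pi[s], s}
        else:
            table[x] = table.get(x, set()) | {pi[s], s}
    return table


def assign_ec_literal(read_kmers, table, pi):
    """Literal transcription of the equivalence-class rule: intersect parent
    colors over ALL read k-mers, union shades, keep shades whose parent
    survives."""
    color_sets = [table.get(x, set()) for x in read_kmers]
    if not color_sets:
        return None
    canon_colors = None
    shades = set()
    for cs in color_sets:
        parents = {c for c in cs if isinstance(c, int)}
        shades |= {c for c in cs if isinstance(c, str)}
        canon_colors = parents if canon_colors is None else canon_colors & parents
    if not canon_colors:
        return None
    valid = frozenset(s for s in shades if pi[s] in canon_colors)
    return frozenset(canon_colors), valid


def fisher_bruteforce(a, b, c, d):
    """Exhaustive two-sided Fisher oracle in exact integer arithmetic."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    weights = {
        x: math.comb(row1, x) * math.comb(n - row1, col1 - x)
        for x in range(lo, hi + 1)
    }
    observed = weights[a]
    return sum(w for w in weights.values() if w <= observed) / math.comb(n, col1)


def random_records(rng, n_seqs, min_len=50, max_len=500):
    bases = np.frombuffer(b"ACGT", dtype="S1")
    out = []
    for i in range(n_seqs):
        length = int(rng.integers(min_len, max_len + 1))
        out.append((f"seq{i}", rng.choice(bases, size=length).tobytes().decode()))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
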