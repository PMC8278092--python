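"""Independent oracles used by the test suite.

Everything here is deliberately written against different libraries or by
brute force, so agreement with the package is a two-route check rather
than a tautology.
"""
from __future__ import annotations

import itertools

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_WOBBLES = {("G", "U"), ("U", "G")}


def bh_stepup(p):
    """Brute-force Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def hypergeom_tail(k, M, K, n):
    """P(X >= k) by explicit summation of the hypergeometric pmf."""
    from math import comb
    hi = min(K, n)
    total = comb(M, n)
    return sum(comb(K, x) * comb(M - K, n - x) for x in range(k, hi + 1)) / total


def pearson_with_p(x, y):
    r, p = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return r, p


# ---------------------------------------------------------------------------
# alignment oracle: Biopython PairwiseAligner with the seed scaling encoded
# as a lowercase query alphabet

def make_aligner(match=5.0, wobble=1.0, mismatch=-3.0, gap_open=-9.0,
                 gap_extend=-4.0, seed_scale=4.0):
    alpha = "ACGUacgu"
    M = substitution_matrices.Array(alphabet=alpha, dims=2)
    for a in "ACGU":
        for b in "ACGU":
            s = (match if (a, b) in _PAIRS
                 else wobble if (a, b) in _WOBBLES else mismatch)
            M[a, b] = s
            M[b, a] = (match if (b, a) in _PAIRS
                       else wobble if (b, a) in _WOBBLES else mismatch)
            M[a.lower(), b] = seed_scale * s
            M[a.lower(), b.lower()] = seed_scale * s
            M[b, a.lower()] = seed_scale * float(M[b.upper(), a])
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = M
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def _encode_query(mirna, seed_start=2, seed_end=8):
    m = len(mirna)
    rev = mirna.upper().replace("T", "U")[::-1]
    return "".join(c.lower() if seed_start <= m - i <= seed_end else c
                   for i, c in enumerate(rev))


def oracle_score(mirna, segment, aligner):
    """Best local alignment score of the (reversed, seed-encoded) miRNA
    against a transcript segment, by an independent engine."""
    if not segment:
        return 0.0
    t = segment.upper().replace("T", "U")
    return float(aligner.score(t, _encode_query(mirna)))


def assert_hits_optimal(mirna, transcript, min_score, aligner, hits):
    """Validate a scanner hit list against the aligner oracle.

    Checks, greedily in descending-score order: (a) each reported score is
    the true maximum over the remaining transcript segments, (b) the
    reported interval itself achieves exactly that score, and (c) once all
    hits are removed no remaining segment reaches ``min_score``.  Boundary
    choices among equal-score alignments are left to the scanner.
    """
    ordered = sorted(hits, key=lambda h: (-h[2], h[0]))
    segments = [(0, transcript)]
    for start, end, score in ordered:
        best = max((oracle_score(mirna, seg, aligner) for _, seg in segments),
                   default=0.0)
        assert score == best, (score, best)
        site = transcript[start - 1:end]
        assert oracle_score(mirna, site, aligner) == score
        new_segments = []
        placed = False
        for off, seg in segments:
            if off <= start - 1 and end <= off + len(seg):
                placed = True
                if start - 1 > off:
                    new_segments.append((off, seg[:start - 1 - off]))
                if end < off + len(seg):
                    new_segments.append((end, seg[end - off:]))
            else:
                new_segments.append((off, seg))
        assert placed, f"hit [{start}, {end}] crosses a prior hit"
        segments = new_segments
    leftover = max((oracle_score(mirna, seg, aligner) for _, seg in segments),
                   default=0.0)
    assert leftover < min_score


def random_rna(rng, length):
    return "".join(rng.choice(list("ACGU"), size=length))


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def reverse_complement_rna(seq):
    comp = {"A": "U", "U": "A", "G": "C", "C": "G", "T": "A"}
    return "".join(comp[c] for c in seq.upper()[::-1])
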