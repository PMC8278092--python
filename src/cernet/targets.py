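"""Miranda-style miRNA target-site scanning.

A miRNA binds a transcript antiparallel, so sites are found by locally
aligning the *reversed* miRNA (3'->5') against the transcript (5'->3')
under a complementarity scoring scheme: Watson-Crick pair +5, G:U wobble
+1, mismatch -3, gap open -9, gap extend -4 per additional gapped base.
Contributions at miRNA positions 2-8 (the seed, counted 5'->3') are scaled
by 4.0, and hits must reach the score cutoff (default 140).

Non-overlapping hits are reported greedily by descending score (ties to
the leftmost start): each accepted hit splits its transcript segment in
two and the remainder is rescanned, which guarantees hits can never
overlap nor bridge across an accepted site.

Each hit is annotated with a canonical seed class from the exact
complementarity pattern at positions 2-8 and the transcript adenine
opposite position 1 (8mer / 7mer-m8 / 7mer-A1 / 6mer / alignment-only).

Thermodynamic (folding-energy) filtering is deliberately not modelled;
see the optional ``au_content`` helper for a weighted-AU-context proxy.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .datatypes import TargetHit

_ALPHABET = "ACGUN"
_CODE = {b: i for i, b in enumerate(_ALPHABET)}

# base pairings, (miRNA base, transcript base)
_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_WOBBLES = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class ScanParams:
    """Scoring constants of the scanner (Miranda-like defaults)."""

    match: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_scale: float = 4.0
    seed_start: int = 2  # miRNA positions scaled, 1-based inclusive
    seed_end: int = 8
    min_score: float = 140.0

    def score_matrix(self) -> np.ndarray:
        s = np.full((5, 5), self.mismatch)
        for (a, b) in _PAIRS:
            s[_CODE[a], _CODE[b]] = self.match
        for (a, b) in _WOBBLES:
            s[_CODE[a], _CODE[b]] = self.wobble
        s[_CODE["N"], :] = -1e4
        s[:, _CODE["N"]] = -1e4
        return s


DEFAULT_PARAMS = ScanParams()


def encode(seq: str, name: str = "sequence") -> np.ndarray:
    """Uppercase, T->U, and encode to integer codes; rejects other letters."""
    s = seq.upper().replace("T", "U")
    try:
        return np.fromiter((_CODE[c] for c in s), dtype=np.int8, count=len(s))
    except KeyError as exc:
        raise ValueError(f"invalid character {exc.args[0]!r} in {name}") from None


@njit(cache=False)
def _sw_fill(W, gap_open, gap_extend):  # pragma: no cover - exercised via scan
    m, n = W.shape
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), -1e18)
    F = np.full((m + 1, n + 1), -1e18)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] + gap_open
            if E[i, j - 1] + gap_extend > e:
                e = E[i, j - 1] + gap_extend
            E[i, j] = e
            f = H[i - 1, j] + gap_open
            if F[i - 1, j] + gap_extend > f:
                f = F[i - 1, j] + gap_extend
            F[i, j] = f
            h = H[i - 1, j - 1] + W[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
    return H, E, F, best


def _traceback(H, E, F, W, i, j, gap_extend):
    """Aligned (query_idx, transcript_idx) pairs of the local path ending at (i, j).

    Ambiguous cells prefer the diagonal, then a transcript gap, matching the
    fill order; the choice only affects which equal-score path is reported.
    """
    pairs = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0.0:
                break
            if np.isclose(h, H[i - 1, j - 1] + W[i - 1, j - 1]):
                pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif np.isclose(h, E[i, j]):
                state = "E"
            else:
                state = "F"
        elif state == "E":
            if np.isclose(E[i, j], E[i, j - 1] + gap_extend):
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # F
            if np.isclose(F[i, j], F[i - 1, j] + gap_extend):
                i -= 1
            else:
                i -= 1
                state = "H"
    pairs.reverse()
    return pairs


def _weights(m: int, params: ScanParams) -> np.ndarray:
    """Per reversed-query-position weight; reversed index i maps to miRNA
    position m - i (1-based, 5'->3')."""
    pos = m - np.arange(m)  # original 1-based positions
    return np.where((pos >= params.seed_start) & (pos <= params.seed_end),
                    params.seed_scale, 1.0)


def _best_local_hit(q, w, t_codes, params, S):
    """Best local alignment of reversed query against a transcript segment.

    Returns (score, start0, end0_exclusive, pairs) or None if below cutoff.
    Ties on score resolve to the leftmost start, then the shortest span.
    """
    if t_codes.size == 0:
        return None
    W = w[:, None] * S[q[:, None], t_codes[None, :]]
    H, E, F, best = _sw_fill(W, params.gap_open, params.gap_extend)
    if best < params.min_score:
        return None
    cells = np.argwhere(np.isclose(H, best))
    candidates = []
    for i, j in cells:
        pairs = _traceback(H, E, F, W, int(i), int(j), params.gap_extend)
        if not pairs:
            continue
        tpos = [p[1] for p in pairs]
        candidates.append((min(tpos), max(tpos) + 1, pairs))
    if not candidates:
        return None
    start0, end0, pairs = min(candidates, key=lambda c: (c[0], c[1]))
    return float(best), start0, end0, pairs


def _classify_seed(pairs, q, t_full, offset, m, params, S):
    """Seed class from exact Watson-Crick pairing at positions 2-8 and the
    transcript adenine across from position 1."""
    exact = {}
    tpos_of = {}
    for qi, tj in pairs:
        pos = m - qi
        tpos_of[pos] = offset + tj
        exact[pos] = S[q[qi], t_full[offset + tj]] == params.match
    seed28 = all(exact.get(p, False) for p in range(2, 9))
    seed27 = all(exact.get(p, False) for p in range(2, 8))
    a1 = False
    if 1 in tpos_of:
        a1 = t_full[tpos_of[1]] == _CODE["A"]
    elif 2 in tpos_of and tpos_of[2] + 1 < t_full.size:
        a1 = t_full[tpos_of[2] + 1] == _CODE["A"]
    if seed28 and a1:
        return "8mer"
    if seed28:
        return "7mer-m8"
    if seed27 and a1:
        return "7mer-A1"
    if seed27:
        return "6mer"
    return "alignment-only"


def scan_targets(mirna_seq: str, transcript_seq: str,
                 params: ScanParams | None = None, *,
                 mirna_id: str = "mirna",
                 transcript_id: str = "transcript") -> list:
    """All non-overlapping binding sites of one miRNA on one transcript.

    Hits (score >= ``params.min_score``) are returned in ascending start
    order with 1-based inclusive transcript coordinates.
    """
    params = params or DEFAULT_PARAMS
    if not transcript_seq:
        return []
    m = len(mirna_seq)
    if not 18 <= m <= 26:
        raise ValueError(f"miRNA length must be 18-26 nt, got {m} ({mirna_id})")
    q = encode(mirna_seq, f"miRNA {mirna_id}")[::-1].copy()
    t = encode(transcript_seq, f"transcript {transcript_id}")
    w = _weights(m, params)
    S = params.score_matrix()

    hits = []
    # worklist of transcript segments (offset, codes); best hit per segment
    segments = [(0, t)]
    cache = {}
    for _ in range(len(transcript_seq)):  # hard bound on iterations
        best_key, best_val = None, None
        for off, seg in segments:
            if off not in cache:
                cache[off] = _best_local_hit(q, w, seg, params, S)
            val = cache[off]
            if val is None:
                continue
            score, s0, e0, _pairs = val
            rank = (-score, off + s0)
            if best_key is None or rank < best_key:
                best_key, best_val, best_off = rank, val, off
        if best_val is None:
            break
        score, s0, e0, pairs = best_val
        seed_class = _classify_seed(pairs, q, t, best_off, m, params, S)
        hits.append(TargetHit(mirna_id, transcript_id,
                              best_off + s0 + 1, best_off + e0,
                              score, seed_class))
        # split the segment around the accepted hit and rescan the halves
        new_segments = []
        for off, seg in segments:
            if off != best_off:
                new_segments.append((off, seg))
                continue
            if s0 > 0:
                new_segments.append((off, seg[:s0]))
            if e0 < seg.size:
                new_segments.append((off + e0, seg[e0:]))
            cache.pop(off, None)
        segments = new_segments
    return sorted(hits, key=lambda h: (h.start, h.end))


def scan_many(mirnas: dict, transcripts: dict,
              params: ScanParams | None = None) -> list:
    """Scan every miRNA against every transcript (sorted id order)."""
    hits = []
    for mid in sorted(mirnas):
        for tid in sorted(transcripts):
            hits.extend(scan_targets(mirnas[mid], transcripts[tid], params,
                                     mirna_id=mid, transcript_id=tid))
    return hits


def au_content(transcript_seq: str, start: int, end: int, flank: int = 30) -> float:
    """Weighted AU fraction of the site's flanking context (optional proxy
    for site accessibility; OFF by default everywhere in the pipeline)."""
    s = transcript_seq.upper().replace("T", "U")
    lo, hi = max(0, start - 1 - flank), min(len(s), end + flank)
    ctx = s[lo:hi]
    if not ctx:
        return 0.0
    return sum(c in "AU" for c in ctx) / len(ctx)


# ---------------------------------------------------------------------------
# interaction maps

EVIDENCE_TAGS = ("scan", "whitelist", "both")


class InteractionMap:
    """miRNA -> target transcripts with evidence tags.

    A pair is a member iff it has at least one scan hit AND, when
    ``require_whitelist`` was set at build time, it also appears in the
    interaction whitelist.  Tags record the evidence ("scan" or "both").
    """

    def __init__(self, pairs: dict, require_whitelist: bool):
        # pairs: {(mirna_id, target_id): tag}
        self._pairs = dict(pairs)
        self.require_whitelist = require_whitelist
        self._by_mirna = {}
        for (mid, tid) in self._pairs:
            self._by_mirna.setdefault(mid, set()).add(tid)

    def targets_of(self, mirna_id: str) -> set:
        return set(self._by_mirna.get(mirna_id, set()))

    def mirnas_of(self, target_id: str) -> set:
        return {m for (m, t) in self._pairs if t == target_id}

    def tag(self, mirna_id: str, target_id: str) -> str | None:
        return self._pairs.get((mirna_id, target_id))

    def pairs(self) -> dict:
        return dict(self._pairs)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)


def build_interaction_map(hits, whitelist, require_whitelist: bool = True,
                          known_ids=None) -> InteractionMap:
    """Combine scan hits with the interaction whitelist.

    ``whitelist`` is an iterable of (mirna_id, target_id) pairs (or a
    DataFrame with those columns).  Whitelist rows referencing ids outside
    ``known_ids`` (when given) are logged and kept.
    """
    import logging

    log = logging.getLogger(__name__)
    if hasattr(whitelist, "itertuples"):
        wl = {(r.mirna_id, r.target_id) for r in whitelist.itertuples()}
    else:
        wl = {tuple(p) for p in whitelist}
    if known_ids is not None:
        known = set(known_ids)
        for (m, t) in sorted(wl):
            if m not in known or t not in known:
                log.info("whitelist pair (%s, %s) references unknown ids; kept", m, t)
    scan_pairs = {(h.mirna_id, h.transcript_id) for h in hits}
    pairs = {}
    for p in scan_pairs:
        in_wl = p in wl
        if require_whitelist and not in_wl:
            continue
        pairs[p] = "both" if in_wl else "scan"
    return InteractionMap(pairs, require_whitelist)
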