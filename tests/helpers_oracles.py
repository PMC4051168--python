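"""Independent oracle implementations used only by the tests.

These deliberately share no code with the package: the local-alignment
oracle is a plain full-matrix Gotoh dynamic program, the classification
oracle a literal filter/argmax/tie transcription, the interval oracle a
per-read linear scan.
"""

from __future__ import annotations


def gotoh_local_score(query: str, subject: str, match: int, mismatch: int,
                      gap_open: int, gap_extend: int) -> int:
    """Optimal local alignment score under affine gaps where a gap of
    length L costs gap_open + L * gap_extend.  O(n*m) full matrix."""
    n, m = len(query), len(subject)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject (up)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (left)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          F[i][j - 1] - gap_extend)
            s = match if query[i - 1] == subject[j - 1] else -mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return int(best)


def brute_force_classify(hits, min_identity, min_read_coverage, max_evalue):
    """(genome_id or None, ambiguous) by literal filter + argmax + tie rule."""
    passing = []
    for h in hits:
        if h.percent_identity < min_identity:
            continue
        if min_read_coverage is not None:
            cov = (h.q_end - h.q_start + 1) / h.query_length
            if cov < min_read_coverage:
                continue
        if h.evalue > max_evalue:
            continue
        passing.append(h)
    if not passing:
        return None, False
    best = max(h.bit_score for h in passing)
    winners = sorted(h.subject_id for h in passing if h.bit_score == best)
    return winners[0], len(winners) > 1


def midpoint_on_target(start: int, end: int, targets) -> bool:
    """Linear-scan midpoint membership over (start, end) 0-based half-open
    target tuples."""
    mid = (start + end) // 2
    return any(lo <= mid < hi for lo, hi in targets)
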