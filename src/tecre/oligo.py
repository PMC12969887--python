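"""Ungapped nucleotide alignment scoring with Karlin-Altschul bit conversion.

Used to assess how specific a short oligonucleotide (e.g. an shRNA guide) is
for its intended transcript versus the rest of a transcript set: the best
ungapped local segment pair is found on every diagonal of query x target
(both strands), and its raw score S is normalized to bits via
``(lambda*S - ln K) / ln 2``. Defaults are the standard ungapped
Karlin-Altschul constants for +1/-3 nucleotide scoring: lambda = 1.374,
K = 0.711. No E-values: the comparison needs bits only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Seq import reverse_complement

DEFAULT_REWARD = 1
DEFAULT_PENALTY = -3
DEFAULT_LAMBDA = 1.374
DEFAULT_K = 0.711


@dataclass(frozen=True)
class UngappedHit:
    query_id: str
    target_id: str
    raw_score: int
    match_len: int
    identity: float
    strand: str
    bits: float


def _best_segment_score(
    q: np.ndarray, t: np.ndarray, reward: int, penalty: int
) -> tuple[int, int, float]:
    """Best ungapped segment over all diagonals (max-subarray per diagonal).

    Returns (raw score, segment length, identity over the best segment).
    """
    nq, nt = len(q), len(t)
    best = (0, 0, 0.0)
    for shift in range(-(nq - 1), nt):
        lo = max(0, -shift)
        hi = min(nq, nt - shift)
        if hi <= lo:
            continue
        eq = q[lo:hi] == t[lo + shift : hi + shift]
        run_score = 0
        run_len = 0
        run_match = 0
        for is_match in eq:
            step = reward if is_match else penalty
            if run_score + step <= 0:
                run_score, run_len, run_match = 0, 0, 0
            else:
                run_score += step
                run_len += 1
                run_match += int(is_match)
            if run_score > best[0]:
                best = (
                    run_score,
                    run_len,
                    run_match / run_len if run_len else 0.0,
                )
    return best


def best_ungapped_hit(
    query: str,
    target: str,
    reward: int = DEFAULT_REWARD,
    penalty: int = DEFAULT_PENALTY,
    lam: float = DEFAULT_LAMBDA,
    k_const: float = DEFAULT_K,
    query_id: str = "query",
    target_id: str = "target",
) -> UngappedHit:
    """Maximal-scoring ungapped local segment pair over both target strands.

    Score = reward*matches + penalty*mismatches, never negative; a perfect
    n-nt match under +1 scoring yields S = n.
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    if not (reward > 0 > penalty):
        raise ValueError("require reward > 0 > penalty")
    q = np.frombuffer(query.upper().encode(), dtype="S1")
    fwd = np.frombuffer(target.upper().encode(), dtype="S1")
    rev = np.frombuffer(reverse_complement(target.upper()).encode(), dtype="S1")
    s_fwd = _best_segment_score(q, fwd, reward, penalty)
    s_rev = _best_segment_score(q, rev, reward, penalty)
    strand = "+" if s_fwd >= s_rev else "-"
    score, length, ident = s_fwd if strand == "+" else s_rev
    return UngappedHit(
        query_id=query_id,
        target_id=target_id,
        raw_score=score,
        match_len=length,
        identity=ident,
        strand=strand,
        bits=karlin_altschul_bits(score, lam, k_const),
    )


def karlin_altschul_bits(
    raw_score: float, lam: float = DEFAULT_LAMBDA, k_const: float = DEFAULT_K
) -> float:
    """bits = (lambda*S - ln K) / ln 2; strictly increasing and affine in S."""
    if lam <= 0 or k_const <= 0:
        raise ValueError("lambda and K must be positive")
    return (lam * raw_score - math.log(k_const)) / math.log(2)


def specificity_report(
    query: str,
    targets: dict[str, str],
    reward: int = DEFAULT_REWARD,
    penalty: int = DEFAULT_PENALTY,
    lam: float = DEFAULT_LAMBDA,
    k_const: float = DEFAULT_K,
    query_id: str = "query",
    specific_margin_bits: float = 5.0,
) -> tuple[list[UngappedHit], bool | None]:
    """One hit per target, sorted by bits descending (ties by target id),
    plus a specificity flag: the top hit beats the runner-up by at least
    ``specific_margin_bits`` (None with a single target)."""
    if not query:
        raise ValueError("empty query")
    if not targets:
        raise ValueError("need >= 1 target")
    hits = [
        best_ungapped_hit(
            query, seq, reward, penalty, lam, k_const,
            query_id=query_id, target_id=tid,
        )
        for tid, seq in targets.items()
    ]
    hits.sort(key=lambda h: (-h.bits, h.target_id))
    if len(hits) == 1:
        return hits, None
    return hits, (hits[0].bits - hits[1].bits) >= specific_margin_bits
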