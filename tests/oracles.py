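"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by the most literal method available —
full DP matrices, linear scans, exhaustive enumeration — and never calls
the code path it checks.
"""

from __future__ import annotations

import numpy as np

NEG = float("-inf")


def overlap_affine_score(t: str, q: str, match: float = 2.0,
                         mismatch: float = -3.0, open_: float = -5.0,
                         extend: float = -2.0) -> float:
    """Optimal semi-global (dovetail) affine-gap alignment score by full
    dynamic programming.

    A gap of length L costs ``open_ + (L-1)*extend``; a terminal gap in
    *one* sequence at each end is free (leading/trailing overhangs), so the
    floor is an all-end-gap alignment of score 0.
    """
    m, n = len(t), len(q)
    M = np.full((m + 1, n + 1), NEG)  # t[i-1] aligned to q[j-1]
    X = np.full((m + 1, n + 1), NEG)  # paid gap in q (consuming t)
    Y = np.full((m + 1, n + 1), NEG)  # paid gap in t (consuming q)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if t[i - 1] == q[j - 1] else mismatch
            start = 0.0 if (i == 1 or j == 1) else NEG  # free leading overhang
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1],
                              Y[i - 1][j - 1], start)
            from_free_x = 0.0 + open_ if i == 1 else NEG
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend,
                          Y[i - 1][j] + open_, from_free_x)
            from_free_y = 0.0 + open_ if j == 1 else NEG
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend,
                          X[i][j - 1] + open_, from_free_y)
    best = 0.0  # empty overlap: both sequences end-gapped
    for i in range(1, m + 1):  # free trailing overhang of t
        best = max(best, M[i][n], X[i][n], Y[i][n])
    for j in range(1, n + 1):  # free trailing overhang of q
        best = max(best, M[m][j], X[m][j], Y[m][j])
    return best


def flow_index_by_scan(flow_values, flow_order: str) -> list[int]:
    """Re-derive flow_index_per_base by scanning rounded flow signals."""
    out: list[int] = []
    for f, v in enumerate(flow_values, start=1):
        k = int(np.floor(v / 100.0 + 0.5))
        out.extend([f] * k)
    return out


def homopolymer_run_by_scan(reference: str, anchor: int) -> tuple[int, int]:
    """Maximal run of identical bases containing ``anchor`` (linear scan)."""
    base = reference[anchor]
    start = anchor
    while start > 0 and reference[start - 1] == base:
        start -= 1
    end = anchor + 1
    while end < len(reference) and reference[end] == base:
        end += 1
    return start, end


def apply_edit(seq: str, pos: int, ref: str, alt: str) -> str:
    assert seq[pos:pos + len(ref)] == ref
    return seq[:pos] + alt + seq[pos + len(ref):]


def rightmost_placement(seq: str, pos: int, ref: str, alt: str,
                        window: int = 50) -> tuple[int, str, str]:
    """3'-most equivalent placement of a pure indel by exhaustive search.

    Enumerates candidate positions around ``pos`` and keeps the rightmost
    whose edit yields the identical mutated sequence.
    """
    mutated = apply_edit(seq, pos, ref, alt)
    L = len(ref) or len(alt)
    best = (pos, ref, alt)
    for p in range(max(0, pos - window), min(len(seq), pos + window) + 1):
        if ref:  # deletion
            cand_ref = seq[p:p + L]
            if len(cand_ref) == L and apply_edit(seq, p, cand_ref, "") == mutated:
                best = max(best, (p, cand_ref, ""), key=lambda x: x[0])
        else:    # insertion before p
            if p + L <= len(mutated):
                cand_alt = mutated[p:p + L]
                if apply_edit(seq, p, "", cand_alt) == mutated:
                    best = max(best, (p, "", cand_alt), key=lambda x: x[0])
    return best


def filter_decision_literal(support_f: int, support_r: int,
                            cov_f: int, cov_r: int, fraction: float,
                            min_reads: int, min_fraction: float,
                            require_both: bool) -> str:
    """The screening rules transcribed as literally as possible."""
    if support_f + support_r < min_reads:
        return "rejected_support"
    if require_both:
        only_one_strand_covered = (cov_f == 0) or (cov_r == 0)
        present_on_both = support_f > 0 and support_r > 0
        if not present_on_both and not only_one_strand_covered:
            return "rejected_strand"
        # exemption applies, unless the covered strand itself lacks support
        if only_one_strand_covered:
            if cov_f > 0 and support_f == 0:
                return "rejected_strand"
            if cov_r > 0 and support_r == 0:
                return "rejected_strand"
    if fraction < min_fraction:
        return "rejected_frequency"
    return "validated"
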