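"""Global pairwise and progressive multiple alignment.

The pairwise aligner is a Gotoh affine-gap dynamic program over a
substitution matrix (BLOSUM62 by default) with a deterministic traceback
(tie order: diagonal > up > left). The progressive MSA builds a UPGMA guide
tree from pairwise p-distances and merges profiles in guide-tree order,
scoring profile columns by expected pairwise substitution score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage

_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {a: i for i, a in enumerate(_ALPHABET)}
GAP = "-"


@dataclass(frozen=True)
class ScoreParams:
    """Substitution matrix name and affine gap costs.

    The first residue of a gap costs ``gap_open``; each subsequent residue
    costs ``gap_extend`` (Biopython's open/extend convention).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0


def _submatrix(params: ScoreParams) -> np.ndarray:
    m = substitution_matrices.load(params.matrix)
    out = np.zeros((len(_ALPHABET), len(_ALPHABET)))
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            out[i, j] = m[a, b]
    return out


def encode(seq: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))


def _affine_dp(S: np.ndarray, go: float, ge: float):
    """Gotoh DP over a precomputed position-score matrix S (n x m).

    Returns (score, path) where path is a list of (i, j) moves with i/j in
    {0,1} marking whether a row/column of S is consumed at each step.
    Traceback prefers diagonal, then up (gap in the second sequence), then
    left.
    """
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in second seq (up moves)
    Y = np.full((n + 1, m + 1), NEG)  # gap in first seq (left moves)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + ge * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = go + ge * (j - 1)
    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Si = S[i - 1]
        # X depends only on the previous row: vectorize
        Xi[1:] = np.maximum(Mi1[1:] + go, np.maximum(Xi1[1:] + ge, Yi1[1:] + go))
        Xi[0] = X[i, 0]
        for j in range(1, m + 1):
            best_prev = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Mi[j] = best_prev + Si[j - 1]
            Yi[j] = max(Mi[j - 1] + go, Yi[j - 1] + ge, Xi[j - 1] + go)
    score = max(M[n, m], X[n, m], Y[n, m])

    # traceback
    path = []
    i, j = n, m
    # deterministic preference on equal scores: M (diagonal) > X (up) > Y (left)
    if M[n, m] >= X[n, m] and M[n, m] >= Y[n, m]:
        state = "M"
    elif X[n, m] >= Y[n, m]:
        state = "X"
    else:
        state = "Y"
    while i > 0 or j > 0:
        if state == "M":
            path.append((1, 1))
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            if prev[0] >= prev[1] and prev[0] >= prev[2]:
                state = "M"
            elif prev[1] >= prev[2]:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            path.append((1, 0))
            v = X[i, j]
            if i > 1 and abs(X[i - 1, j] + ge - v) < 1e-9:
                state = "X"
            elif abs(M[i - 1, j] + go - v) < 1e-9:
                state = "M"
            elif abs(X[i - 1, j] + ge - v) < 1e-9:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:
            path.append((0, 1))
            v = Y[i, j]
            if abs(M[i, j - 1] + go - v) < 1e-9:
                state = "M"
            elif abs(Y[i, j - 1] + ge - v) < 1e-9:
                state = "Y"
            else:
                state = "X"
            j -= 1
        if i == 0 and j == 0:
            break
    path.reverse()
    return float(score), path


def pairwise_align(seq_a: str, seq_b: str,
                   score_params: Optional[ScoreParams] = None):
    """Optimal global alignment of two sequences.

    Returns (aligned_a, aligned_b, score). Deterministic traceback with tie
    order diagonal > up > left.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_align requires non-empty sequences")
    params = score_params or ScoreParams()
    sub = _submatrix(params)
    ea, eb = encode(seq_a), encode(seq_b)
    S = sub[np.ix_(ea, eb)]
    score, path = _affine_dp(S, params.gap_open, params.gap_extend)
    out_a, out_b = [], []
    i = j = 0
    for di, dj in path:
        out_a.append(seq_a[i] if di else GAP)
        out_b.append(seq_b[j] if dj else GAP)
        i += di
        j += dj
    return "".join(out_a), "".join(out_b), score


def _profile_freqs(rows: list[str], sub_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Residue-frequency matrix (L x alphabet) and gap fraction per column."""
    L = len(rows[0])
    freqs = np.zeros((L, sub_size))
    gaps = np.zeros(L)
    for row in rows:
        for c, ch in enumerate(row):
            if ch == GAP:
                gaps[c] += 1
            else:
                freqs[c, _AA_INDEX[ch]] += 1
    k = len(rows)
    return freqs / k, gaps / k


def _merge_profiles(rows_a: list[str], rows_b: list[str], sub: np.ndarray,
                    params: ScoreParams) -> list[str]:
    fa, _ = _profile_freqs(rows_a, sub.shape[0])
    fb, _ = _profile_freqs(rows_b, sub.shape[0])
    S = fa @ sub @ fb.T  # expected pairwise substitution score per column pair
    _, path = _affine_dp(S, params.gap_open, params.gap_extend)
    out = []
    for row in rows_a:
        i = 0
        built = []
        for di, _dj in path:
            built.append(row[i] if di else GAP)
            i += di
        out.append("".join(built))
    for row in rows_b:
        j = 0
        built = []
        for _di, dj in path:
            built.append(row[j] if dj else GAP)
            j += dj
        out.append("".join(built))
    return out


def alignment_pdistance(rows: Sequence[str]) -> np.ndarray:
    """p-distance matrix with pairwise deletion of gapped columns."""
    arr = np.array([[_AA_INDEX.get(c, -1) if c != GAP else -1 for c in row]
                    for row in rows], dtype=np.int64)
    k = arr.shape[0]
    valid = arr >= 0
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            both = valid[i] & valid[j]
            n = int(both.sum())
            if n == 0:
                d[i, j] = d[j, i] = 1.0
            else:
                diff = int(((arr[i] != arr[j]) & both).sum())
                d[i, j] = d[j, i] = diff / n
    return d


def progressive_msa(records, score_params: Optional[ScoreParams] = None) -> list:
    """Progressive multiple alignment.

    ``records`` is a sequence of objects with ``id`` and ``sequence``
    attributes (or (id, sequence) pairs). Returns a list of (id,
    aligned_sequence) in input order. Guide tree: UPGMA over pairwise
    p-distances from global pairwise alignments.
    """
    params = score_params or ScoreParams()
    items = [(r[0], r[1]) if isinstance(r, tuple) else (r.id, r.sequence)
             for r in records]
    if len(items) == 1:
        return [items[0]]
    if len(items) == 2:
        a, b, _ = pairwise_align(items[0][1], items[1][1], params)
        return [(items[0][0], a), (items[1][0], b)]

    sub = _submatrix(params)
    k = len(items)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b, _ = pairwise_align(items[i][1], items[j][1], params)
            dist[i, j] = dist[j, i] = alignment_pdistance([a, b])[0, 1]
    condensed = dist[np.triu_indices(k, 1)]
    Z = linkage(condensed, method="average")

    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [items[i][1]]) for i in range(k)
    }
    for step, (a, b, _, _) in enumerate(Z):
        ia, ib = int(a), int(b)
        idx_a, rows_a = clusters.pop(ia)
        idx_b, rows_b = clusters.pop(ib)
        merged = _merge_profiles(rows_a, rows_b, sub, params)
        clusters[k + step] = (idx_a + idx_b, merged)
    (order, rows), = clusters.values()
    by_index = dict(zip(order, rows))
    return [(items[i][0], by_index[i]) for i in range(k)]
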