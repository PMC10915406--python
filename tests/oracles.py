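"""Independent brute-force oracles used to validate the library's
implementations. Each is written in the most literal way possible (explicit
loops, full DP tables, direct enumeration) and shares no code with the
package.
"""

from itertools import combinations

import numpy as np


def sw_score_bruteforce(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Smith-Waterman optimal local score via the full Gotoh DP table.

    A gap of length k costs gap_open + (k - 1) * gap_extend.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def sw_similarity_bruteforce(a: str, b: str, matrix, gap_open=11.0, gap_extend=1.0) -> float:
    ab = sw_score_bruteforce(a, b, matrix, gap_open, gap_extend)
    aa = sw_score_bruteforce(a, a, matrix, gap_open, gap_extend)
    bb = sw_score_bruteforce(b, b, matrix, gap_open, gap_extend)
    return ab / (aa * bb) ** 0.5


def auroc_bruteforce(labels, scores) -> float:
    """All-pairs concordance count with ties worth 0.5."""
    labels = list(labels)
    scores = list(scores)
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def aupr_bruteforce(labels, scores) -> float:
    """Average precision by enumerating the step curve at every distinct
    score threshold, descending."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        called = scores >= t
        tp = float(np.sum(labels[called] == 1))
        precision = tp / float(np.sum(called))
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def aoie_bruteforce(matrix) -> float:
    """Pairwise-concordance enumeration per column against the leave-one-out
    row-sum ordering; ties 0.5; columns without a rankable pair contribute
    0.5."""
    m = np.asarray(matrix, dtype=float)
    n_e, n_c = m.shape
    totals = [np.nansum(m[i]) for i in range(n_e)]
    col_scores = []
    for j in range(n_c):
        g = []
        for i in range(n_e):
            cell = m[i, j]
            g.append(totals[i] - (0.0 if np.isnan(cell) else cell))
        pairs = []
        for i, k in combinations(range(n_e), 2):
            if np.isnan(m[i, j]) or np.isnan(m[k, j]):
                continue
            dv = m[i, j] - m[k, j]
            dg = g[i] - g[k]
            if dv == 0 or dg == 0:
                pairs.append(0.5)
            elif (dv > 0) == (dg > 0):
                pairs.append(1.0)
            else:
                pairs.append(0.0)
        col_scores.append(sum(pairs) / len(pairs) if pairs else 0.5)
    return sum(col_scores) / len(col_scores)


def aoic_bruteforce(matrix) -> float:
    return aoie_bruteforce(np.asarray(matrix, dtype=float).T)


def pearson_bruteforce(x, y):
    """Closed-form r and two-sided t-distribution p-value via scipy's
    distribution function only."""
    from scipy.stats import t as tdist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xm, ym = x - x.mean(), y - y.mean()
    r = float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return r, float(2 * tdist.sf(abs(t), n - 2))
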