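"""Independent reference implementations used as test oracles.

Deliberately naive (explicit loops, textbook formulas) and kept separate
from the package code paths they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps

NEG = float("-inf")


def sw_score_oracle(q: str, t: str, match: int, mismatch: int, gap_open: int, gap_extend: int) -> int:
    """Full O(nm) Gotoh local-alignment DP over plain Python lists.

    Gap of length L costs gap_open + (L-1) * gap_extend.
    """
    n, m = len(q), len(t)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if q[i - 1] == t[j - 1] else mismatch
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def j_anchor_scan_oracle(seq: str) -> int | None:
    """First offset whose 12-mer translates to [FW]-G-X-G (any frame)."""
    for off in range(len(seq) - 11):
        block = seq[off : off + 12]
        aa = "".join(GENETIC_CODE[block[k : k + 3]] for k in range(0, 12, 3))
        if aa[0] in "FW" and aa[1] == "G" and aa[3] == "G":
            return off
    return None


def d50_oracle(counts) -> float:
    """Cumulative-sum walk over counts sorted descending."""
    srt = sorted(counts, reverse=True)
    total = sum(srt)
    acc = 0
    for k, c in enumerate(srt, start=1):
        acc += c
        if 2 * acc >= total:
            return 100.0 * k / len(srt)
    raise AssertionError("unreachable")


def roc_auc_oracle(scores, labels) -> float:
    """Pairwise-concordance enumeration, ties counted one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    acc = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                acc += 1.0
            elif p == q:
                acc += 0.5
    return acc / (len(pos) * len(neg))


def welch_t_oracle(a, b) -> tuple[float, float]:
    """Textbook Welch t and two-sided p with Welch-Satterthwaite df."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    t = (a.mean() - b.mean()) / np.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def chi_square_oracle(table) -> float:
    """Sum of (O-E)^2/E over the 2x2 table."""
    o = np.asarray(table, float)
    row = o.sum(axis=1)
    col = o.sum(axis=0)
    total = o.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = row[i] * col[j] / total
            stat += (o[i, j] - e) ** 2 / e
    return float(stat)


def permanova_f_oracle(dist: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F via Gower-centered matrix and hat-matrix traces (McArdle-Anderson)."""
    n = dist.shape[0]
    a = len(np.unique(labels))
    A = -0.5 * dist**2
    C = np.eye(n) - np.ones((n, n)) / n
    G = C @ A @ C
    X = np.zeros((n, a))
    for k, g in enumerate(np.unique(labels)):
        X[labels == g, k] = 1.0
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    ss_between = np.trace(H @ G @ H)
    resid = np.eye(n) - H
    ss_within = np.trace(resid @ G @ resid)
    return float((ss_between / (a - 1)) / (ss_within / (n - a)))


def permanova_exhaustive_oracle(dist: np.ndarray, n_case: int) -> tuple[float, float]:
    """(observed F, exhaustive p) with cases assumed to be the first n_case rows."""
    n = dist.shape[0]
    obs_labels = np.array([0] * n_case + [1] * (n - n_case))
    f_obs = permanova_f_oracle(dist, obs_labels)
    ge = 0
    count = 0
    for idx in combinations(range(n), n_case):
        lab = np.ones(n, int)
        lab[list(idx)] = 0
        count += 1
        if permanova_f_oracle(dist, lab) >= f_obs - 1e-12:
            ge += 1
    return f_obs, ge / count


def pca_scores_oracle(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Scores/explained-variance via eigendecomposition of the scatter matrix."""
    centered = x - x.mean(axis=0)
    scatter = centered.T @ centered
    w, v = np.linalg.eigh(scatter)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    scores = centered @ v[:, :k]
    return scores, w[:k] / w.sum()
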