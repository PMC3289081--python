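"""Needleman-Wunsch dynamic programming (maximization, linear gap model).

Shared by the sphere-neighborhood alignment (zero gap cost, where NW
degenerates to a maximum-weight order-preserving matching) and by the
global structure alignment (log-probability scores, constant negative
gap penalty).  Traceback is deterministic: match is preferred over
advancing in the first sequence, which is preferred over advancing in
the second.
"""

from __future__ import annotations

import numpy as np


def nw_score(S: np.ndarray, gap: float) -> float:
    """Optimal global alignment score only (no traceback)."""
    n, m = S.shape
    if n == 0 or m == 0:
        return gap * (n + m)
    H = np.empty((n + 1, m + 1))
    H[0, :] = gap * np.arange(m + 1)
    H[:, 0] = gap * np.arange(n + 1)
    for i in range(1, n + 1):
        Hi, Hp, Si = H[i], H[i - 1], S[i - 1]
        for j in range(1, m + 1):
            d = Hp[j - 1] + Si[j - 1]
            u = Hp[j] + gap
            l = Hi[j - 1] + gap
            Hi[j] = d if d >= u and d >= l else (u if u >= l else l)
    return float(H[n, m])


def nw_align(S: np.ndarray, gap: float) -> tuple[list[tuple[int, int]], float]:
    """Optimal global alignment: (pairs, score).

    Pairs are strictly increasing in both coordinates.  Entries of ``S``
    equal to ``-inf`` forbid the corresponding match.
    """
    n, m = S.shape
    if n == 0 or m == 0:
        return [], gap * (n + m)
    H = np.empty((n + 1, m + 1))
    H[0, :] = gap * np.arange(m + 1)
    H[:, 0] = gap * np.arange(n + 1)
    for i in range(1, n + 1):
        Hi, Hp, Si = H[i], H[i - 1], S[i - 1]
        for j in range(1, m + 1):
            d = Hp[j - 1] + Si[j - 1]
            u = Hp[j] + gap
            l = Hi[j - 1] + gap
            Hi[j] = d if d >= u and d >= l else (u if u >= l else l)
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 and j > 0:
        h = H[i, j]
        if h == H[i - 1, j - 1] + S[i - 1, j - 1]:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif h == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs, float(H[n, m])
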