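"""Low-level matching-statistics engine.

A suffix automaton (DAWG) over the subject recognises exactly the set of
substrings of the subject; scanning the query against it yields, for every
query position, the length of the longest subject substring ending there.
Building the automaton over the *reversed* subject and scanning the
*reversed* query therefore yields per-start matching statistics: the length
of the longest prefix of each query suffix that occurs somewhere in the
subject.  Construction and scan are both linear in sequence length.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["build_automaton", "matching_statistics_from_automaton"]


@njit(cache=True)
def _build(s):  # pragma: no cover - exercised via build_automaton
    n = s.shape[0]
    max_states = 2 * n + 5
    trans = np.full((max_states, 4), -1, dtype=np.int32)
    link = np.empty(max_states, dtype=np.int32)
    length = np.zeros(max_states, dtype=np.int32)
    link[0] = -1
    size = 1
    last = 0
    for idx in range(n):
        c = s[idx]
        cur = size
        size += 1
        length[cur] = length[last] + 1
        link[cur] = -1
        p = last
        while p != -1 and trans[p, c] == -1:
            trans[p, c] = cur
            p = link[p]
        if p == -1:
            link[cur] = 0
        else:
            q = trans[p, c]
            if length[p] + 1 == length[q]:
                link[cur] = q
            else:
                clone = size
                size += 1
                length[clone] = length[p] + 1
                link[clone] = link[q]
                for a in range(4):
                    trans[clone, a] = trans[q, a]
                while p != -1 and trans[p, c] == q:
                    trans[p, c] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        last = cur
    return trans[:size], link[:size], length[:size]


@njit(cache=True)
def _scan(trans, link, length, q):  # pragma: no cover
    m = q.shape[0]
    out = np.empty(m, dtype=np.int64)
    v = 0
    l = 0
    for j in range(m):
        c = q[j]
        while v != 0 and trans[v, c] == -1:
            v = link[v]
            l = length[v]
        if trans[v, c] != -1:
            v = trans[v, c]
            l += 1
        else:
            l = 0
        out[j] = l
    return out


def build_automaton(codes: np.ndarray):
    """Build a suffix automaton over ``codes`` (uint8 values in 0..3).

    Returns an opaque triple of arrays consumed by
    :func:`matching_statistics_from_automaton`.
    """
    if codes.size == 0:
        raise ValueError("cannot index an empty sequence")
    return _build(np.ascontiguousarray(codes, dtype=np.uint8))


def matching_statistics_from_automaton(automaton, query_codes: np.ndarray) -> np.ndarray:
    """Longest match ending at each position of ``query_codes``."""
    trans, link, length = automaton
    return _scan(trans, link, length, np.ascontiguousarray(query_codes, dtype=np.uint8))
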