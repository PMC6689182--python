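"""Simplified Zuker-style MFE dynamic program.

Energy model (see ``params`` for the constants):

* stack term for two adjacent base pairs (Watson-Crick published values,
  flat simplified values for wobble-containing stacks),
* hairpin loops: ``HAIRPIN_A + HAIRPIN_B * loop_size`` (loop >= 3 nt),
* bulge/interior loops: ``INTERIOR_A + INTERIOR_B * unpaired`` with at most
  ``MAX_INTERIOR`` unpaired nt,
* multiloops: ``MULTI_A + MULTI_B * unpaired + MULTI_C * branches``,
* exterior unpaired nucleotides are free; no dangles, no coaxial stacking.

The matrix fill is numba-jitted when numba is importable and falls back to the
identical pure-Python code otherwise. Traceback reads the filled matrices and
re-derives the optimal choices in a fixed preference order (stack, then
interior with the 5'-most inner pair, then multibranch with the 5'-most split,
then hairpin) so co-optimal structures resolve deterministically.
"""

from __future__ import annotations

import numpy as np

from .params import (
    HAIRPIN_A,
    HAIRPIN_B,
    INTERIOR_A,
    INTERIOR_B,
    MAX_INTERIOR,
    MIN_HAIRPIN,
    MULTI_A,
    MULTI_B,
    MULTI_C,
    PAIRABLE,
    STACK,
    encode,
)

INF = 1e30
_EPS = 1e-9


def _fill(s, pairable, stack, V, WM):  # noqa: C901 - hot loop kept flat
    n = s.shape[0]
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            # ---- V[i, j]: minimum energy given i pairs j
            v = INF
            if pairable[s[i], s[j]] and j - i - 1 >= MIN_HAIRPIN:
                v = HAIRPIN_A + HAIRPIN_B * (j - i - 1)
                # stacked pair
                if j - i - 1 >= MIN_HAIRPIN + 2 and V[i + 1, j - 1] < INF:
                    cand = stack[s[i], s[j], s[i + 1], s[j - 1]] + V[i + 1, j - 1]
                    if cand < v:
                        v = cand
                # bulge / interior loops (>=1 unpaired total, capped)
                kmax = min(i + MAX_INTERIOR + 1, j - 1)
                for k in range(i + 1, kmax + 1):
                    u1 = k - i - 1
                    for l in range(j - 1, k, -1):
                        u2 = j - l - 1
                        if u1 + u2 == 0:
                            continue
                        if u1 + u2 > MAX_INTERIOR:
                            break
                        if V[k, l] < INF:
                            cand = INTERIOR_A + INTERIOR_B * (u1 + u2) + V[k, l]
                            if cand < v:
                                v = cand
                # multibranch closure (>= 2 branches inside); each side of the
                # split needs room for a branch (span >= MIN_HAIRPIN + 1)
                for k in range(i + MIN_HAIRPIN + 3, j - MIN_HAIRPIN - 2):
                    if WM[i + 1, k - 1] < INF and WM[k, j - 1] < INF:
                        cand = MULTI_A + WM[i + 1, k - 1] + WM[k, j - 1]
                        if cand < v:
                            v = cand
            V[i, j] = v
            # ---- WM[i, j]: >= 1 branch inside a multiloop
            w = INF
            if WM[i + 1, j] < INF:
                w = WM[i + 1, j] + MULTI_B
            if j - 1 >= i and WM[i, j - 1] < INF:
                cand = WM[i, j - 1] + MULTI_B
                if cand < w:
                    w = cand
            if V[i, j] < INF:
                cand = V[i, j] + MULTI_C
                if cand < w:
                    w = cand
            for k in range(i + MIN_HAIRPIN + 2, j - MIN_HAIRPIN - 1):
                if WM[i, k - 1] < INF and WM[k, j] < INF:
                    cand = WM[i, k - 1] + WM[k, j]
                    if cand < w:
                        w = cand
            WM[i, j] = w


def _exterior(V, n, W):
    # exterior array shifted by one: W[k] = MFE over the prefix of length k
    W[0] = 0.0
    for k in range(1, n + 1):
        j = k - 1
        best = W[k - 1]
        for i in range(k):
            if V[i, j] < INF:
                cand = (W[i] if i > 0 else 0.0) + V[i, j]
                if cand < best:
                    best = cand
        W[k] = best


def _batch(seq_codes, starts, length, pairable, stack, out):
    V = np.full((length, length), INF, dtype=np.float64)
    WM = np.full((length, length), INF, dtype=np.float64)
    W = np.zeros(length + 1, dtype=np.float64)
    for idx in range(starts.shape[0]):
        window = seq_codes[starts[idx] : starts[idx] + length]
        V[:] = INF
        WM[:] = INF
        _fill(window, pairable, stack, V, WM)
        _exterior(V, length, W)
        e = W[length]
        out[idx] = e if e < 0.0 else 0.0


try:  # pragma: no cover - exercised indirectly
    import numba

    _fill = numba.njit(cache=True)(_fill)
    _exterior = numba.njit(cache=True)(_exterior)
    _batch = numba.njit(cache=True)(_batch)
except Exception:  # numba unavailable: pure-Python fallback
    pass


def _matrices(seq_codes: np.ndarray):
    n = seq_codes.shape[0]
    V = np.full((n, n), INF, dtype=np.float64)
    WM = np.full((n, n), INF, dtype=np.float64)
    _fill(seq_codes, PAIRABLE, STACK, V, WM)
    W = np.zeros(n + 1, dtype=np.float64)
    _exterior(V, n, W)
    return V, WM, W


def mfe_energy(seq: str) -> float:
    """MFE of the builtin model; 0.0 when no structure has negative energy."""
    if len(seq) < 2:
        return 0.0
    _, _, W = _matrices(encode(seq))
    return float(min(W[len(seq)], 0.0))


def mfe_energies_batch(seq_codes: np.ndarray, starts: np.ndarray, length: int) -> np.ndarray:
    """MFE for each window ``seq[start:start+length]``; energy-only, fast path."""
    out = np.empty(len(starts), dtype=np.float64)
    if len(starts):
        _batch(seq_codes, np.asarray(starts, dtype=np.int64), length, PAIRABLE, STACK, out)
    return out


# ---------------------------------------------------------------------------
# Traceback


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= _EPS


def _trace_v(s, V, WM, i, j, pairs) -> None:
    pairs.append((i, j))
    v = V[i, j]
    if j - i - 1 >= MIN_HAIRPIN + 2 and V[i + 1, j - 1] < INF:
        if _close(v, STACK[s[i], s[j], s[i + 1], s[j - 1]] + V[i + 1, j - 1]):
            _trace_v(s, V, WM, i + 1, j - 1, pairs)
            return
    kmax = min(i + MAX_INTERIOR + 1, j - 1)
    for k in range(i + 1, kmax + 1):
        u1 = k - i - 1
        for l in range(j - 1, k, -1):
            u2 = j - l - 1
            if u1 + u2 == 0 or u1 + u2 > MAX_INTERIOR:
                continue
            if V[k, l] < INF and _close(v, INTERIOR_A + INTERIOR_B * (u1 + u2) + V[k, l]):
                _trace_v(s, V, WM, k, l, pairs)
                return
    for k in range(i + MIN_HAIRPIN + 3, j - MIN_HAIRPIN - 2):
        if WM[i + 1, k - 1] < INF and WM[k, j - 1] < INF:
            if _close(v, MULTI_A + WM[i + 1, k - 1] + WM[k, j - 1]):
                _trace_wm(s, V, WM, i + 1, k - 1, pairs)
                _trace_wm(s, V, WM, k, j - 1, pairs)
                return
    # hairpin: nothing further to trace


def _trace_wm(s, V, WM, i, j, pairs) -> None:
    w = WM[i, j]
    if V[i, j] < INF and _close(w, V[i, j] + MULTI_C):
        _trace_v(s, V, WM, i, j, pairs)
        return
    for k in range(i + MIN_HAIRPIN + 2, j - MIN_HAIRPIN - 1):
        if WM[i, k - 1] < INF and WM[k, j] < INF and _close(w, WM[i, k - 1] + WM[k, j]):
            _trace_wm(s, V, WM, i, k - 1, pairs)
            _trace_wm(s, V, WM, k, j, pairs)
            return
    if WM[i + 1, j] < INF and _close(w, WM[i + 1, j] + MULTI_B):
        _trace_wm(s, V, WM, i + 1, j, pairs)
        return
    if j - 1 >= i and WM[i, j - 1] < INF and _close(w, WM[i, j - 1] + MULTI_B):
        _trace_wm(s, V, WM, i, j - 1, pairs)
        return
    raise AssertionError("traceback failed in WM")  # pragma: no cover


def mfe_fold(seq: str) -> tuple[float, str]:
    """MFE energy and one deterministic co-optimal dot-bracket structure."""
    n = len(seq)
    if n < 2:
        return 0.0, "." * n
    s = encode(seq)
    V, WM, W = _matrices(s)
    dg = float(W[n])
    if dg > -_EPS:
        return 0.0, "." * n
    pairs: list[tuple[int, int]] = []
    # exterior traceback, preferring the 5'-most pairing split
    segments = []
    k = n
    while k > 0:
        target = W[k]
        chosen = None
        for i in range(k):  # 5'-most pair first
            if V[i, k - 1] < INF and _close(target, (W[i] if i > 0 else 0.0) + V[i, k - 1]):
                chosen = i
                break
        if chosen is not None:
            segments.append((chosen, k - 1))
            k = chosen
        else:
            k -= 1
    for i, jj in segments:
        _trace_v(s, V, WM, i, jj, pairs)
    db = ["."] * n
    for a, b in pairs:
        db[a], db[b] = "(", ")"
    return dg, "".join(db)
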