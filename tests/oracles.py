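"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by a different route than the library
(regex scans, run-length encoding, exhaustive tail sums, sort-and-index
percentiles) so agreement is informative.
"""

from __future__ import annotations

import re
from math import comb

import numpy as np


def choi_nonwear_oracle(counts, window=90, spike_tolerance=2, flank=30) -> np.ndarray:
    """Regex-based non-wear scan: maximal zero runs absorbing short spikes
    flanked by >= ``flank`` zeros, kept when the total run >= ``window``."""
    s = "".join("z" if c == 0 else "n" for c in counts)
    pat = re.compile(
        rf"z+(?:(?<=z{{{flank}}})n{{1,{spike_tolerance}}}(?=z{{{flank}}})z+)*"
    )
    nonwear = np.zeros(len(s), dtype=bool)
    for m in pat.finditer(s):
        if m.end() - m.start() >= window:
            nonwear[m.start() : m.end()] = True
    return nonwear


def rle_bouts_oracle(posture, wear) -> list[int]:
    """Run-length encoding of sit-labelled wear minutes."""
    flags = [str(p) == "sit" and bool(w) for p, w in zip(posture, wear)]
    out, run = [], 0
    for f in flags:
        if f:
            run += 1
        elif run:
            out.append(run)
            run = 0
    if run:
        out.append(run)
    return out


def quartile_oracle(values) -> np.ndarray:
    """Sort-and-index percentile assignment with linear interpolation."""
    v = np.asarray(values, dtype=float)
    srt = np.sort(v)
    n = len(srt)

    def pct(p):
        h = (n - 1) * p / 100.0
        lo = int(np.floor(h))
        hi = int(np.ceil(h))
        return srt[lo] + (h - lo) * (srt[hi] - srt[lo])

    q1, q2, q3 = pct(25), pct(50), pct(75)
    out = np.ones(n, dtype=int)
    out += v > q1
    out += v > q2
    out += v > q3
    return out


def hypergeom_tail_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p: sum of hypergeometric pmf over overlaps >= a.

    Table rows are (in pathway & query, in pathway only) and
    (query only, neither); margins K = a+b (pathway), n = a+c (query),
    M = a+b+c+d (universe).
    """
    M, K, n = a + b + c + d, a + b, a + c
    denom = comb(M, n)
    p = 0.0
    for k in range(a, min(K, n) + 1):
        p += comb(K, k) * comb(M - K, n - k) / denom
    return p


def delta_ct_oracle(ct_values, control_rows, target_rows):
    """Elementwise 2^-(Ct_target - mean control Ct), plain loops."""
    out = {}
    n_cols = ct_values.shape[1]
    for tr in target_rows:
        row = []
        for j in range(n_cols):
            ctrl = [ct_values.iloc[ci, j] for ci in control_rows]
            ctrl = [c for c in ctrl if np.isfinite(c)]
            dct = ct_values.iloc[tr, j] - sum(ctrl) / len(ctrl)
            row.append(2.0 ** (-dct))
        out[tr] = row
    return out
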