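"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written as plain Python loops, separate from
the vectorised library code paths it checks.
"""

from __future__ import annotations

import math
import statistics

from scipy import stats as _stats


def trim_oracle(seq, quals, leading_q=28, trailing_q=29, window=4,
                window_q=15.0, minlen=90):
    """Plain-loop quality trimming with the documented semantics."""
    q = [ord(c) - 33 for c in quals]
    start, end = 0, len(q)
    while start < end and q[start] < leading_q:
        start += 1
    while end > start and q[end - 1] < trailing_q:
        end -= 1
    if end - start >= window:
        for i in range(start, end - window + 1):
            if sum(q[i : i + window]) / window < window_q:
                end = i
                break
        while end > start and q[end - 1] < trailing_q:
            end -= 1
    if end - start < minlen:
        return None
    return seq[start:end], quals[start:end]


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def merge_oracle(fseq, fquals, rseq, rquals, min_overlap=10,
                 min_assembly=284, max_assembly=290, min_consensus_q=26,
                 min_identity=0.8):
    """Plain-loop overlap merge; returns (seq, quals, overlap) or a reason."""
    rr = "".join(_COMP[c] for c in reversed(rseq))
    rq = [ord(c) - 33 for c in reversed(rquals)]
    fq = [ord(c) - 33 for c in fquals]
    m, n = len(fseq), len(rr)
    if min(m, n) < min_overlap:
        return "no_overlap"
    best = None  # (matches, ov, -offset)
    for off in range(0, m - min_overlap + 1):
        ov = min(m - off, n)
        matches = sum(fseq[off + i] == rr[i] for i in range(ov))
        key = (matches, ov, -off)
        if best is None or key > best:
            best = key
    matches, ov, neg_off = best
    off = -neg_off
    if matches / ov < min_identity:
        return "no_overlap"
    length = max(m, off + n)
    if not (min_assembly <= length <= max_assembly):
        return "length_out_of_range"
    seq, quals = [], []
    for i in range(length):
        in_f = i < m
        j = i - off
        in_r = 0 <= j < n
        if in_f and in_r:
            if fseq[i] == rr[j]:
                base, q = fseq[i], max(fq[i], rq[j])
            elif fq[i] >= rq[j]:
                base, q = fseq[i], fq[i]
            else:
                base, q = rr[j], rq[j]
        elif in_f:
            base, q = fseq[i], fq[i]
        else:
            base, q = rr[j], rq[j]
        if q < min_consensus_q:
            base = "N"
        seq.append(base)
        quals.append(chr(min(q, 60) + 33))
    return "".join(seq), "".join(quals), ov


def bh_oracle(pvals):
    """Sort-and-cummin Benjamini–Hochberg step-up."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adjusted = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n / rank)
        adjusted[i] = running
    return adjusted


def t_test_oracle(x, y):
    """Closed-form pooled-variance two-sided Student's t-test."""
    nx, ny = len(x), len(y)
    vx = statistics.variance(x)
    vy = statistics.variance(y)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    se = math.sqrt(sp2 * (1 / nx + 1 / ny))
    t = (statistics.mean(x) - statistics.mean(y)) / se
    p = 2.0 * _stats.t.sf(abs(t), nx + ny - 2)
    return t, p


def stability_oracle(series, window=5, step=1):
    """Window-by-window mean/sample-SD loop over a list of totals."""
    out = []
    for start in range(0, len(series) - window + 1, step):
        block = series[start : start + window]
        sd = statistics.stdev(block)
        mean = statistics.mean(block)
        out.append(math.inf if sd == 0 else mean / sd)
    return out
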