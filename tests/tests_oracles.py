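"""Brute-force sequence oracles: direct per-window recounts on raw strings,
kept independent of the package's cumulative-sum implementation."""

import numpy as np


def window_gc_oe(seq: str, start: int, end: int):
    w = seq[start:end]
    n_c, n_g = w.count("C"), w.count("G")
    n_cpg = w.count("CG")
    gc = (n_c + n_g) / len(w)
    oe = n_cpg * len(w) / (n_c * n_g) if n_c and n_g else 0.0
    return gc, oe


def island_oracle(seq: str, window=200, min_gc=0.5, min_oe=0.6):
    """Maximal runs of positions covered by any passing window."""
    covered = np.zeros(len(seq), dtype=bool)
    for s in range(len(seq) - window + 1):
        gc, oe = window_gc_oe(seq, s, s + window)
        if gc >= min_gc and oe >= min_oe:
            covered[s : s + window] = True
    out = []
    i = 0
    n = len(seq)
    while i < n:
        if covered[i]:
            j = i
            while j < n and covered[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def class_oracle(seq: str, window=500, step=5):
    starts = list(range(0, len(seq) - window + 1, step))
    if starts[-1] != len(seq) - window:
        starts.append(len(seq) - window)
    stats = [window_gc_oe(seq, s, s + window) for s in starts]
    if any(gc >= 0.55 and oe >= 0.75 for gc, oe in stats):
        return "HCP"
    if all(oe < 0.48 for _, oe in stats):
        return "LCP"
    return "ICP"
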