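"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's vectorized code paths: plain Python
loops and textbook formulas only.
"""
from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def brute_offtarget_count(spacer, genome, on_target=None, max_mm=1):
    """Position-by-position scan over every strand/PAM for near-matches of
    the spacer's PAM-proximal 17-mer next to an NGG or NAG PAM."""
    core = spacer[-17:]
    total = 0
    for name, seq in genome.replicons.items():
        n = len(seq)
        for strand in "+-":
            t = seq if strand == "+" else revcomp(seq)
            ext = t + (t[:19] if genome.circular else "")
            n_start = n if genome.circular else n - 19
            for q in range(max(n_start, 0)):
                win = ext[q : q + 20]
                if win[18] not in "GA" or win[19] != "G":
                    continue
                mm = sum(a != b for a, b in zip(win[:17], core))
                if mm > max_mm:
                    continue
                fwd = q if strand == "+" else (n - (q + 17)) % n
                if on_target is not None and on_target == (name, strand, fwd):
                    continue
                total += 1
    return total


def brute_bh(pvalues):
    """Benjamini-Hochberg adjusted p-values from the definition."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def brute_size_factors(counts):
    """Median-of-ratios normalization from the definition (counts: 2D array,
    guides x samples)."""
    x = np.asarray(counts, dtype=float)
    keep = [i for i in range(x.shape[0]) if all(x[i] > 0)]
    refs = [float(np.exp(np.mean(np.log(x[i])))) for i in keep]
    factors = []
    for j in range(x.shape[1]):
        ratios = sorted(x[i, j] / r for i, r in zip(keep, refs))
        mid = len(ratios) // 2
        med = (
            ratios[mid]
            if len(ratios) % 2
            else 0.5 * (ratios[mid - 1] + ratios[mid])
        )
        factors.append(med)
    return np.array(factors)


def trapezoid_by_hand(x, y):
    total = 0.0
    for i in range(1, len(x)):
        total += 0.5 * (y[i] + y[i - 1]) * (x[i] - x[i - 1])
    return total
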