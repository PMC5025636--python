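"""Independent reference implementations used to check the pipeline.

These deliberately avoid the code paths they verify: Poisson tails are
summed term by term with ``math``, island assembly is a regex over the
eligibility bitstring, and bin coverage is a per-fragment interval
intersection loop.
"""

from __future__ import annotations

import math
import re

import numpy as np


def poisson_tail(c: int, lam: float) -> float:
    """P(X >= c) for X ~ Poisson(lam), summed directly."""
    if c <= 0:
        return 1.0
    # 1 - sum_{k<c} pmf(k), with pmf built up incrementally
    pmf = math.exp(-lam)
    cdf = pmf
    for k in range(1, c):
        pmf *= lam / k
        cdf += pmf
    return max(1.0 - cdf, 0.0)


def log_pmf(c: int, lam: float) -> float:
    return -lam + c * math.log(lam) - math.lgamma(c + 1)


def islands_by_regex(eligible: np.ndarray, counts: np.ndarray, lam: float,
                     max_gap: int, window_w: int) -> list[tuple[int, int, float]]:
    """Maximal runs of eligible windows bridging <= max_gap ineligible ones.

    Returns (start_bp, end_bp, score) per island, score being the summed
    surprisal of the eligible member windows.
    """
    bits = "".join("1" if e else "0" for e in eligible)
    out = []
    for m in re.finditer("1(?:0{0,%d}1)*" % max_gap, bits):
        members = [i for i in range(m.start(), m.end()) if eligible[i]]
        score = -sum(log_pmf(int(counts[i]), lam) for i in members)
        out.append((m.start() * window_w, m.end() * window_w, score))
    return out


def bin_coverage_bruteforce(frag_starts, frag_ends, w0: int, w1: int,
                            bin_size: int) -> np.ndarray:
    """Per-bin fragment-overlap counts by direct interval intersection."""
    n_bins = (w1 - w0) // bin_size
    cov = np.zeros(n_bins, dtype=int)
    for s, e in zip(frag_starts, frag_ends):
        for b in range(n_bins):
            b0 = w0 + b * bin_size
            if s < b0 + bin_size and e > b0:
                cov[b] += 1
    return cov
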