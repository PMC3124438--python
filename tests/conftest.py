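"""Shared fixtures and independent alignment oracles."""

from __future__ import annotations

import numpy as np
import pytest

from fessurvey.tandem import DetectorParams


def unrolled_dp_score(segment: str, motif: str, params: DetectorParams | None = None) -> int:
    """Brute-force oracle for the wraparound alignment score.

    Explicitly unrolls the motif and runs a plain semi-global DP (whole
    segment aligned, pattern prefix and suffix free).  Independent of the
    cyclic implementation.  The unroll length 2n + m is a safe bound: an
    all-substitution alignment scores >= -3n, and every pattern character
    beyond the n consumed diagonally costs a -5 gap, so an optimal
    alignment never uses more than 2n + m pattern characters.
    """
    params = params or DetectorParams()
    n, m = len(segment), len(motif)
    target = 2 * n + m
    pattern = (motif * (target // m + 1))[:target]
    P = len(pattern)
    NEG = -(10**9)
    prev = [0] * (P + 1)  # row i=0: free leading pattern gaps
    for i in range(1, n + 1):
        cur = [NEG] * (P + 1)
        ci = segment[i - 1]
        for j in range(P + 1):
            best = prev[j] - params.indel_penalty  # gap in pattern
            if j > 0:
                sub = params.match_weight if ci == pattern[j - 1] else -params.mismatch_penalty
                diag = prev[j - 1] + sub
                if diag > best:
                    best = diag
                left = cur[j - 1] - params.indel_penalty  # gap in segment
                if left > best:
                    best = left
            cur[j] = best
        prev = cur
    return max(prev)


@pytest.fixture(scope="session")
def wdp_oracle():
    return unrolled_dp_score


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture(scope="session")
def dna_factory():
    return random_dna
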