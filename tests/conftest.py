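"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from Bio import Align


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def make_rng():
    return lambda seed: np.random.default_rng(seed)


def smith_waterman_summary(query: str, subject: str):
    """Independent Smith-Waterman oracle (Biopython, affine gaps).

    Returns (identity percent, query coverage, subject coverage) of the
    optimal local alignment under match +1 / mismatch -2 and gap
    open 5 / extend 2 costs.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    alignments = aligner.align(query, subject)
    if len(alignments) == 0 or alignments.score <= 0:
        return 0.0, 0.0, 0.0
    aln = alignments[0]
    q_blocks, s_blocks = aln.aligned
    matches = columns = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        for i in range(qe - qs):
            columns += 1
            matches += query[qs + i] == subject[ss + i]
    q_cov = sum(e - s for s, e in q_blocks) / len(query)
    s_cov = sum(e - s for s, e in s_blocks) / len(subject)
    return 100.0 * matches / columns, q_cov, s_cov
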