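"""Shared fixtures: tiny hand-built references and random profile factories."""

from __future__ import annotations

import numpy as np
import pytest

from parclip.ingest import AlignedRead, ReadGroup
from parclip.sitecaller import ConversionProfile


@pytest.fixture
def flat_reference():
    """One contig of repeating ACGT with known T positions (3, 7, 11, ...)."""
    return {"chr1": "ACGT" * 50}


def make_read(read_id, start, end, reference, chrom="chr1", strand="+",
              conversions=(), other_mismatches=()):
    """Build an AlignedRead matching the reference except at stated mismatches.

    ``conversions`` are plus-strand reference offsets turned into T=>C
    (A=>G for '-' reads); ``other_mismatches`` are (offset, read_base).
    """
    from parclip.ingest import reverse_complement

    ref = reference[chrom][start:end]
    seq = list(ref)
    mismatches = []
    for off in conversions:
        if strand == "+":
            assert ref[off - start] == "T"
            seq[off - start] = "C"
            mismatches.append((off, "T", "C"))
        else:
            assert ref[off - start] == "A"
            seq[off - start] = "G"
            mismatches.append((off, "A", "G"))
    for off, base in other_mismatches:
        mismatches.append((off, ref[off - start], base))
        seq[off - start] = base
    plus_seq = "".join(seq)
    return AlignedRead(
        read_id=read_id, chrom=chrom, strand=strand, start=start, end=end,
        sequence=plus_seq if strand == "+" else reverse_complement(plus_seq),
        mismatches=tuple(sorted(mismatches)),
    )


def random_profile(rng: np.random.Generator, max_len: int = 200) -> ConversionProfile:
    """A synthetic conversion profile with at least one conversion event."""
    L = int(rng.integers(10, max_len + 1))
    is_t = rng.random(L) < 0.3
    if not is_t.any():
        is_t[int(rng.integers(L))] = True
    x_tc = np.zeros(L, dtype=np.int64)
    x_tt = np.zeros(L, dtype=np.int64)
    t_idx = np.flatnonzero(is_t)
    x_tc[t_idx] = rng.poisson(0.8, size=len(t_idx))
    x_tt[t_idx] = rng.poisson(2.0, size=len(t_idx))
    if x_tc.sum() == 0:
        x_tc[t_idx[0]] = 1
    depth = x_tc + x_tt + rng.integers(0, 8, size=L)
    group = ReadGroup(chrom="fixture", strand="+", start=0, end=L, reads=[])
    return ConversionProfile(group=group, x_tc=x_tc, x_tt=x_tt,
                             depth=depth.astype(np.int64), is_t=is_t)
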