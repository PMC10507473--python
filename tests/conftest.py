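"""Shared fixture builders for compact hand-written call sets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chlorisnp.callset import Callset, SampleMetadata

# call-code shorthand used across test files
R, H, A, M = 0, 1, 2, -1


def make_callset(
    calls,
    depths=None,
    samples=None,
    chrom="chr1",
    start_pos=100,
    ref="A",
    alt="G",
):
    """Callset from a list-of-rows call matrix (codes R/H/A/M)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    if depths is None:
        depths = np.full_like(calls, 10, dtype=np.int32)
    else:
        depths = np.asarray(depths, dtype=np.int32)
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(start_pos, start_pos + n_sites * 10, 10),
            "ref": ref,
            "alt": alt,
        }
    )
    return Callset(samples=list(samples), sites=sites, calls=calls, depths=depths)


def make_metadata(spec):
    """Metadata from [(sample_id, cultivar, ploidy), ...]."""
    return SampleMetadata(
        pd.DataFrame(spec, columns=["sample_id", "cultivar", "ploidy"])
    )


@pytest.fixture
def toy_metadata():
    return make_metadata(
        [("s0", "cA", 2), ("s1", "cA", 2), ("s2", "cB", 2),
         ("s3", "cT", 4), ("s4", "cT", 4), ("s5", "cT", 4)]
    )
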