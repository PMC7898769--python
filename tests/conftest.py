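from __future__ import annotations

import numpy as np
import pytest

from vmscreen.catalogue import RepeatFeature, group_into_elements
from vmscreen.registry import SubelementRegistry

LTR = "IAPLTR1_Mm"
INT = "IAPEz-int"
CF = "LTR/ERVK"


@pytest.fixture(scope="session")
def registry() -> SubelementRegistry:
    return SubelementRegistry.default()


def make_features(rows, chrom="chr1"):
    """Rows of (start, end, strand, rep_name, element_id) -> features."""
    return [RepeatFeature(chrom, s, e, st, n, CF, i) for s, e, st, n, i in rows]


# element-oriented subelement patterns per structure class
_PATTERNS = {
    "FULL": [LTR, INT, LTR],
    "SOLO_LTR": [LTR],
    "FRAG_NO5": [INT, LTR],
    "FRAG_NO3": [LTR, INT],
    "FRAG_INTERNAL_ONLY": [INT],
    "FRAG_OTHER": [INT, LTR, INT],
}


def random_catalogue(rng: np.random.Generator, registry=None,
                     n_max: int = 12, n_chroms: int = 2):
    """A random mix of structures with mendable and unmendable gaps.

    Inter-element gaps are drawn near the 2000 bp adjacency limit on
    both sides, so mending decisions are exercised at the boundary.
    """
    features = []
    eid = 0
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        pos = int(rng.integers(0, 5000))
        for _ in range(int(rng.integers(1, n_max + 1))):
            pattern = _PATTERNS[
                str(rng.choice(list(_PATTERNS), p=[0.2, 0.2, 0.2, 0.2, 0.1, 0.1]))
            ]
            strand = str(rng.choice(["+", "-"]))
            genomic = pattern if strand == "+" else pattern[::-1]
            for name in genomic:
                length = int(rng.integers(100, 600))
                features.append(
                    RepeatFeature(chrom, pos, pos + length, strand, name, CF, eid)
                )
                pos += length
            eid += 1
            pos += int(rng.choice([100, 500, 1900, 2100, 4000, 20000]))
    return group_into_elements(features, registry)
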