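"""Shared fixtures: compact pedigree construction and seeded RNG."""

from __future__ import annotations

import numpy as np
import pytest

from pedphase2 import Genotype2, Member, Pedigree


def make_pedigree(rows) -> Pedigree:
    """Build a pedigree from (id, father, mother, (g1, g2)) tuples."""
    return Pedigree(
        Member(member_id=mid, father_id=f, mother_id=m,
               genotype=Genotype2(*g))
        for mid, f, m, g in rows)


@pytest.fixture
def trio_factory():
    def build(gf, gm, gc):
        return make_pedigree([
            ("f", None, None, gf),
            ("m", None, None, gm),
            ("c", "f", "m", gc),
        ])
    return build


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
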