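"""Shared fixtures and brute-force helpers for the test suite."""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pytest

from promidiag.activity_data import ACTIVE, INACTIVE, ActivityMatrix
from promidiag.chem_similarity import Fingerprint


def make_matrix(triples) -> ActivityMatrix:
    """Build a matrix from (compound, target, outcome) triples."""
    m = ActivityMatrix()
    for c, t, o in triples:
        m.add(c, t, o)
    return m


def random_matrix(rng: np.random.Generator, n_compounds: int = 12, n_targets: int = 6,
                  density: float = 0.6, active_rate: float = 0.35) -> ActivityMatrix:
    """Random ternary matrix; some compounds reach PD >= 2 by chance."""
    m = ActivityMatrix()
    for ci in range(n_compounds):
        cid = f"c{ci:03d}"
        m.add_compound(cid)
        for ti in range(n_targets):
            if rng.random() < density:
                outcome = ACTIVE if rng.random() < active_rate else INACTIVE
                m.add(cid, f"t{ti:02d}", outcome)
    return m


def fp_from_bits(on_bits, n_bits: int = 32) -> Fingerprint:
    return Fingerprint.from_on_bits(on_bits, n_bits=n_bits)


def random_fingerprints(rng: np.random.Generator, ids, n_bits: int = 64,
                        density: float = 0.3) -> Dict[str, Fingerprint]:
    return {
        i: Fingerprint(bits=(rng.random(n_bits) < density).astype(np.uint8), n_bits=n_bits)
        for i in ids
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_matrix() -> ActivityMatrix:
    """MT compound m1 active on t1..t3 with eligible/ineligible ST candidates."""
    return make_matrix([
        ("m1", "t1", ACTIVE), ("m1", "t2", ACTIVE), ("m1", "t3", ACTIVE),
        # c1: PD 1, active t1, explicitly inactive on t2, t3 -> eligible for t1
        ("c1", "t1", ACTIVE), ("c1", "t2", INACTIVE), ("c1", "t3", INACTIVE),
        # c2: active t2 but untested on t3 -> ineligible
        ("c2", "t2", ACTIVE), ("c2", "t1", INACTIVE),
    ])
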