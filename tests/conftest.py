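"""Shared fixtures: a miR-143-like hairpin and a small synthetic reference set."""

from __future__ import annotations

import numpy as np
import pytest

from isomirkit import Hairpin, MatureAnnotation
from isomirkit.simulate import SimSpec, make_references


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def mir143_like() -> tuple[Hairpin, MatureAnnotation]:
    """A 100-nt hairpin with a 3p mature annotated at positions 60..80."""
    rng = np.random.default_rng(143)
    hp = Hairpin("hsa-mir-143", random_dna(rng, 100))
    ann = MatureAnnotation(
        "hsa-mir-143", "hsa-miR-143", "3p", 60, 80, hp.subseq(60, 80)
    )
    return hp, ann


@pytest.fixture(scope="session")
def small_refs():
    """Six synthetic hairpins with annotations and decoys."""
    return make_references(SimSpec(seed=3, n_hairpins=6, n_switch=0, n_acpre=0, n_orphan=0))
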