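"""Shared small fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from hydroprofiler.refdb import (
    ActivityCategory,
    HydrogenaseEntry,
    MetalClass,
    ReferenceDB,
)
from hydroprofiler.simulate import generate_genome, generate_reference_and_decoys


@pytest.fixture(scope="session")
def tiny_db() -> ReferenceDB:
    """Five handcrafted entries, one per category, with distinctive sequences."""
    cats = list(ActivityCategory)
    metals = [MetalClass.NIFE, MetalClass.FEFE, MetalClass.FE, MetalClass.NIFE, MetalClass.FEFE]
    rng = np.random.default_rng(123)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    entries = []
    for i, (cat, metal) in enumerate(zip(cats, metals)):
        seq = "".join(aas[j] for j in rng.integers(0, 20, size=60))
        entries.append(
            HydrogenaseEntry(
                entry_id=f"{cat.value}_01",
                protein_seq=seq,
                metal_class=metal,
                activity_category=cat,
                source_label="fixture",
            )
        )
    return ReferenceDB(entries=tuple(entries), version_tag="tiny")


@pytest.fixture(scope="session")
def small_reference():
    """A generated 2-per-category reference with 2 decoys (seeded)."""
    return generate_reference_and_decoys(
        n_per_category=2, protein_length=(120, 200), n_decoys=2, seed=42
    )


@pytest.fixture(scope="session")
def small_genome(small_reference):
    db, _ = small_reference
    items = [(e.entry_id, e.protein_seq) for e in db.entries[:3]]
    return generate_genome(20_000, items, seed=7, genome_id="gfix")
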