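"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from metanno.ec import ECNumber
from metanno.model import AnnotationSet


def brute_force_regions(sets_by_label: dict) -> dict[frozenset, int]:
    """Exclusive Venn region counts by direct membership testing.

    Independent of the implementation under test: for every element of the
    union, ask each labeled set whether it contains the element, and bucket
    by the resulting supporter set.
    """
    union = set()
    for s in sets_by_label.values():
        union |= set(s)
    regions: dict[frozenset, int] = {}
    for element in union:
        supporters = frozenset(lab for lab, s in sets_by_label.items() if element in s)
        regions[supporters] = regions.get(supporters, 0) + 1
    return regions


def make_ec(i: int) -> ECNumber:
    """Deterministic distinct complete EC for small test universes."""
    return ECNumber(i % 6 + 1, i // 6 % 20 + 1, i // 120 % 20 + 1, i // 2400 + 1)


def random_annotation_sets(
    rng: random.Random,
    genome: str = "G",
    n_tools: int | None = None,
    max_units: int = 50,
) -> dict[str, AnnotationSet]:
    """Random small per-tool annotation sets over a shared gene/EC pool."""
    if n_tools is None:
        n_tools = rng.randint(2, 6)
    genes = [f"g{i}" for i in range(rng.randint(3, 12))]
    ecs = [make_ec(i) for i in range(rng.randint(3, 12))]
    pool = [(g, e) for g in genes for e in ecs]
    out = {}
    for t in range(n_tools):
        size = rng.randint(1, min(max_units, len(pool)))
        pairs = frozenset(rng.sample(pool, size))
        out[f"tool{t}"] = AnnotationSet(genome, f"tool{t}", pairs)
    return out


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)
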