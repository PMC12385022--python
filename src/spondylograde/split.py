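"""Seeded train/validation/test splitting of a dataset manifest."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .phantom import DatasetManifest


@dataclass
class SplitSpec:
    """Split proportions (train, val, test) summing to 1, plus a seed."""

    ratios: tuple = (0.7, 0.2, 0.1)
    seed: int = 0

    def __post_init__(self):
        r = tuple(float(x) for x in self.ratios)
        if len(r) != 3 or any(not 0.0 <= x <= 1.0 for x in r):
            raise ValueError(f"ratios must be 3 values in [0,1], got {self.ratios}")
        if not math.isclose(sum(r), 1.0, abs_tol=1e-9):
            raise ValueError(f"ratios must sum to 1, got {sum(r)}")
        self.ratios = r


def split_sizes(n: int, ratios) -> list[int]:
    """Largest-remainder apportionment of n items into len(ratios) parts."""
    exact = [n * r for r in ratios]
    base = [int(math.floor(e)) for e in exact]
    short = n - sum(base)
    remainders = sorted(range(len(ratios)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in remainders[:short]:
        base[i] += 1
    return base


def split_dataset(manifest: DatasetManifest, spec: SplitSpec):
    """Shuffle entries with the spec's seed and partition by its ratios.

    Returns (train, val, test) manifests; partitions are disjoint and cover
    the input exactly.
    """
    n = manifest.n
    if n == 0:
        raise ValueError("manifest is empty")
    nonzero = sum(1 for r in spec.ratios if r > 0)
    if n < nonzero:
        raise ValueError(f"cannot split {n} entries into {nonzero} non-empty parts")
    sizes = split_sizes(n, spec.ratios)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    bounds = np.cumsum([0] + sizes)
    parts = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        entries = [manifest.entries[i] for i in order[lo:hi]]
        parts.append(DatasetManifest(entries=entries, grade_mix=manifest.grade_mix,
                                     seed=spec.seed))
    return tuple(parts)
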