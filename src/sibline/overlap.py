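"""Upset-style exclusive intersection counts of per-sample gene sets.

Each gene in the union is assigned to exactly one membership pattern —
the subset of samples that carry it — so the pattern counts partition
the union (they sum to the union size).  This is the "exclusive
intersection" convention of upset plots, not cumulative intersections.
"""

from __future__ import annotations

from typing import Mapping, Set

import pandas as pd

__all__ = ["exclusive_intersections", "intersections_frame"]


def exclusive_intersections(
    collection: Mapping[str, Set[str]]
) -> dict[tuple[str, ...], int]:
    """Count genes per exact membership pattern.

    Keys of the result are tuples of sample ids in the collection's
    order; only patterns with at least one gene appear.
    """
    samples = list(collection)
    if not samples:
        raise ValueError("need at least one sample")
    if len(set(samples)) != len(samples):
        raise ValueError("sample ids must be unique")
    counts: dict[tuple[str, ...], int] = {}
    union = set().union(*collection.values())
    for gene in union:
        pattern = tuple(s for s in samples if gene in collection[s])
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def intersections_frame(counts: Mapping[tuple[str, ...], int]) -> pd.DataFrame:
    """Tabular form sorted by count (descending), upset-plot style."""
    rows = [
        ("&".join(pattern), len(pattern), n)
        for pattern, n in sorted(
            counts.items(), key=lambda kv: (-kv[1], kv[0])
        )
    ]
    return pd.DataFrame(rows, columns=["pattern", "degree", "n_genes"])
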