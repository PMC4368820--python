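"""Fisher-exact overrepresentation of gene sets in a selected feature list.

The one-sided p-value is the hypergeometric upper tail P(X >= k) of the
overlap k between the selection (size n) and a set (size K) drawn from a
universe of N annotatable features. A set is "detected" when p < 0.001.
The chance benchmark for any bias measure is obtained by disordering the
feature-function links: resampling each set's members uniformly from the
universe while preserving set sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataError, GeneSetCollection

__all__ = [
    "fisher_overrepresentation",
    "bias_toward_functions",
    "disorder_links",
    "DEFAULT_ENRICH_CUT",
]

DEFAULT_ENRICH_CUT = 1e-3


def _upper_tail(k: int, N: int, K: int, n: int) -> float:
    # P(X >= k) for overlap of an n-selection with a K-set in an N-universe
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_overrepresentation(
    selected,
    collection: GeneSetCollection,
    enrich_cut: float = DEFAULT_ENRICH_CUT,
) -> pd.DataFrame:
    """Score every set in the collection for overrepresentation.

    Returns a frame indexed by set id with columns k (overlap), K (set
    size), n (selection size), N (universe size), p (one-sided upper
    tail) and detected (p strictly below ``enrich_cut``), sorted by
    ascending p with ties broken by set id.
    """
    selected = frozenset(selected)
    stray = selected - collection.universe
    if stray:
        raise DataError(
            f"selected features outside the annotation universe: {sorted(stray)[:5]}"
        )
    N = len(collection.universe)
    n = len(selected)
    rows = []
    for name, members in collection.sets.items():
        k = len(selected & members)
        rows.append((name, k, len(members), n, N, _upper_tail(k, N, len(members), n)))
    frame = pd.DataFrame(
        rows, columns=["function", "k", "K", "n", "N", "p"]
    ).set_index("function")
    frame["detected"] = frame["p"] < enrich_cut
    # ascending p; ties broken by set id via the stable sort
    return frame.sort_index(kind="mergesort").sort_values(by="p", kind="mergesort")


def bias_toward_functions(selected, specific, universe) -> float:
    """Overrepresentation p of a selection against a union set of functions.

    ``specific`` is the union of the members of the disease-specific
    function sets; the return value is the one-sided hypergeometric upper
    tail of the overlap.
    """
    universe = frozenset(universe)
    selected = frozenset(selected)
    specific = frozenset(specific)
    if not specific <= universe:
        raise DataError("specific function members must lie in the universe")
    if not selected <= universe:
        raise DataError("selected features must lie in the universe")
    k = len(selected & specific)
    return _upper_tail(k, len(universe), len(specific), len(selected))


def disorder_links(collection: GeneSetCollection, seed: int) -> GeneSetCollection:
    """Destroy feature-function links while preserving set sizes.

    Each set's members are resampled uniformly without replacement from
    the universe with a seeded generator, giving the chance benchmark
    for detection-bias measures.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(collection.universe)
    sets = {
        name: frozenset(rng.choice(universe, size=len(members), replace=False))
        for name, members in collection.sets.items()
    }
    return GeneSetCollection(sets=sets, universe=collection.universe)
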