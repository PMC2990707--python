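"""Permutation tests for overrepresentation of annotation classes in top-K sets.

The null resamples K-subsets of the probe universe uniformly, so the replicate
feature count is exactly hypergeometric; an exact log-space tail sum serves as
the closed-form oracle.  P-values use the (b+1)/(B+1) pseudocount convention
and are one-sided (overrepresentation, >= observed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .diffexp import TopKSet

#: above this simulation volume, replicate counts are drawn directly from the
#: (identical) hypergeometric distribution instead of materialising subsets
_SUBSET_PATH_LIMIT = 5e7


@dataclass(frozen=True)
class EnrichmentResult:
    tissue: str
    k: int
    feature: str
    observed: int
    universe_size: int
    feature_count: int
    b: int
    p_perm: float
    p_exact: float


def count_feature(topk: TopKSet, annot: pd.DataFrame, feature: str, value=None) -> int:
    """Exact count of top-K members carrying the feature.

    ``feature`` names an annotation column; ``value`` defaults to True for
    boolean columns and must be given otherwise (e.g. ``("region_class",
    "interval")``).
    """
    members = list(topk.probes)
    missing = set(members) - set(annot.index)
    if missing:
        raise KeyError(f"top-K member(s) lacking annotation: {sorted(missing)[:5]}")
    col = annot.loc[members, feature]
    if value is None:
        value = True
    return int((col == value).sum())


def _log_hypergeom_pmf(x: np.ndarray, n: int, m: int, k: int) -> np.ndarray:
    return (
        gammaln(m + 1) - gammaln(x + 1) - gammaln(m - x + 1)
        + gammaln(n - m + 1) - gammaln(k - x + 1) - gammaln(n - m - k + x + 1)
        - (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))
    )


def hypergeometric_tail(n: int, m: int, k: int, x: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N=n, m, K=k), exact in log space."""
    if not (0 <= m <= n and 0 <= k <= n):
        raise ValueError(f"inconsistent universe: N={n}, m={m}, K={k}")
    if not 0 <= x <= min(k, m):
        raise ValueError(f"x={x} outside [0, min(K, m)={min(k, m)}]")
    if x == 0:
        return 1.0
    support = np.arange(max(x, max(0, k - (n - m))), min(k, m) + 1)
    logs = _log_hypergeom_pmf(support.astype(float), n, m, k)
    peak = logs.max()
    return float(min(1.0, np.exp(peak) * np.exp(logs - peak).sum()))


def _null_counts(n: int, m: int, k: int, b: int, rng: np.random.Generator) -> np.ndarray:
    """Feature counts in B uniformly drawn K-subsets of an N-probe universe."""
    if n * b <= _SUBSET_PATH_LIMIT:
        counts = np.empty(b, dtype=np.int64)
        feature_mask = np.zeros(n, dtype=bool)
        feature_mask[:m] = True  # labels are exchangeable under the null
        chunk = max(1, int(_SUBSET_PATH_LIMIT // (4 * n)))
        done = 0
        while done < b:
            size = min(chunk, b - done)
            keys = rng.random((size, n))
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
            counts[done : done + size] = feature_mask[idx].sum(axis=1)
            done += size
        return counts
    # distributionally identical shortcut for large N*B
    return rng.hypergeometric(m, n - m, k, size=b)


def permutation_enrichment(
    x: int,
    universe_size: int,
    feature_count: int,
    k: int,
    b: int = 100_000,
    seed: int | np.random.Generator = 0,
    tissue: str = "",
    feature: str = "",
) -> EnrichmentResult:
    """One-sided permutation test of the observed feature count in a top-K set.

    Each of B replicates draws K probes uniformly without replacement from the
    universe and counts feature members; p = (b + 1)/(B + 1) with b the number
    of replicates reaching the observed count.
    """
    if b < 1:
        raise ValueError("need at least one permutation")
    if k < 1:
        raise ValueError("top set must be non-empty")
    if not 0 <= x <= min(k, feature_count):
        raise ValueError(f"observed count {x} inconsistent with K={k}, m={feature_count}")
    if not (feature_count <= universe_size and k <= universe_size):
        raise ValueError("feature count and K must not exceed the universe size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = _null_counts(universe_size, feature_count, k, b, rng)
    hits = int((counts >= x).sum())
    return EnrichmentResult(
        tissue=tissue,
        k=k,
        feature=feature,
        observed=x,
        universe_size=universe_size,
        feature_count=feature_count,
        b=b,
        p_perm=(hits + 1) / (b + 1),
        p_exact=hypergeometric_tail(universe_size, feature_count, k, x),
    )


def enrich_topk(
    topk: TopKSet,
    annot: pd.DataFrame,
    feature: str,
    value=None,
    b: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Convenience wrapper: count a feature in a top-K set and test it."""
    x = count_feature(topk, annot, feature, value)
    m = int((annot[feature] == (True if value is None else value)).sum())
    label = feature if value is None else f"{feature}={value}"
    return permutation_enrichment(
        x, len(annot), m, topk.k, b=b, seed=seed, tissue=topk.tissue, feature=label
    )


def cpg_enrichment(
    probe_set,
    annot: pd.DataFrame,
    b: int = 100_000,
    seed: int | np.random.Generator = 0,
    tissue: str = "",
) -> EnrichmentResult:
    """CpG-neighbour overrepresentation within a set of CNV-chromosome probes.

    The universe is restricted to flanking probes of the CNV chromosome; the
    tested set is intersected with that universe.
    """
    flank = annot[annot["region_class"] == "flank_cnv_chr"]
    members = [p for p in probe_set if p in flank.index]
    x = int(flank.loc[members, "cpg_neighbor"].sum())
    m = int(flank["cpg_neighbor"].sum())
    return permutation_enrichment(
        x, len(flank), m, len(members), b=b, seed=seed, tissue=tissue, feature="cpg_neighbor"
    )
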