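"""Per-tissue differential expression across genotypes: ANOVA ranking,
contrasts against wild type, and detection calls.

The ranking statistic is the classical one-way ANOVA F across the four
genotype groups, computed per probe on log2 intensities.  Contrasts against
the wild-type (two-copies-in-trans) group use Welch's unequal-variance t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GENOTYPES, WILDTYPE

_TINY_P = np.finfo(float).tiny


@dataclass(frozen=True)
class TopKSet:
    """The K most differentially expressed probes of one tissue."""

    tissue: str
    k: int
    probes: tuple[str, ...]
    statistic: str = "anova_F"

    def __post_init__(self) -> None:
        if len(self.probes) != self.k:
            raise ValueError(f"expected {self.k} members, got {len(self.probes)}")

    def __contains__(self, probe: str) -> bool:
        return probe in set(self.probes)


def _tissue_groups(
    matrix: pd.DataFrame, samples: pd.DataFrame, tissue: str, group_col: str = "genotype"
) -> dict[str, np.ndarray]:
    """Column blocks of the matrix per group within one tissue (probes x reps)."""
    sub = samples[samples["tissue"] == tissue]
    if sub.empty:
        raise ValueError(f"no samples for tissue {tissue!r}")
    groups = {}
    for g, block in sub.groupby(group_col, observed=True):
        cols = block.index.to_list()
        if len(cols) < 2:
            raise ValueError(f"group {g!r} in tissue {tissue!r} has {len(cols)} replicate(s); need >=2")
        groups[str(g)] = matrix[cols].to_numpy()
    return groups


def anova_f(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way ANOVA over rows.

    Each element of ``groups`` is a (n_probes, n_i) block.  Degenerate rows
    (zero between- and within-group variance) get F = 0, p = 1; rows with zero
    within- but positive between-group variance get F = inf and the smallest
    positive p.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.shape[1] for g in groups])
    n_total = int(ns.sum())
    means = np.column_stack([g.mean(axis=1) for g in groups])  # probes x k
    grand = (means * ns).sum(axis=1) / n_total
    ssb = (ns * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.zeros_like(ssb)
    for g, m in zip(groups, means.T):
        ssw += ((g - m[:, None]) ** 2).sum(axis=1)
    dfb, dfw = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(f, dfb, dfw)
    degenerate = ssw == 0
    f = np.where(degenerate & (ssb == 0), 0.0, f)
    p = np.where(degenerate & (ssb == 0), 1.0, p)
    p = np.where(degenerate & (ssb > 0), _TINY_P, p)
    return f, np.clip(p, _TINY_P, 1.0)


def probe_anova(matrix: pd.DataFrame, samples: pd.DataFrame, tissue: str) -> pd.DataFrame:
    """One-way ANOVA F across genotype groups per probe, plus ranks.

    Returns a DataFrame indexed by probe with columns F, pvalue, rank (1 = most
    differential; ties broken by smaller p, then probe id).
    """
    groups = _tissue_groups(matrix, samples, tissue)
    f, p = anova_f(list(groups.values()))
    out = pd.DataFrame({"F": f, "pvalue": p}, index=matrix.index)
    order = np.lexsort((out.index.to_numpy(), out["pvalue"].to_numpy(), -out["F"].to_numpy()))
    rank = np.empty(len(out), dtype=int)
    rank[order] = np.arange(1, len(out) + 1)
    out["rank"] = rank
    return out


def rank_top_k(de: pd.DataFrame, tissue: str, k: int) -> TopKSet:
    """The K probes with largest F (ties: smaller p, then lexicographic id)."""
    if k <= 0:
        raise ValueError(f"K must be positive, got {k}")
    if k > len(de):
        raise ValueError(f"K = {k} exceeds the {len(de)} ranked probes")
    members = de.sort_values("rank").index[:k]
    return TopKSet(tissue=tissue, k=k, probes=tuple(members))


def welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch two-sample test over rows: (mean difference a-b, p)."""
    diff = a.mean(axis=1) - b.mean(axis=1)
    with warnings.catch_warnings():
        # near-constant rows trigger a harmless precision warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero-variance rows: p undefined; identical means are null, distinct are extreme
    bad = ~np.isfinite(p)
    p[bad & (diff == 0)] = 1.0
    p[bad & (diff != 0)] = _TINY_P
    return diff, np.clip(p, _TINY_P, 1.0)


def contrast_vs_wildtype(
    matrix: pd.DataFrame, samples: pd.DataFrame, tissue: str, genotype: str
) -> pd.DataFrame:
    """log2 fold change (genotype minus wild type) and Welch p, per probe."""
    if genotype == WILDTYPE:
        raise ValueError("contrast genotype must differ from the wild-type group")
    groups = _tissue_groups(matrix, samples, tissue)
    for g in (genotype, WILDTYPE):
        if g not in groups:
            raise ValueError(f"genotype {g!r} absent from tissue {tissue!r}")
    log2fc, p = welch(groups[genotype], groups[WILDTYPE])
    return pd.DataFrame({"log2fc": log2fc, "pvalue": p}, index=matrix.index)


def diffexp_table(matrix: pd.DataFrame, samples: pd.DataFrame, tissue: str) -> pd.DataFrame:
    """Combined per-tissue table: F, p, rank and per-genotype contrasts."""
    table = probe_anova(matrix, samples, tissue)
    present = set(samples.loc[samples["tissue"] == tissue, "genotype"])
    for g in GENOTYPES:
        if g == WILDTYPE or g not in present:
            continue
        con = contrast_vs_wildtype(matrix, samples, tissue, g)
        table[f"log2fc_{g}"] = con["log2fc"]
        table[f"pvalue_{g}"] = con["pvalue"]
    return table


def detection_call(
    matrix: pd.DataFrame, samples: pd.DataFrame, threshold: float | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Expressed calls per (probe, tissue) and tissue breadth per probe.

    A probe is called expressed in a tissue when its mean log2 intensity across
    all samples of that tissue reaches ``threshold``.  When no threshold is
    given, the 25th percentile of the global intensity distribution is used —
    a weak default; pass an explicit between-modes threshold when one is known
    (e.g. ``GeneratorConfig.detection_threshold()`` for synthetic data).
    """
    if threshold is None:
        threshold = float(np.quantile(matrix.to_numpy(), 0.25))
    tissues = list(dict.fromkeys(samples["tissue"]))
    calls = {}
    for t in tissues:
        cols = samples.index[samples["tissue"] == t].to_list()
        calls[t] = matrix[cols].mean(axis=1) >= threshold
    expressed = pd.DataFrame(calls)
    breadth = expressed.sum(axis=1)
    breadth.name = "tissue_breadth"
    return expressed, breadth
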