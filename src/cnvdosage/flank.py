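"""Statistics characterising interval dosage response and flanking-gene
deregulation: dosage-ratio summaries, direction concordance across rearranged
genotypes, chromosomal clustering, breakpoint-distance correlation,
tissue-breadth and expression-level comparisons, and platform concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import GENOTYPES, WILDTYPE, RegionConfig
from .diffexp import contrast_vs_wildtype

REARRANGED = ("1n", "2n_cis", "3n")


# ---------------------------------------------------------------------------
# dosage response of interval probes


def _override_mask(annot: pd.DataFrame) -> pd.Series:
    """Probes whose active copy numbers deviate from the region-class default."""
    default = {
        g: np.where(annot["region_class"] == "interval",
                    {"1n": 1, "2n_trans": 2, "2n_cis": 2, "3n": 3}[g], 2)
        for g in GENOTYPES
    }
    mask = pd.Series(False, index=annot.index)
    for g in GENOTYPES:
        mask |= annot[f"copies_{g}"].to_numpy() != default[g]
    return mask


@dataclass
class DosageSummary:
    """Linear-scale expression ratios to wild type for interval probes.

    ``table`` rows: one per (genotype, group) where group is "interval" for
    default-copy probes or "anchor_<c>cp" for anchor probes with c active
    copies in that genotype.  ``per_tissue`` carries the same means per tissue.
    """

    table: pd.DataFrame
    per_tissue: pd.DataFrame

    def ratio(self, genotype: str, group: str = "interval") -> float:
        row = self.table[(self.table["genotype"] == genotype) & (self.table["group"] == group)]
        return float(row["mean_ratio"].iloc[0])


def dosage_summary(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    annot: pd.DataFrame,
    tissue_scope: str | list[str] = "pooled",
) -> DosageSummary:
    """Mean +/- SD linear ratio to wild type over interval probes, per genotype.

    Per probe the log2 fold change vs wild type is averaged across the tissues
    in scope before exponentiation; anchor-override probes are summarised
    separately by their active copy number.
    """
    interval = annot[annot["region_class"] == "interval"]
    if interval.empty:
        raise ValueError("no interval probes in the annotation")
    tissues = (
        list(dict.fromkeys(samples["tissue"])) if tissue_scope == "pooled" else
        ([tissue_scope] if isinstance(tissue_scope, str) else list(tissue_scope))
    )
    overrides = _override_mask(interval)
    rows, tissue_rows = [], []
    for g in REARRANGED:
        fc = pd.DataFrame(
            {t: contrast_vs_wildtype(matrix, samples, t, g)["log2fc"] for t in tissues}
        ).loc[interval.index]
        pooled_ratio = np.exp2(fc.mean(axis=1))
        groups = {"interval": interval.index[~overrides]}
        for probe in interval.index[overrides]:
            c = int(interval.loc[probe, f"copies_{g}"])
            groups.setdefault(f"anchor_{c}cp", []).append(probe)
        for name, members in groups.items():
            members = pd.Index(members)
            if members.empty:
                continue
            r = pooled_ratio.loc[members]
            rows.append(
                {"genotype": g, "group": name, "mean_ratio": r.mean(),
                 "sd_ratio": r.std(ddof=1) if len(r) > 1 else 0.0, "n_probes": len(r)}
            )
            if name == "interval":
                for t in tissues:
                    rt = np.exp2(fc.loc[members, t])
                    tissue_rows.append(
                        {"genotype": g, "tissue": t, "mean_ratio": rt.mean(), "n_probes": len(rt)}
                    )
    return DosageSummary(pd.DataFrame(rows), pd.DataFrame(tissue_rows))


# ---------------------------------------------------------------------------
# direction concordance


@dataclass
class ConcordanceResult:
    pairwise: dict  # (genotype, genotype) -> same-direction fraction
    threeway: float
    n_used: int
    n_excluded: int  # probes with a zero fold change in some genotype


def direction_concordance(contrasts: dict, probes) -> ConcordanceResult:
    """Sign agreement of log2 fold changes across the three rearranged genotypes.

    ``contrasts`` maps each rearranged genotype to a probe-indexed log2fc
    Series.  A zero fold change agrees with nothing; probes with any zero sign
    are excluded and counted.
    """
    probes = pd.Index(probes)
    if probes.empty:
        raise ValueError("empty probe set")
    signs = pd.DataFrame({g: np.sign(contrasts[g].loc[probes]) for g in REARRANGED})
    usable = (signs != 0).all(axis=1)
    s = signs[usable]
    n = len(s)
    pairwise = {}
    for i, gi in enumerate(REARRANGED):
        for gj in REARRANGED[i + 1:]:
            pairwise[(gi, gj)] = float((s[gi] == s[gj]).mean()) if n else float("nan")
    threeway = float(((s[REARRANGED[0]] == s[REARRANGED[1]]) &
                      (s[REARRANGED[1]] == s[REARRANGED[2]])).mean()) if n else float("nan")
    return ConcordanceResult(pairwise, threeway, n, int((~usable).sum()))


# ---------------------------------------------------------------------------
# chromosomal clustering


@dataclass
class ClusteringResult:
    statistic: float  # mean nearest-affected-neighbour distance, rank units
    p_value: float
    b: int
    n_genes: int
    n_affected: int


def _mean_nn_distance(sorted_ranks: np.ndarray) -> np.ndarray:
    """Mean nearest-neighbour gap per row of sorted rank vectors (k >= 2)."""
    gaps = np.diff(sorted_ranks, axis=-1)
    left = np.concatenate([gaps[..., :1] * 0 + np.iinfo(np.int64).max, gaps], axis=-1)
    right = np.concatenate([gaps, gaps[..., :1] * 0 + np.iinfo(np.int64).max], axis=-1)
    return np.minimum(left, right).mean(axis=-1)


def clustering_test(
    positions, affected, b: int = 10_000, seed: int | np.random.Generator = 0
) -> ClusteringResult:
    """Permutation test for clustering of affected genes along a chromosome.

    Genes are reduced to their rank along the chromosome (by midpoint), which
    neutralises the non-uniform physical spacing of genes.  The statistic S is
    the mean distance, in rank units, from each affected gene to its nearest
    affected neighbour; small S means clustered.  The null redraws the k
    affected labels uniformly among the n genes; p = (b + 1)/(B + 1) with b the
    number of replicates with S_rep <= S_obs.
    """
    positions = np.asarray(positions)
    affected = np.asarray(affected, dtype=bool)
    if positions.shape != affected.shape:
        raise ValueError("positions and affected flags must align")
    n = len(positions)
    k = int(affected.sum())
    if k < 2:
        raise ValueError("clustering undefined for fewer than two affected genes")
    if n < 3:
        raise ValueError("need at least three genes")
    order = np.argsort(positions, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    s_obs = float(_mean_nn_distance(np.sort(ranks[affected])[None, :])[0])
    if k == n:
        return ClusteringResult(s_obs, 1.0, b, n, k)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    chunk = max(1, int(2e7 // max(n, 1)))
    done = 0
    while done < b:
        size = min(chunk, b - done)
        keys = rng.random((size, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k] + 1  # ranks are 1..n
        s_rep = _mean_nn_distance(np.sort(idx, axis=1))
        hits += int((s_rep <= s_obs + 1e-12).sum())
        done += size
    return ClusteringResult(s_obs, (hits + 1) / (b + 1), b, n, k)


# ---------------------------------------------------------------------------
# breakpoint distance, breadth, level, platform


@dataclass
class DistanceCorrelation:
    r: float
    n: int
    defined: bool  # False when a variable is constant (r undefined)


def breakpoint_distance(annot: pd.DataFrame, region: RegionConfig, probes=None) -> pd.Series:
    """Minimum distance from each probe midpoint to either interval breakpoint."""
    sub = annot if probes is None else annot.loc[pd.Index(probes)]
    mid = sub["midpoint"]
    return pd.concat([(mid - region.left).abs(), (mid - region.right).abs()], axis=1).min(axis=1)


def breakpoint_distance_correlation(
    log2fc: pd.Series, annot: pd.DataFrame, region: RegionConfig
) -> DistanceCorrelation:
    """Pearson r between |log2FC| and breakpoint distance over the given probes.

    ``log2fc`` may contain repeated probe ids (tissues pooled by concatenation).
    """
    if len(log2fc) < 3:
        raise ValueError("need at least three points")
    dist = breakpoint_distance(annot, region, log2fc.index).to_numpy(dtype=float)
    y = np.abs(log2fc.to_numpy(dtype=float))
    if np.ptp(dist) == 0 or np.ptp(y) == 0:
        return DistanceCorrelation(float("nan"), len(y), defined=False)
    r = stats.pearsonr(dist, y).statistic
    return DistanceCorrelation(float(r), len(y), defined=True)


@dataclass
class GroupComparison:
    mean_a: float
    median_a: float
    n_a: int
    mean_b: float
    median_b: float
    n_b: int
    u_statistic: float
    p_value: float
    method: str


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> GroupComparison:
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        float(np.mean(a)), float(np.median(a)), len(a),
        float(np.mean(b)), float(np.median(b)), len(b),
        float(res.statistic), float(min(1.0, res.pvalue)), method,
    )


def tissue_breadth_comparison(breadth: pd.Series, affected) -> GroupComparison:
    """Mann-Whitney comparison of tissue breadth: affected vs all other probes."""
    affected = pd.Index(affected)
    a = breadth.loc[breadth.index.isin(affected)].to_numpy(dtype=float)
    b = breadth.loc[~breadth.index.isin(affected)].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    return _mannwhitney(a, b)


@dataclass
class LevelComparison:
    comparison: GroupComparison
    smooth: pd.DataFrame  # columns: level, statistic, smoothed


def expression_level_comparison(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    affected,
    tissue: str,
    statistic: pd.Series | None = None,
) -> LevelComparison:
    """Are affected probes expressed at different levels than the rest?

    Compares wild-type mean log2 levels (Mann-Whitney) and returns a lowess
    smooth of a per-probe statistic (e.g. the ANOVA F) against level for
    diagnostic plotting.
    """
    cols = samples.index[(samples["tissue"] == tissue) & (samples["genotype"] == WILDTYPE)]
    if len(cols) == 0:
        raise ValueError(f"no wild-type samples in tissue {tissue!r}")
    level = matrix[cols.to_list()].mean(axis=1)
    affected = pd.Index(affected)
    a = level.loc[level.index.isin(affected)].to_numpy(dtype=float)
    b = level.loc[~level.index.isin(affected)].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    comparison = _mannwhitney(a, b)
    if statistic is None:
        smooth = pd.DataFrame(columns=["level", "statistic", "smoothed"])
    else:
        stat = statistic.loc[level.index].to_numpy(dtype=float)
        x = level.to_numpy(dtype=float)
        order = np.argsort(x, kind="stable")
        fitted = lowess(
            stat[order], x[order], frac=0.3, delta=0.01 * np.ptp(x), return_sorted=False
        )
        smooth = pd.DataFrame(
            {"level": x[order], "statistic": stat[order], "smoothed": fitted},
            index=level.index[order],
        )
    return LevelComparison(comparison, smooth)


def platform_concordance(x, y) -> float:
    """Squared Pearson correlation between paired measurements (e.g. array vs qPCR)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired measurements must have equal length")
    if len(x) < 3:
        raise ValueError("need at least three pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("measurements must be finite")
    return float(stats.pearsonr(x, y).statistic ** 2)
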