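"""Strain-background confound filter.

Probes whose expression differs between the two inbred strains of an
independent reference dataset (Welch test per tissue, Benjamini-Hochberg FDR
within tissue, flagged when q < threshold in at least one tissue) may reflect
genetic background rather than the engineered CNV and are removed from the
candidate set to form the restricted ("Most-diff-restricted") analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .diffexp import _tissue_groups, welch


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class StrainFilterResult:
    """Per-probe strain-difference tests and the resulting removal set."""

    pvalues: pd.DataFrame  # probes x tissues
    qvalues: pd.DataFrame  # probes x tissues, BH within tissue
    flagged: pd.Series  # bool per probe: q < threshold in >= 1 tissue
    threshold: float

    @property
    def removed(self) -> set[str]:
        return set(self.flagged.index[self.flagged])

    def restricted(self, candidates) -> set[str]:
        return set(candidates) - self.removed


def strain_de_flags(
    matrix: pd.DataFrame, samples: pd.DataFrame, threshold: float = 0.1
) -> StrainFilterResult:
    """Flag probes differentially expressed between the two reference strains.

    ``samples`` must carry ``strain_label`` with exactly two levels and >= 2
    replicates per strain per tissue.
    """
    if "strain_label" not in samples.columns:
        raise ValueError("reference sample table lacks a strain_label column")
    strains = sorted(set(samples["strain_label"]))
    if len(strains) != 2:
        raise ValueError(f"expected exactly two strains, found {strains}")
    tissues = list(dict.fromkeys(samples["tissue"]))
    pvals, qvals = {}, {}
    for t in tissues:
        groups = _tissue_groups(matrix, samples, t, group_col="strain_label")
        _, p = welch(groups[strains[0]], groups[strains[1]])
        pvals[t] = p
        qvals[t] = bh_adjust(p)
    pvalues = pd.DataFrame(pvals, index=matrix.index)
    qvalues = pd.DataFrame(qvals, index=matrix.index)
    flagged = (qvalues < threshold).any(axis=1)
    flagged.name = "flagged"
    return StrainFilterResult(pvalues, qvalues, flagged, threshold)


def restrict_set(candidates, filter_result: StrainFilterResult) -> set[str]:
    """Candidate probes minus the strain-flagged ones (Most-diff-restricted)."""
    return filter_result.restricted(candidates)
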