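"""Synthetic expression datasets emulating an engineered-CNV study design.

The generator produces a probes x samples log2-intensity matrix for four
genotypes (one, two-in-trans, two-in-cis, or three copies of a rearranged
interval) across several tissues, together with sample metadata, a probe
annotation and a ground-truth table recording every injected effect:

* multiplicative dosage effects on interval probes (default 0.66x / 1.02x /
  1.38x for one, two-in-cis and three copies, relative to wild type);
* copy-number-independent "structural" shifts on a fraction of flanking probes
  on the CNV chromosome, sharing their sign across all three rearranged
  genotypes with configurable probability;
* strain-background artifacts confined to a distal block of the CNV
  chromosome, present in all rearranged genotypes of the main dataset and
  distinguishing the two inbred strains of the companion reference dataset;
* homoscedastic Gaussian noise on the log2 scale.

A probe is "expressed" in a random subset of tissues; in tissues where it is
not expressed its signal is background drawn below the detection threshold and
no effect applies.  Interval probes are expressed in every tissue so that the
dosage signal is defined everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    GENOTYPES,
    WILDTYPE,
    RegionConfig,
    build_probe_annotation,
    write_expression_matrix,
    write_probe_annotation_bed,
    write_region_config,
    write_sample_table,
)

REARRANGED = ("1n", "2n_cis", "3n")

#: anchor-gene copy-number exceptions: engineering anchors whose active copy
#: number does not track the interval copy number.
ANCHOR_OVERRIDES = {
    "cops3_like": {"1n": 1, "2n_trans": 2, "2n_cis": 1, "3n": 2},
    "zfp179_like": {"1n": 2, "2n_trans": 2, "2n_cis": 3, "3n": 2},
}

_NONCONSTANT_SIGN_PATTERNS = np.array(
    [p for p in np.ndindex(2, 2, 2) if len(set(p)) > 1], dtype=float
) * 2.0 - 1.0  # six (+/-1)^3 patterns that are not all-equal


@dataclass
class GeneratorConfig:
    """Full effect model of the synthetic study.

    Defaults encode the emulated design: ~70 interval probesets among 20,000,
    five tissues, >=3 replicates per genotype x tissue, dosage ratios
    0.66 / 1.02 / 1.38, and a strain-artifact block distal to the interval.
    """

    n_probes: int = 20_000
    n_interval_probes: int = 70
    n_cnv_chr_probes: int = 1_200
    cnv_chromosome: str = "chr11"
    cnv_chr_length: int = 122_000_000
    interval_start: int = 76_843_886
    interval_end: int = 92_963_733
    tissues: tuple[str, ...] = ("cerebellum", "heart", "kidney", "testis", "hippocampus")
    replicates: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    unexpressed_mean: float = 3.0
    dosage_ratio: dict = field(
        default_factory=lambda: {"1n": 0.66, "2n_trans": 1.0, "2n_cis": 1.02, "3n": 1.38}
    )
    anchor_probes: bool = True
    flank_fraction: float = 0.15
    flank_shift_sd: float = 0.4
    flank_shared_direction_prob: float = 0.8
    strain_block: tuple[int, int] = (93_500_000, 122_000_000)
    strain_affected_fraction: float = 0.3
    strain_effect_min: float = 0.5
    strain_effect_sd: float = 0.5
    noise_sd: float = 0.25
    cpg_fraction: float = 0.4
    breadth_prob: float = 0.36
    breadth_prob_flank_effect: float = 0.52
    reference_tissues: tuple[str, ...] = ("brain", "liver", "testis", "kidney", "lung", "heart")
    reference_strains: tuple[str, str] = ("129S2", "C57BL6J")
    reference_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_interval_probes + 2 > self.n_cnv_chr_probes or self.n_cnv_chr_probes > self.n_probes:
            raise ValueError("need n_interval_probes < n_cnv_chr_probes <= n_probes")
        if any(r <= 0 for r in self.dosage_ratio.values()):
            raise ValueError("dosage ratios must be positive")
        for name in ("flank_fraction", "flank_shared_direction_prob", "strain_affected_fraction",
                     "cpg_fraction", "breadth_prob", "breadth_prob_flank_effect"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.replicates < 2 or self.reference_replicates < 2:
            raise ValueError("need >=2 replicates per cell")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def region(self) -> RegionConfig:
        return RegionConfig(self.cnv_chromosome, self.interval_start, self.interval_end)

    def detection_threshold(self) -> float:
        """Log2 level separating the expressed and background modes."""
        return 0.5 * (self.baseline_mean + self.unexpressed_mean)

    def null(self) -> "GeneratorConfig":
        """Copy of the config with every injected effect switched off."""
        return replace(
            self,
            dosage_ratio={g: 1.0 for g in GENOTYPES},
            flank_fraction=0.0,
            strain_affected_fraction=0.0,
        )


@dataclass
class SyntheticDataset:
    """A generated dataset: matrix, metadata, annotation and ground truth."""

    matrix: pd.DataFrame
    samples: pd.DataFrame
    annot: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig

    def expected_log2_mean(self, probe: str, genotype: str, tissue: str) -> float:
        return expected_log2_mean(probe, genotype, tissue, self.truth, self.config)

    def __iter__(self):  # allow tuple-style unpacking
        return iter((self.matrix, self.samples, self.annot, self.truth))


# ---------------------------------------------------------------------------
# truth construction


def _copies_ratio(copies: int, ratio: dict) -> float:
    table = {1: ratio["1n"], 2: 1.0, 3: ratio["3n"]}
    if copies not in table:
        raise ValueError(f"unsupported active copy number {copies} (need 1, 2 or 3)")
    return table[copies]


def _build_annotation(config: GeneratorConfig, rng: np.random.Generator):
    n, n_cnv, n_int = config.n_probes, config.n_cnv_chr_probes, config.n_interval_probes
    width = len(str(n))
    probe_ids = np.array([f"p{i:0{width}d}" for i in range(1, n + 1)])
    chromosome = np.empty(n, dtype=object)
    mid = np.empty(n, dtype=np.int64)

    # interval probes: evenly spread midpoints across the rearranged interval
    span = config.interval_end - config.interval_start
    mid[:n_int] = config.interval_start + (
        (np.arange(n_int) + 0.5) / n_int * span
    ).astype(np.int64)
    # other CNV-chromosome probes: uniform over the chromosome outside the interval
    n_flank = n_cnv - n_int
    left = rng.integers(1, config.interval_start, size=n_flank)
    right = rng.integers(config.interval_end + 1, config.cnv_chr_length, size=n_flank)
    frac_left = (config.interval_start - 1) / (
        config.cnv_chr_length - (config.interval_end - config.interval_start)
    )
    take_left = rng.random(n_flank) < frac_left
    mid[n_int:n_cnv] = np.where(take_left, left, right)
    chromosome[:n_cnv] = config.cnv_chromosome
    # remaining probes: spread over other chromosomes
    others = [f"chr{i}" for i in list(range(1, 20)) + ["X"] if f"chr{i}" != config.cnv_chromosome]
    chromosome[n_cnv:] = np.array(others)[np.arange(n - n_cnv) % len(others)]
    mid[n_cnv:] = rng.integers(1, 150_000_000, size=n - n_cnv)

    half = 25  # nominal probe footprint
    frame = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": chromosome,
            "start": np.maximum(mid - half, 1),
            "end": mid + half,
            "gene_id": np.char.replace(probe_ids.astype(str), "p", "g"),
            "cpg_neighbor": rng.random(n) < config.cpg_fraction,
        }
    )
    overrides = {}
    if config.anchor_probes:
        anchor_ids = probe_ids[:2]
        frame.loc[0, "gene_id"] = "cops3_like"
        frame.loc[1, "gene_id"] = "zfp179_like"
        overrides = {
            anchor_ids[0]: ANCHOR_OVERRIDES["cops3_like"],
            anchor_ids[1]: ANCHOR_OVERRIDES["zfp179_like"],
        }
    return build_probe_annotation(frame, config.region, overrides), overrides


def _build_truth(config: GeneratorConfig, annot: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    n = len(annot)
    truth = pd.DataFrame(index=annot.index)
    truth["baseline"] = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    is_interval = (annot["region_class"] == "interval").to_numpy()
    is_flank = (annot["region_class"] == "flank_cnv_chr").to_numpy()
    has_override = np.zeros(n, dtype=bool)
    for g in GENOTYPES:
        default = np.where(is_interval, {"1n": 1, "2n_trans": 2, "2n_cis": 2, "3n": 3}[g], 2)
        has_override |= annot[f"copies_{g}"].to_numpy() != default

    # dosage multipliers (linear scale)
    for g in GENOTYPES:
        mult = np.ones(n)
        mult[is_interval] = config.dosage_ratio[g]
        if has_override.any():
            copies = annot.loc[has_override, f"copies_{g}"]
            mult[has_override] = [_copies_ratio(int(c), config.dosage_ratio) for c in copies]
        truth[f"dosage_mult_{g}"] = mult

    # flanking structural effects: one magnitude per carrier, sign pattern
    # constant across the rearranged genotypes with prob flank_shared_direction_prob
    flank_idx = np.flatnonzero(is_flank)
    n_carriers = int(round(config.flank_fraction * len(flank_idx)))
    carriers = rng.choice(flank_idx, size=n_carriers, replace=False) if n_carriers else np.array([], int)
    carrier_mask = np.zeros(n, dtype=bool)
    carrier_mask[carriers] = True
    magnitude = np.abs(rng.normal(0.0, config.flank_shift_sd, size=n_carriers))
    base_sign = rng.choice([-1.0, 1.0], size=n_carriers)
    shared = rng.random(n_carriers) < config.flank_shared_direction_prob
    signs = np.repeat(base_sign[:, None], 3, axis=1)
    n_mixed = int((~shared).sum())
    if n_mixed:
        pick = rng.integers(0, len(_NONCONSTANT_SIGN_PATTERNS), size=n_mixed)
        signs[~shared] = _NONCONSTANT_SIGN_PATTERNS[pick]
    truth["flank_carrier"] = carrier_mask
    for j, g in enumerate(REARRANGED):
        shift = np.zeros(n)
        shift[carriers] = signs[:, j] * magnitude
        truth[f"flank_shift_{g}"] = shift

    # strain-background artifacts: distal block of the CNV chromosome
    lo, hi = config.strain_block
    in_block = (
        (annot["chromosome"] == config.cnv_chromosome)
        & (annot["midpoint"] >= lo)
        & (annot["midpoint"] <= hi)
    ).to_numpy()
    block_idx = np.flatnonzero(in_block)
    n_strain = int(round(config.strain_affected_fraction * len(block_idx)))
    hit = rng.choice(block_idx, size=n_strain, replace=False) if n_strain else np.array([], int)
    effect = np.zeros(n)
    if n_strain:
        effect[hit] = rng.choice([-1.0, 1.0], size=n_strain) * (
            config.strain_effect_min + np.abs(rng.normal(0.0, config.strain_effect_sd, size=n_strain))
        )
    truth["strain_effect"] = effect

    # tissue-expression sets: flank-effect carriers have broader breadth
    p = np.where(carrier_mask, config.breadth_prob_flank_effect, config.breadth_prob)
    for t in config.tissues:
        expressed = rng.random(n) < p
        expressed[is_interval] = True  # interval probes expressed everywhere
        truth[f"expressed_{t}"] = expressed
    return truth


def expected_log2_mean(
    probe: str, genotype: str, tissue: str, truth: pd.DataFrame, config: GeneratorConfig
) -> float:
    """Deterministic noiseless mean for one (probe, genotype, tissue)."""
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    row = truth.loc[probe]
    if not row[f"expressed_{tissue}"]:
        return float(config.unexpressed_mean)
    mean = row["baseline"] + np.log2(row[f"dosage_mult_{genotype}"])
    if genotype in REARRANGED:
        mean += row[f"flank_shift_{genotype}"]
        mean += row["strain_effect"]
    return float(mean)


def _mean_matrix(
    truth: pd.DataFrame, config: GeneratorConfig, genotypes: Sequence[str], tissues: Sequence[str]
) -> dict[tuple[str, str], np.ndarray]:
    """Noiseless mean vector per (genotype, tissue) over all probes."""
    baseline = truth["baseline"].to_numpy()
    out = {}
    for g in genotypes:
        mean_g = baseline + np.log2(truth[f"dosage_mult_{g}"].to_numpy())
        if g in REARRANGED:
            mean_g = mean_g + truth[f"flank_shift_{g}"].to_numpy() + truth["strain_effect"].to_numpy()
        for t in tissues:
            expressed = truth[f"expressed_{t}"].to_numpy()
            out[(g, t)] = np.where(expressed, mean_g, config.unexpressed_mean)
    return out


# ---------------------------------------------------------------------------
# dataset generation


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate the main four-genotype dataset.

    All randomness derives from ``config.seed`` through a fixed spawn order
    (layout, truth, main noise, reference noise); the same seed reproduces the
    output bit for bit.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_layout, rng_truth, rng_noise, _ = [np.random.default_rng(s) for s in ss.spawn(4)]
    annot, _ = _build_annotation(config, rng_layout)
    truth = _build_truth(config, annot, rng_truth)

    means = _mean_matrix(truth, config, GENOTYPES, config.tissues)
    sample_rows, columns = [], []
    for g in GENOTYPES:
        for t in config.tissues:
            for r in range(1, config.replicates + 1):
                sid = f"{g}_{t}_r{r}"
                sample_rows.append({"sample_id": sid, "genotype": g, "tissue": t, "replicate": r})
                columns.append(means[(g, t)])
    values = np.column_stack(columns)
    if config.noise_sd > 0:
        values = values + rng_noise.normal(0.0, config.noise_sd, size=values.shape)
    samples = pd.DataFrame(sample_rows).set_index("sample_id", drop=False)
    matrix = pd.DataFrame(values, index=annot.index, columns=samples.index.to_list())
    matrix.columns.name = None
    return SyntheticDataset(matrix, samples, annot, truth, config)


def generate_strain_reference(
    config: GeneratorConfig, dataset: SyntheticDataset | None = None
) -> SyntheticDataset:
    """Generate the two-strain reference dataset used by the confound filter.

    Shares the probe universe (and strain-artifact truth) of the main dataset;
    the first configured strain carries the injected artifacts.  Probes are
    treated as expressed in every reference tissue.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_layout, rng_truth, _, rng_ref = [np.random.default_rng(s) for s in ss.spawn(4)]
    if dataset is None:
        annot, _ = _build_annotation(config, rng_layout)
        truth = _build_truth(config, annot, rng_truth)
    else:
        annot, truth = dataset.annot, dataset.truth
        if not annot.index.equals(truth.index):
            raise ValueError("probe universe mismatch between annotation and truth")

    baseline = truth["baseline"].to_numpy()
    artifact = truth["strain_effect"].to_numpy()
    strain_a, strain_b = config.reference_strains
    sample_rows, columns = [], []
    for strain in (strain_a, strain_b):
        mean_s = baseline + (artifact if strain == strain_a else 0.0)
        for t in config.reference_tissues:
            for r in range(1, config.reference_replicates + 1):
                sid = f"{strain}_{t}_r{r}"
                sample_rows.append(
                    {"sample_id": sid, "strain_label": strain, "tissue": t, "replicate": r}
                )
                columns.append(mean_s)
    values = np.column_stack(columns)
    if config.noise_sd > 0:
        values = values + rng_ref.normal(0.0, config.noise_sd, size=values.shape)
    samples = pd.DataFrame(sample_rows).set_index("sample_id", drop=False)
    matrix = pd.DataFrame(values, index=annot.index, columns=samples.index.to_list())
    matrix.columns.name = None
    return SyntheticDataset(matrix, samples, annot, truth, config)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path, prefix: str = "main") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(dataset.matrix, outdir / f"{prefix}_matrix.tsv")
    write_sample_table(dataset.samples, outdir / f"{prefix}_samples.tsv")
    write_probe_annotation_bed(dataset.annot, outdir / f"{prefix}_probes.bed")
    truth = dataset.truth.copy()
    truth.index.name = "probe_id"
    truth.to_csv(outdir / f"{prefix}_truth.tsv", sep="\t")
    cfg = dataset.config
    overrides = {}
    if cfg.anchor_probes:
        ids = dataset.annot.index[:2]
        overrides = {ids[0]: ANCHOR_OVERRIDES["cops3_like"], ids[1]: ANCHOR_OVERRIDES["zfp179_like"]}
    write_region_config(outdir / "region.yaml", cfg.region, overrides)
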