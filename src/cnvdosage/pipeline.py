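"""End-to-end orchestration: simulate/load -> validate -> rank -> enrich ->
strain-filter -> flanking statistics, with a machine-readable JSON report.

Every stage is a pure function of its inputs and the run seed, so an identical
(config, seed) pair regenerates an identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    GENOTYPES,
    WILDTYPE,
    load_region_config,
    read_expression_matrix,
    read_probe_annotation,
    read_sample_table,
    validate_dataset,
)
from .simulate import (
    REARRANGED,
    GeneratorConfig,
    SyntheticDataset,
    generate_dataset,
    generate_strain_reference,
)
from .diffexp import detection_call, diffexp_table, rank_top_k
from .enrichment import cpg_enrichment, enrich_topk
from .strainfilter import bh_adjust, restrict_set, strain_de_flags
from .flank import (
    breakpoint_distance_correlation,
    clustering_test,
    direction_concordance,
    dosage_summary,
    expression_level_comparison,
    tissue_breadth_comparison,
)

log = logging.getLogger("cnvdosage")


@dataclass
class PipelineConfig:
    """Run configuration: either generator settings or input paths per dataset."""

    generator: GeneratorConfig | None = field(default_factory=GeneratorConfig)
    # path-based input (exclusive with generator)
    matrix_path: str | None = None
    samples_path: str | None = None
    probes_bed: str | None = None
    region_yaml: str | None = None
    reference_matrix_path: str | None = None
    reference_samples_path: str | None = None
    k_presets: tuple[int, ...] = (100, 1000)
    b_permutations: int = 100_000
    clustering_permutations: int = 10_000
    fdr: float = 0.1
    contrast_q: float = 0.05
    detection_threshold: float | None = None
    strain_filter: bool = True
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        paths = [self.matrix_path, self.samples_path, self.probes_bed, self.region_yaml]
        if self.generator is not None and any(p is not None for p in paths):
            raise ValueError("give either generator settings or input paths, not both")
        if self.generator is None and not all(p is not None for p in paths):
            raise ValueError("path-based input needs matrix, samples, probes and region files")
        if not (0 < self.fdr < 1 and 0 < self.contrast_q < 1):
            raise ValueError("fdr and contrast_q must lie in (0, 1)")
        if any(k <= 0 for k in self.k_presets):
            raise ValueError("K presets must be positive")

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def _load_or_generate(config: PipelineConfig):
    if config.generator is not None:
        gen = replace(config.generator, seed=config.seed)
        dataset = generate_dataset(gen)
        log.info("generated dataset: %d probes x %d samples", *dataset.matrix.shape)
        return dataset, dataset.matrix, dataset.samples, dataset.annot, gen.region
    matrix = read_expression_matrix(config.matrix_path)
    samples = read_sample_table(config.samples_path)
    region, overrides = load_region_config(config.region_yaml)
    annot = read_probe_annotation(config.probes_bed, region, overrides)
    log.info("loaded dataset: %d probes x %d samples", *matrix.shape)
    return None, matrix, samples, annot, region


def summarize_region_composition(topk_sets: list, annot: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions per region class for each top-K set."""
    rows = []
    for topk in topk_sets:
        classes = annot.loc[list(topk.probes), "region_class"]
        for cls in ("interval", "flank_cnv_chr", "other"):
            n = int((classes == cls).sum())
            rows.append(
                {"tissue": topk.tissue, "k": topk.k, "region_class": cls,
                 "count": n, "proportion": n / topk.k}
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the report dictionary."""
    ss = np.random.SeedSequence(config.seed)
    rng_enrich, rng_cluster, rng_cpg = [np.random.default_rng(s) for s in ss.spawn(3)]

    dataset, matrix, samples, annot, region = _load_or_generate(config)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "tissues": list(dict.fromkeys(samples["tissue"])),
    }

    validation = validate_dataset(matrix, samples, annot)
    report["validation"] = validation.to_dict()
    if not validation.passed:
        raise RuntimeError(f"stage validate failed: {validation.findings[0].message}")

    tissues = report["tissues"]
    de = {t: diffexp_table(matrix, samples, t) for t in tissues}
    log.info("diffexp: %d tissues ranked", len(de))

    topk_sets = [rank_top_k(de[t], t, k) for t in tissues for k in config.k_presets]
    report["region_composition"] = summarize_region_composition(topk_sets, annot).to_dict("records")

    enrichment_rows = []
    for topk in topk_sets:
        for cls in ("interval", "flank_cnv_chr"):
            res = enrich_topk(
                topk, annot, "region_class", cls, b=config.b_permutations, seed=rng_enrich
            )
            enrichment_rows.append(_jsonable(res))
    report["enrichment"] = enrichment_rows
    log.info("enrichment: %d tests", len(enrichment_rows))

    # Most-diff flank sets and affected probes: flank members of the top-K list
    # whose contrast vs wild type survives BH (within the candidate set) in at
    # least one rearranged genotype
    k_max = max(config.k_presets)
    flank_ids = set(annot.index[annot["region_class"] == "flank_cnv_chr"])
    mostdiff_flank: dict[str, list[str]] = {}
    affected: set[str] = set()
    dereg_sets: dict[str, set[str]] = {g: set() for g in REARRANGED}
    for t in tissues:
        members = [p for p in rank_top_k(de[t], t, k_max).probes if p in flank_ids]
        mostdiff_flank[t] = members
        for g in REARRANGED:
            col = f"pvalue_{g}"
            if col not in de[t].columns or not members:
                continue
            q = pd.Series(bh_adjust(de[t].loc[members, col].to_numpy()), index=members)
            de[t].loc[members, f"q_{g}"] = q
            hits = set(q.index[q < config.contrast_q])
            dereg_sets[g] |= hits
            affected |= hits
    report["affected_flank"] = {"n": len(affected), "per_tissue_mostdiff": {t: len(v) for t, v in mostdiff_flank.items()}}

    # strain-background filter on the reference dataset
    candidates = set().union(*(mostdiff_flank[t] for t in tissues)) | (
        set().union(*(set(s.probes) for s in topk_sets)) & set(annot.index[annot["chromosome"] == _cnv_chromosome(annot)])
    )
    if config.strain_filter:
        if config.generator is not None:
            reference = generate_strain_reference(dataset.config, dataset)
            ref_matrix, ref_samples = reference.matrix, reference.samples
        else:
            if not (config.reference_matrix_path and config.reference_samples_path):
                raise RuntimeError("stage strainfilter failed: missing reference dataset input")
            ref_matrix = read_expression_matrix(config.reference_matrix_path)
            ref_samples = read_sample_table(config.reference_samples_path)
        sf = strain_de_flags(ref_matrix, ref_samples, threshold=config.fdr)
        restricted = restrict_set(candidates, sf)
        report["strain_filter"] = {
            "fdr": config.fdr,
            "n_flagged_total": int(sf.flagged.sum()),
            "n_candidates": len(candidates),
            "n_removed": len(candidates) - len(restricted),
            "n_restricted": len(restricted),
        }
        affected_restricted = affected & restricted
    else:
        sf = None
        report["strain_filter"] = None
        affected_restricted = affected

    # dosage response of interval probes
    ds = dosage_summary(matrix, samples, annot)
    report["dosage_summary"] = ds.table.to_dict("records")

    # direction concordance over Most-diff flank sets (and restricted variant)
    conc = {}
    variants = [("mostdiff", None)] + ([("mostdiff_restricted", sf)] if sf is not None else [])
    for label, keep in variants:
        agree = used = 0
        per_tissue = {}
        for t in tissues:
            members = mostdiff_flank[t]
            if keep is not None:
                members = sorted(restrict_set(members, keep))
            if not members:
                continue
            contrasts = {g: de[t][f"log2fc_{g}"] for g in REARRANGED}
            res = direction_concordance(contrasts, members)
            per_tissue[t] = res.threeway
            agree += res.threeway * res.n_used
            used += res.n_used
        conc[label] = {
            "threeway": agree / used if used else float("nan"),
            "n_used": used,
            "per_tissue": per_tissue,
        }
    report["concordance"] = conc

    # chromosomal clustering of affected genes along the CNV chromosome
    cnv_chr = _cnv_chromosome(annot)
    on_chr = annot[(annot["chromosome"] == cnv_chr) & (annot["region_class"] == "flank_cnv_chr")]
    flags = on_chr.index.isin(affected)
    if flags.sum() >= 2:
        cl = clustering_test(
            on_chr["midpoint"].to_numpy(), flags,
            b=config.clustering_permutations, seed=rng_cluster,
        )
        report["clustering"] = _jsonable(cl)
    else:
        report["clustering"] = None

    # CpG-neighbour enrichment within the affected flank set
    if affected:
        cpg = cpg_enrichment(sorted(affected), annot, b=config.b_permutations, seed=rng_cpg)
        report["cpg_enrichment"] = _jsonable(cpg)
    else:
        report["cpg_enrichment"] = None

    # breakpoint-distance correlation per genotype, tissues pooled
    dist_corr = {}
    for g in REARRANGED:
        pooled = pd.concat(
            [de[t].loc[sorted(affected), f"log2fc_{g}"] for t in tissues]
        ) if affected else pd.Series(dtype=float)
        if len(pooled) >= 3:
            dist_corr[g] = _jsonable(breakpoint_distance_correlation(pooled, annot, region))
        else:
            dist_corr[g] = None
    report["breakpoint_distance_correlation"] = dist_corr

    # tissue breadth and expression level of affected vs other probes
    threshold = config.detection_threshold
    if threshold is None and dataset is not None:
        threshold = dataset.config.detection_threshold()
    _, breadth = detection_call(matrix, samples, threshold)
    if affected:
        report["tissue_breadth"] = _jsonable(tissue_breadth_comparison(breadth, sorted(affected)))
        level_p = {}
        for t in tissues:
            lc = expression_level_comparison(matrix, samples, sorted(affected), t, de[t]["F"])
            level_p[t] = lc.comparison.p_value
        report["expression_level_pvalues"] = level_p
    else:
        report["tissue_breadth"] = None
        report["expression_level_pvalues"] = None

    # per-genotype deregulation counts among Most-diff flank members
    union_members = set().union(*(mostdiff_flank[t] for t in tissues)) if tissues else set()
    report["flank_deregulated"] = {g: len(v) for g, v in dereg_sets.items()}
    report["flank_union_size"] = len(union_members)

    if config.outdir:
        _write_outputs(config, report, de, topk_sets)
    return report


def _cnv_chromosome(annot: pd.DataFrame) -> str:
    on_interval = annot.loc[annot["region_class"] == "interval", "chromosome"]
    if on_interval.empty:
        raise ValueError("annotation has no interval probes; CNV chromosome unknown")
    return str(on_interval.iloc[0])


def _write_outputs(config: PipelineConfig, report: dict, de: dict, topk_sets: list) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for t, table in de.items():
        out = table.copy()
        out.index.name = "probe_id"
        out.to_csv(outdir / f"diffexp_{t}.tsv", sep="\t", float_format="%.6g")
    rows = [
        {"tissue": s.tissue, "k": s.k, "rank": i + 1, "probe_id": p}
        for s in topk_sets
        for i, p in enumerate(s.probes)
    ]
    pd.DataFrame(rows).to_csv(outdir / "topk_members.tsv", sep="\t", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    log.info("report written to %s", outdir / "report.json")
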