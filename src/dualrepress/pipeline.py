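"""End-to-end synthetic benchmark run.

Generates every input with planted truth, pushes it through the full
analysis (filter → normalize → log2 → d-statistic → permutation FDR →
DEG calls → enrichment → seed scan → integration) and returns both the
results and the truth record, so recovery can be scored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dualrepress import io
from dualrepress.enrichment import EnrichmentResult, RegulatoryNetwork, enrich_all
from dualrepress.expression import (
    DEResult,
    ExpressionMatrix,
    call_degs,
    detection_filter,
    log2_transform,
    quantile_normalize,
    sam_fdr,
)
from dualrepress.integrate import bound_upregulated, dual_regulated, write_report
from dualrepress.seeds import MirnaRecord, mirna_target_genes, scan_all
from dualrepress.synthetic import (
    SynthConfig,
    TruthRecord,
    generate_annotation,
    generate_expression,
    generate_network,
    generate_transcript_regions,
)

logger = logging.getLogger(__name__)

# default miRNA used by the synthetic benchmark (arbitrary valid sequence)
DEFAULT_MIRNA = MirnaRecord(id="synth-mir", sequence="AAAGTGCTTCCCTTTTGTGTGT")


@dataclass
class RunResult:
    """Everything produced by one synthetic end-to-end run."""

    config: SynthConfig
    truth: TruthRecord
    matrix: ExpressionMatrix
    de: DEResult
    up_in_b: set[str]
    up_in_a: set[str]
    network: RegulatoryNetwork
    universe: set[str]
    enrichment: EnrichmentResult
    seed_report: pd.DataFrame
    bound_up: pd.DataFrame
    dual: pd.DataFrame
    annotation: dict[str, set[str]]
    regions: dict[str, str]
    mirna: MirnaRecord

    @property
    def truth_dual(self) -> set[str]:
        """Planted dual set: bound by the planted regulator, planted up,
        annotated, and carrying planted seed sites."""
        reg = sorted(self.truth.enriched_regulators)
        bound = self.network.target_set(reg[0]) if reg else set()
        return (
            bound
            & self.truth.up_genes()
            & self.truth.annotation_members
            & self.truth.seed_positive_genes()
        )

    @property
    def called_dual(self) -> set[str]:
        return set(self.dual.loc[self.dual["dual"], "gene"])


def run_synthetic_pipeline(
    config: SynthConfig,
    mirna: MirnaRecord = DEFAULT_MIRNA,
    fdr_threshold: float = 0.001,
    lfc_threshold: float = 1.0,
    n_perms: int = 1000,
    n_resamples: int = 1000,
    alpha: float = 0.05,
    s0_policy: float | str = "median",
    outdir: str | Path | None = None,
) -> RunResult:
    """Generate, analyze, integrate; optionally write all artifacts.

    The annotation set is seeded with the planted regulator's planted-up
    targets (the bound+derepressed truth) and a configured fraction of
    those genes (``config.frac_dual``) receives planted seed sites, so
    the run has a known dual-regulation ground truth.
    """
    matrix, truth = generate_expression(config)
    network, truth = generate_network(config, truth)
    regulator = config.regulator_ids()[0]

    # --- expression preprocessing (filter first: dual truth is planted
    # only among genes that survive detection, so recovery is not capped
    # by random absent flags)
    filtered = detection_filter(matrix)
    detected_genes = set(filtered.gene_ids)

    # --- plant annotation and seed sites around the detected bound∩up truth
    candidates = sorted(
        network.target_set(regulator) & truth.up_genes() & detected_genes
    )
    plan_rng = config.rng(97)
    annot_members = list(candidates[: config.annotation_size])
    others = [g for g in config.gene_ids() if g not in set(annot_members)]
    n_fill = config.annotation_size - len(annot_members)
    if n_fill > 0:
        annot_members += list(plan_rng.choice(others, size=n_fill, replace=False))
    annotation, truth = generate_annotation(config, truth, members=annot_members)

    bound_up_truth = sorted(set(candidates) & truth.annotation_members)
    n_dual = int(round(config.frac_dual * len(bound_up_truth)))
    dual_genes = list(
        plan_rng.choice(bound_up_truth, size=n_dual, replace=False)
        if n_dual
        else []
    )
    site_plan: dict[str, list[str]] = {}
    for g in dual_genes:
        # one 7-mer in the 3'UTR, occasionally an extra 6-mer in the ORF
        site_plan[f"{g}|3UTR"] = ["7mer"]
        if plan_rng.random() < 0.3:
            site_plan[f"{g}|ORF"] = ["6mer"]
    transcript_genes = sorted(
        set(truth.annotation_members) | set(dual_genes)
    )
    regions, truth = generate_transcript_regions(
        config, mirna, truth=truth, genes=transcript_genes, site_plan=site_plan
    )

    # --- expression analysis
    normalized = filtered.with_values(quantile_normalize(filtered.values))
    logged = normalized.with_values(log2_transform(normalized.values))
    de = sam_fdr(logged, n_perms=n_perms, s0_policy=s0_policy)
    up_b, up_a = call_degs(de, fdr_threshold, lfc_threshold)

    # --- enrichment over detected genes present in the network
    universe = set(logged.gene_ids) & network.genes
    enrichment = enrich_all(
        network,
        up_b & universe,
        universe,
        n_resamples=n_resamples,
        alpha=alpha,
        master_seed=config.seed,
    )

    # --- seed scanning and integration
    seed_report = scan_all(regions, mirna)
    bound_up = bound_upregulated(
        network, regulator, de, truth.annotation_members
    )
    dual = dual_regulated(bound_up, seed_report)

    result = RunResult(
        config=config,
        truth=truth,
        matrix=matrix,
        de=de,
        up_in_b=up_b,
        up_in_a=up_a,
        network=network,
        universe=universe,
        enrichment=enrichment,
        seed_report=seed_report,
        bound_up=bound_up,
        dual=dual,
        annotation=annotation,
        regions=regions,
        mirna=mirna,
    )
    if outdir is not None:
        write_artifacts(result, outdir)
    return result


def write_artifacts(result: RunResult, outdir: str | Path) -> dict[str, Path]:
    """Write every generated input and computed output under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_expression(
        result.matrix, outdir / "expression.tsv", outdir / "detection.tsv"
    )
    io.write_network(result.network, outdir / "network.tsv")
    io.write_gmt(result.annotation, outdir / "annotation.gmt")
    io.write_fasta(result.regions, outdir / "regions.fa")
    io.write_fasta(
        {result.mirna.id: result.mirna.sequence}, outdir / "mirna.fa"
    )
    io.write_gene_list(result.up_in_b, outdir / "up_in_B.txt")
    io.write_gene_list(result.up_in_a, outdir / "up_in_A.txt")
    io.write_gene_list(result.universe, outdir / "universe.txt")

    de_table = result.de.table.reset_index(names="gene")
    seed_table = result.seed_report.copy()
    seed_table["positions"] = seed_table["positions"].map(
        lambda ps: ";".join(f"{k}:{p}" for k, p in ps)
    )
    enrich_table = result.enrichment.table.reset_index()
    paths = write_report(
        outdir,
        {
            "de": de_table,
            "enrichment": enrich_table,
            "seeds": seed_table,
            "bound_up": result.bound_up,
            "dual_regulation": result.dual,
        },
        config_snapshot=result.config.to_dict(),
        master_seed=result.config.seed,
        input_checksums={
            name: io.file_sha256(outdir / name)
            for name in (
                "expression.tsv",
                "detection.tsv",
                "network.tsv",
                "annotation.gmt",
                "regions.fa",
                "mirna.fa",
            )
        },
    )
    return paths
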