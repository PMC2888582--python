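"""End-to-end orchestration: simulate/load inputs, then run every stage.

Stage order: primary filter -> decoy null + empirical p-values -> protein
retention -> sum-Xcorr quantification + ANOVA differential calls ->
membership partition -> GO-slim profiling, GAQ, component partitioning ->
net-effect tables -> gene-set enrichment.  Per-stage record counts are logged
to stderr.

The decoy null is fitted from all decoy records at their raw Xcorr (the
random-match score distribution); the primary filter's score gates apply to
target PSMs, which are what the statistics and quantification consume.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from gvprotcomm import (
    FilterPolicy,
    GeneSetCollection,
    GroundTruth,
    SimulationConfig,
    anova_differential,
    apply_primary_filter,
    build_quant_matrix,
    call_proteins,
    classify_membership,
    collect_peptide_evidence,
    compare_categories,
    expression_net_effect,
    fit_decoy_null,
    gaq_score,
    map_to_slim,
    membership_counts,
    partition_by_component,
    read_gaf,
    read_gmt,
    read_obo,
    read_psm_table,
    read_regulation,
    regulation_net_effect,
    score_gene_sets,
)
from gvprotcomm.decoy_stats import calls_to_frame
from gvprotcomm.simulate import CUMULUS, OOCYTE, write_simulation

logger = logging.getLogger("gvprotcomm.pipeline")


@dataclasses.dataclass
class PipelineResult:
    """Every intermediate and final table of one pipeline run."""

    filtered_targets: pd.DataFrame
    reject_tally: dict
    protein_calls: pd.DataFrame
    quant: "object"  # QuantMatrix with stats
    membership: pd.Series
    membership_summary: dict[str, int]
    slim_map: dict[str, set[str]]
    unclassified: set[str]
    slim_summary: pd.DataFrame
    gaq_per_protein: pd.Series
    gaq_mean: float
    component_partitions: dict[str, dict[str, int]]
    expression_net: pd.DataFrame
    regulation_net: pd.DataFrame
    enrichment: pd.DataFrame
    truth: GroundTruth | None = None


def run_all(
    input_dir: str | Path,
    output_dir: str | Path | None = None,
    alpha: float = 0.05,
    policy: FilterPolicy | None = None,
) -> PipelineResult:
    """Run every stage on a directory produced by :func:`write_simulation`
    (or files following the same layout); optionally write result CSVs."""
    input_dir = Path(input_dir)
    psms = pd.concat(
        [
            read_psm_table(input_dir / f"psms_{OOCYTE}.tsv"),
            read_psm_table(input_dir / f"psms_{CUMULUS}.tsv"),
        ],
        ignore_index=True,
    )
    logger.info("loaded %d PSM records (%d decoy)", len(psms), int(psms.is_decoy.sum()))

    targets = psms[~psms["is_decoy"]].reset_index(drop=True)
    decoys = psms[psms["is_decoy"]].reset_index(drop=True)
    filtered, tally = apply_primary_filter(targets, policy)
    logger.info(
        "primary filter: %d/%d targets pass (rejections: %s)",
        len(filtered), len(targets), dict(tally),
    )

    null = fit_decoy_null(decoys)
    evidence = collect_peptide_evidence(filtered, null)
    calls = call_proteins(evidence, alpha=alpha)
    retained = [c.accession for c in calls if c.retained]
    logger.info("retained %d/%d proteins (>=1 peptide p<%g)", len(retained), len(calls), alpha)

    quant = build_quant_matrix(
        filtered, retained_accessions=retained, samples=(OOCYTE, CUMULUS)
    )
    quant = anova_differential(quant, alpha=alpha)
    stats = quant.stats
    n_diff = int(stats["differential"].sum())
    n_up = int((stats["direction"] == "higher").sum())
    logger.info("differential: %d (%d higher, %d lower in cumulus)", n_diff, n_up, n_diff - n_up)

    membership = classify_membership(quant)
    summary = membership_counts(membership, (OOCYTE, CUMULUS))
    logger.info("membership: %s", summary)

    ontology = read_obo(input_dir / "ontology.obo")
    annotations = read_gaf(input_dir / "annotations.gaf")
    dangling = annotations.dangling_terms(ontology)
    if dangling:
        logger.warning("GAF references %d terms absent from the ontology: %s",
                       len(dangling), sorted(dangling)[:5])
    annotations = annotations.subset(retained)
    slim = [l.strip() for l in open(input_dir / "slim_terms.txt") if l.strip()]
    bp_annotations = annotations.by_namespace(ontology, "biological_process")
    slim_map, unclassified = map_to_slim(bp_annotations, ontology, slim)
    logger.info("slim mapping: %d proteins mapped, %d unclassified",
                len(slim_map), len(unclassified))

    presence = {}
    for sample in (OOCYTE, CUMULUS):
        group = quant.group_values(sample)
        for rep in group.columns:
            presence[(sample, int(rep))] = set(group.index[group[rep] > 0])
    slim_summary = compare_categories(slim_map, presence, (OOCYTE, CUMULUS),
                                      categories=slim, alpha=alpha)

    gaq, gaq_mean = gaq_score(annotations, ontology, proteins=retained)
    logger.info("mean GAQ over %d retained proteins: %.2f", len(retained), gaq_mean)

    components = {}
    for term, label in (("GO:2000001", "membrane"), ("GO:2000002", "nucleus")):
        if term in ontology:
            components[label] = partition_by_component(annotations, membership, term, ontology)
    logger.info("component partitions: %s", components)

    expr_net = expression_net_effect(quant, slim_map, categories=slim)
    regulation = read_regulation(input_dir / "regulation.tsv")
    oocyte_universe = set(membership.index[membership.isin([f"{OOCYTE}-only", "common"])])
    reg_net = regulation_net_effect(regulation, oocyte_universe)

    gene_sets = read_gmt(input_dir / "gene_sets.gmt")
    collection = GeneSetCollection.from_gmt(gene_sets, universe=set(membership.index))
    focus = set(stats.index[stats["differential"]])
    enrich = (
        score_gene_sets(focus, collection, pathway_alpha=alpha)
        if focus
        else pd.DataFrame()
    )
    logger.info("enrichment: %d/%d sets network-significant",
                int(enrich["network_significant"].sum()) if len(enrich) else 0,
                len(enrich))

    truth_path = input_dir / "ground_truth.tsv"
    truth = GroundTruth.read(truth_path) if truth_path.exists() else None

    result = PipelineResult(
        filtered_targets=filtered,
        reject_tally=dict(tally),
        protein_calls=calls_to_frame(calls),
        quant=quant,
        membership=membership,
        membership_summary=summary,
        slim_map=slim_map,
        unclassified=unclassified,
        slim_summary=slim_summary,
        gaq_per_protein=gaq,
        gaq_mean=gaq_mean,
        component_partitions=components,
        expression_net=expr_net,
        regulation_net=reg_net,
        enrichment=enrich,
        truth=truth,
    )
    if output_dir is not None:
        _write_outputs(result, Path(output_dir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.protein_calls.to_csv(outdir / "protein_calls.csv", index=False)
    quant_out = result.quant.values.copy()
    quant_out.columns = [f"sumxcorr_{s}_rep{r}" for s, r in quant_out.columns]
    quant_out = quant_out.join(result.quant.stats).join(result.membership)
    quant_out.to_csv(outdir / "quant.csv")
    result.slim_summary.to_csv(outdir / "slim_summary.csv", index=False)
    result.gaq_per_protein.to_frame().to_csv(outdir / "gaq.csv")
    result.expression_net.to_csv(outdir / "net_expression.csv", index=False)
    result.regulation_net.to_csv(outdir / "net_regulation.csv", index=False)
    result.enrichment.to_csv(outdir / "enrichment.csv", index=False)


def simulate_and_run(
    config: SimulationConfig | None = None,
    workdir: str | Path = "pipeline_run",
    alpha: float = 0.05,
) -> PipelineResult:
    """Write a synthetic bundle and run the full pipeline over it."""
    config = config or SimulationConfig()
    workdir = Path(workdir)
    write_simulation(config, workdir / "inputs")
    return run_all(workdir / "inputs", output_dir=workdir / "results", alpha=alpha)
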