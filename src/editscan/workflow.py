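"""End-to-end pipeline orchestration with deterministic, stable outputs.

``run_pipeline`` drives calling -> merging -> DRE classification ->
selection scan -> context profile -> ADAR association -> expression and
splicing integration over an in-memory :class:`Simulation` or a directory
of simulator-dialect inputs, and writes every result as TSV with a stable
column order so that a fixed seed yields byte-identical runs.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from . import adar as adar_mod
from . import context as context_mod
from . import differential, fst, integrate
from .calling import EditingMatrix, Thresholds, call_sample, merge_samples
from .io import read_annotation, read_fasta, read_site_counts, read_snp_mask
from .simulate import Simulation


class StudyInputs:
    """The full set of inputs one analysis run consumes."""

    def __init__(self, reference, annotation, snp_mask, rna, dna, samples,
                 expression=None, splicing_events=None, repeats=None):
        self.reference = reference
        self.annotation = annotation
        self.snp_mask = snp_mask
        self.rna = rna
        self.dna = dna
        self.samples = samples
        self.expression = expression
        self.splicing_events = splicing_events
        self.repeats = repeats

    @classmethod
    def from_simulation(cls, sim: Simulation) -> "StudyInputs":
        return cls(
            reference=sim.reference,
            annotation=sim.annotation,
            snp_mask=sim.snp_mask,
            rna=sim.rna,
            dna=sim.dna,
            samples=sim.samples[["condition", "pair_id"]].copy(),
            expression=sim.expression,
            splicing_events=sim.splicing_events,
            repeats=sim.repeats,
        )

    @classmethod
    def from_directory(cls, indir: str) -> "StudyInputs":
        samples = pd.read_csv(os.path.join(indir, "samples.tsv"), sep="\t").set_index("sample_id")
        rna, dna = {}, {}
        for sample_id in samples.index:
            rna[sample_id] = read_site_counts(
                os.path.join(indir, f"rna_{sample_id}.tsv"), "RNA", sample_id
            )
            dna[sample_id] = read_site_counts(
                os.path.join(indir, f"dna_{sample_id}.tsv"), "DNA", sample_id
            )
        expr_path = os.path.join(indir, "expression.tsv")
        expression = (
            pd.read_csv(expr_path, sep="\t").set_index("gene_id") if os.path.exists(expr_path) else None
        )
        splice_path = os.path.join(indir, "splicing_events.tsv")
        splicing = integrate.read_splicing_events(splice_path) if os.path.exists(splice_path) else None
        repeats_path = os.path.join(indir, "repeats.bed")
        repeats = (
            pd.read_csv(repeats_path, sep="\t", header=None, names=["chrom", "start", "end"])
            if os.path.exists(repeats_path)
            else None
        )
        return cls(
            reference=read_fasta(os.path.join(indir, "reference.fa")),
            annotation=read_annotation(os.path.join(indir, "annotation.gff3")),
            snp_mask=read_snp_mask(os.path.join(indir, "snps.vcf")),
            rna=rna,
            dna=dna,
            samples=samples[["condition", "pair_id"]],
            expression=expression,
            splicing_events=splicing,
            repeats=repeats,
        )


def build_matrix(inputs: StudyInputs, thresholds: Thresholds | None = None) -> EditingMatrix:
    """Call every sample and merge passing sites into an editing matrix."""
    per_sample = {
        sample_id: call_sample(
            inputs.rna[sample_id],
            inputs.dna[sample_id],
            inputs.snp_mask,
            inputs.annotation,
            thresholds,
        )
        for sample_id in inputs.samples.index
    }
    return merge_samples(per_sample, inputs.samples)


def run_pipeline(
    inputs: StudyInputs | Simulation,
    outdir: str | None = None,
    thresholds: Thresholds | None = None,
    min_shared_cov: int = 10,
    min_specific_cov: int = 4,
    fst_threshold: float = 0.25,
    context_k: int = 5,
    seed: int = 0,
) -> dict:
    """Run the full analysis; write stable TSV outputs when ``outdir`` is set."""
    if isinstance(inputs, Simulation):
        inputs = StudyInputs.from_simulation(inputs)
    matrix = build_matrix(inputs, thresholds)
    dre = differential.build_dre_table(matrix, min_shared_cov, min_specific_cov)
    scan = fst.selection_scan(dre, matrix, threshold=fst_threshold)
    dre = scan["table"]
    summaries = differential.summarize_dre(matrix, dre)
    heatmap = differential.dre_heatmap_matrix(matrix, dre)

    a2g = matrix.sites[matrix.sites["edit_type"] == "A>G"]
    profile = context_mod.context_profile(
        a2g.assign(pos=a2g["pos"]), inputs.reference, inputs.annotation, k=context_k, seed=seed
    ) if len(a2g) else None
    regions = context_mod.region_distribution(matrix.sites)
    chroms = context_mod.chromosome_distribution(matrix.sites, inputs.reference)
    repeats = context_mod.repeat_overlap(matrix.sites, inputs.repeats)

    results = {
        "matrix": matrix,
        "dre_table": dre,
        "summaries": summaries,
        "heatmap": heatmap,
        "context_profile": profile,
        "region_distribution": regions,
        "chromosome_distribution": chroms,
        "repeat_overlap": repeats,
        "selection_summaries": scan["summaries"],
    }

    if inputs.expression is not None:
        expr = adar_mod.ExpressionMatrix(inputs.expression[list(inputs.samples.index)], inputs.samples)
        results["adar_global"] = adar_mod.global_adar_correlation(expr, matrix)
        results["adar_ttests"] = adar_mod.adar_paired_ttests(expr)
        results["adar_strata"] = adar_mod.stratify_by_adar1(expr, matrix)
        deg = integrate.paired_log2fc_deg(expr)
        results["deg_table"] = deg
        results["edre"] = integrate.intersect_expression(dre, deg)
    if inputs.splicing_events is not None:
        results["sdre"] = integrate.intersect_splicing(dre, inputs.splicing_events, matrix)

    if outdir is not None:
        _write_outputs(results, matrix, outdir)
    return results


def _write_outputs(results: dict, matrix: EditingMatrix, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)

    def _tsv(df: pd.DataFrame, name: str, index: bool = True) -> None:
        df.to_csv(os.path.join(outdir, name), sep="\t", index=index, float_format="%.6g")

    level = matrix.level.copy()
    level.insert(0, "chrom", matrix.sites["chrom"])
    level.insert(1, "pos", matrix.sites["pos"])
    _tsv(level, "editing_matrix_level.tsv")
    _tsv(matrix.depth, "editing_matrix_depth.tsv")
    _tsv(results["dre_table"].drop(columns=["known"]), "dre_table.tsv")
    _tsv(results["heatmap"], "dre_heatmap.tsv")
    _tsv(results["summaries"]["per_sample"], "dre_per_sample.tsv")
    _tsv(results["summaries"]["per_gene"], "dre_per_gene.tsv")
    _tsv(results["region_distribution"], "region_distribution.tsv")
    _tsv(results["chromosome_distribution"], "chromosome_distribution.tsv")
    if results["context_profile"] is not None:
        _tsv(results["context_profile"].to_frame(), "context_profile.tsv", index=False)
    if results["repeat_overlap"] is not None:
        _tsv(results["repeat_overlap"], "repeat_overlap.tsv")
    for name, df in results["selection_summaries"].items():
        if isinstance(df, pd.DataFrame):
            _tsv(df, f"selection_{name}.tsv")
    if "deg_table" in results:
        _tsv(results["deg_table"], "deg_table.tsv")
        _tsv(results["adar_global"], "adar_global_correlation.tsv")
        _tsv(results["adar_ttests"], "adar_paired_ttests.tsv")
        _tsv(results["edre"]["edre"], "edre.tsv")
        _tsv(results["edre"]["by_group"], "edre_by_group.tsv")
    if "sdre" in results:
        _tsv(results["sdre"]["sdre"], "sdre.tsv", index=False)
        _tsv(results["sdre"]["by_type"], "sdre_by_type.tsv")
        with open(os.path.join(outdir, "sdre_fraction.txt"), "w") as fh:
            fh.write(f"{results['sdre']['fraction_events_with_dre']:.6g}\n")
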