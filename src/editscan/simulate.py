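"""Synthetic paired tumor/normal RNA+DNA site-count data with planted truth.

The generator emulates the data regime of a paired tumor/normal A-to-I
editing study driven by per-site base-count tables:

* a small reference genome with gene models (exon/intron/UTR structure),
  uniform base composition except at planted motif sites;
* planted A-to-I editing sites in three groups (shared, tumor-specific,
  normal-specific) with Beta-distributed editing levels, drawn
  hierarchically (a site-level mean, then per-sample levels around it) so
  that pooled-count tests see realistic overdispersion;
* a per-sample ADAR1 activity multiplier coupled to the global editing
  level through a configurable slope;
* confounders that the filter cascade must remove: germline SNPs (variant
  in the DNA of every sample), somatic-style DNA variants, sequencing
  error at every position, and a handful of low-quality positions;
* sites with divergent tumor/normal editing frequencies planted for the
  F_ST selection scan, an expression matrix with planted differentially
  expressed genes, rMATS-style splicing events constructed to contain a
  known fraction of planted sites, and Alu-like repeat intervals.

Every draw comes from a single seeded generator chain, so identical
configurations produce byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (
    REGION_EXONIC,
    REGION_INTERGENIC,
    REGION_INTRONIC,
    REGION_UTR3,
    REGION_UTR5,
    AnnotationIndex,
    Gene,
    SiteCountsTable,
    Transcript,
    write_fasta,
    write_gff3,
    write_site_counts,
    write_snv_vcf,
)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
GROUPS = ("shared", "tumor_specific", "normal_specific")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.  Defaults are the desk-scale
    regime used throughout the test suite: 10 tumor/normal pairs, negative
    binomial depth with mean 50 and dispersion 0.3 (var = mu + 0.3 mu^2),
    per-base error 0.001, site-level editing means Beta(2, 8) (mean 0.2,
    matching levels mostly in the 10-30% range), and a per-sample level
    concentration of 1/sample_dispersion around the site mean."""

    n_pairs: int = 10
    seed: int = 0
    # genome layout
    n_chroms: int = 2
    chrom_length: int = 150_000
    n_genes: int = 40
    n_site_free_genes: int = 6
    exon_count_range: tuple[int, int] = (3, 8)
    exon_length_range: tuple[int, int] = (120, 250)
    intron_length_range: tuple[int, int] = (300, 900)
    intergenic_gap_range: tuple[int, int] = (500, 3000)
    # planted sites
    n_shared: int = 300
    n_tumor_specific: int = 150
    n_normal_specific: int = 150
    n_shared_diff: int = 60
    shared_effect: float = 0.15
    diff_base_range: tuple[float, float] = (0.2, 0.4)
    n_fst: int = 30
    fst_levels: tuple[float, float] = (0.2, 0.8)  # (normal, tumor)
    level_alpha: float = 2.0
    level_beta: float = 8.0
    sample_dispersion: float = 0.01  # per-sample Beta concentration = 1/dispersion; 0 => none
    motif_bias: float = 0.8
    min_site_separation: int = 12
    edge_margin: int = 30
    region_weights: tuple[tuple[str, float], ...] = (
        (REGION_INTRONIC, 0.78),
        (REGION_UTR3, 0.06),
        (REGION_EXONIC, 0.05),
        (REGION_UTR5, 0.04),
        (REGION_INTERGENIC, 0.07),
    )
    # confounders
    n_snps: int = 30
    n_dna_variants: int = 30
    n_background: int = 2000
    n_low_quality: int = 20
    # depth and error
    rna_depth_mean: float = 50.0
    dna_depth_mean: float = 50.0
    depth_dispersion: float = 0.3
    error_rate: float = 0.001
    mean_quality: float = 36.0
    quality_sd: float = 1.0
    # ADAR and expression
    adar_coupling: float = 0.5
    adar_expr_sd: float = 0.25
    adar_tumor_shift: float = 1.4
    expr_noise_sd: float = 0.2
    n_de_genes: int = 20
    n_de_genes_site_free: int = 4
    de_log2fc: float = 1.5
    # splicing and repeats
    n_splice_events: int = 200
    splice_overlap_frac: float = 0.4
    repeat_site_frac: float = 0.6

    def validate(self) -> None:
        probs = {
            "motif_bias": self.motif_bias,
            "error_rate": self.error_rate,
            "splice_overlap_frac": self.splice_overlap_frac,
            "repeat_site_frac": self.repeat_site_frac,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.level_alpha <= 0 or self.level_beta <= 0:
            raise ConfigError("Beta parameters must be positive")
        for name in (
            "n_pairs", "n_shared", "n_tumor_specific", "n_normal_specific",
            "n_snps", "n_dna_variants", "n_background", "n_genes",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_shared_diff + self.n_fst > self.n_shared:
            raise ConfigError("n_shared_diff + n_fst cannot exceed n_shared")
        if self.sample_dispersion < 0:
            raise ConfigError("sample_dispersion must be >= 0")
        if not 0 <= self.n_de_genes_site_free <= self.n_site_free_genes:
            raise ConfigError("n_de_genes_site_free must not exceed n_site_free_genes")


@dataclass
class Simulation:
    """In-memory bundle of everything one simulated study produces."""

    cfg: SimConfig
    reference: dict[str, str]
    annotation: AnnotationIndex
    sites: pd.DataFrame  # planted truth per site
    samples: pd.DataFrame  # per-sample truth (index sample_id)
    snps: pd.DataFrame
    dna_variants: pd.DataFrame
    rna: dict[str, SiteCountsTable]
    dna: dict[str, SiteCountsTable]
    expression: pd.DataFrame  # genes x samples
    de_truth: pd.DataFrame
    splicing_events: pd.DataFrame
    repeats: pd.DataFrame  # chrom, start, end (0-based half-open)

    @property
    def snp_mask(self):
        from .io import SnpMask

        return SnpMask({(r.chrom, int(r.pos)) for r in self.snps.itertuples(index=False)})

    def write_all(self, outdir: str | os.PathLike) -> None:
        """Write the complete study to a directory in the dialects io reads."""
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        write_fasta(self.reference, os.path.join(outdir, "reference.fa"))
        write_gff3(self.annotation, os.path.join(outdir, "annotation.gff3"))
        write_snv_vcf(self.snps, os.path.join(outdir, "snps.vcf"), source="editscan-sim-snps")
        for sample_id in self.samples.index:
            write_site_counts(self.rna[sample_id], os.path.join(outdir, f"rna_{sample_id}.tsv"))
            write_site_counts(self.dna[sample_id], os.path.join(outdir, f"dna_{sample_id}.tsv"))
        self.samples.reset_index().to_csv(os.path.join(outdir, "samples.tsv"), sep="\t", index=False)
        expr = self.expression.copy()
        expr.insert(0, "gene_id", expr.index)
        expr.to_csv(os.path.join(outdir, "expression.tsv"), sep="\t", index=False)
        self.splicing_events.to_csv(os.path.join(outdir, "splicing_events.tsv"), sep="\t", index=False)
        self.repeats.to_csv(os.path.join(outdir, "repeats.bed"), sep="\t", index=False, header=False)
        write_truth(self, outdir)


def write_truth(sim: Simulation, outdir: str | os.PathLike) -> None:
    """Write the planted truth set (TSV for sites/samples, VCF for variants)."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    sim.sites.to_csv(os.path.join(outdir, "truth_sites.tsv"), sep="\t", index=False)
    sim.samples.reset_index().to_csv(os.path.join(outdir, "truth_samples.tsv"), sep="\t", index=False)
    write_snv_vcf(sim.snps, os.path.join(outdir, "truth_snps.vcf"), source="editscan-sim-snps")
    write_snv_vcf(
        sim.dna_variants, os.path.join(outdir, "truth_dna_variants.vcf"), source="editscan-sim-dna-variants"
    )
    sim.de_truth.to_csv(os.path.join(outdir, "truth_de_genes.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference and annotation
# ---------------------------------------------------------------------------


def simulate_reference(cfg: SimConfig):
    """Build the synthetic reference (dict of chrom -> sequence string) and
    gene models.  Deterministic given ``cfg`` (including the seed).  Raises
    :class:`ConfigError` when the requested gene layout cannot fit the
    genome length.
    """
    sequences, annotation = _reference_arrays(cfg)
    return {name: "".join(arr) for name, arr in sequences.items()}, annotation


def _reference_arrays(cfg: SimConfig, rng: np.random.Generator | None = None):
    """As :func:`simulate_reference` but with mutable per-base arrays, so the
    full simulation can imprint site and motif bases before freezing."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 0])
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    sequences = {
        name: rng.choice(np.array(list("ACGT")), size=cfg.chrom_length) for name in chrom_names
    }
    genes: list[Gene] = []
    cursors = {name: 0 for name in chrom_names}
    for gi in range(cfg.n_genes):
        chrom = chrom_names[gi % cfg.n_chroms]
        gap = int(rng.integers(*cfg.intergenic_gap_range))
        n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        exon_lens = rng.integers(*cfg.exon_length_range, size=n_exons)
        intron_lens = rng.integers(*cfg.intron_length_range, size=max(n_exons - 1, 0))
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursors[chrom] + gap
        exons = []
        pos = start
        for i in range(n_exons):
            exons.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        end = pos
        if end > cfg.chrom_length - cfg.edge_margin:
            raise ConfigError(
                f"gene layout infeasible: gene {gi + 1} of {cfg.n_genes} runs past "
                f"{cfg.chrom_length} bp on {chrom}; increase chrom_length or reduce n_genes"
            )
        gene_id = f"G{gi + 1:03d}"
        cds = (exons[0][0] + int(exon_lens[0]) // 2, exons[-1][1] - int(exon_lens[-1]) // 2)
        gene = Gene(gene_id, chrom, strand, start, end)
        gene.transcripts.append(Transcript(f"{gene_id}.t1", exons, cds))
        genes.append(gene)
        cursors[chrom] = end
    annotation = AnnotationIndex(genes)
    return sequences, annotation


def _segment_pools(cfg: SimConfig, annotation: AnnotationIndex):
    """Per region class, the (chrom, start, end, gene_id, strand) segments sites
    can be planted in.  Site-free reserve genes are excluded so the study keeps
    genes without any editing site."""
    from .io import _region_segments

    gene_ids = sorted(annotation.genes)
    reserve = set(gene_ids[-cfg.n_site_free_genes:]) if cfg.n_site_free_genes else set()
    pools: dict[str, list[tuple[str, int, int, str, str]]] = {
        REGION_EXONIC: [], REGION_INTRONIC: [], REGION_UTR5: [], REGION_UTR3: [], REGION_INTERGENIC: []
    }
    for gene_id in gene_ids:
        if gene_id in reserve:
            continue
        gene = annotation.genes[gene_id]
        for s, e, region in _region_segments(gene):
            pools[region].append((gene.chrom, s, e, gene_id, gene.strand))
        exons = sorted(x for tx in gene.transcripts for x in tx.exons)
        prev = gene.start
        for (es, ee) in exons:
            if es > prev:
                pools[REGION_INTRONIC].append((gene.chrom, prev, es, gene_id, gene.strand))
            prev = max(prev, ee)
    spans = annotation.gene_spans()
    for chrom in sorted({g.chrom for g in annotation.genes.values()} or set()):
        sub = spans[spans.chrom == chrom].sort_values("start")
        prev = cfg.edge_margin
        for row in sub.itertuples(index=False):
            if row.start > prev:
                pools[REGION_INTERGENIC].append((chrom, prev, row.start, "", "unknown"))
            prev = max(prev, row.end)
        chrom_len = len_of(cfg, chrom)
        if chrom_len - cfg.edge_margin > prev:
            pools[REGION_INTERGENIC].append((chrom, prev, chrom_len - cfg.edge_margin, "", "unknown"))
    if not annotation.genes:
        for i in range(cfg.n_chroms):
            chrom = f"chr{i + 1}"
            pools[REGION_INTERGENIC].append(
                (chrom, cfg.edge_margin, cfg.chrom_length - cfg.edge_margin, "", "unknown")
            )
    return pools


def len_of(cfg: SimConfig, chrom: str) -> int:
    return cfg.chrom_length


def _draw_positions(rng, pools, classes, n, taken: set, blocked: np.ndarray | None, min_sep: int):
    """Draw n distinct positions, one region class each, keeping min_sep to
    ``blocked`` positions (and to each other when min_sep > 0)."""
    chosen = []
    placed = list(blocked) if blocked is not None else []
    class_names = [c for c, _w in classes]
    weights = np.array([w for _c, w in classes], dtype=float)
    weights = weights / weights.sum()
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 200 * max(n, 1) + 1000:
            raise ConfigError("could not place planted positions; genome too small for the request")
        region = rng.choice(class_names, p=weights)
        segs = pools[region]
        if not segs:
            continue
        lens = np.array([e - s for (_c, s, e, _g, _s) in segs], dtype=float)
        seg = segs[int(rng.choice(len(segs), p=lens / lens.sum()))]
        chrom, s, e, gene_id, strand = seg
        pos = int(rng.integers(s, e))
        key = (chrom, pos)
        if key in taken:
            continue
        if min_sep:
            near = [p for (c, p) in placed if c == chrom and abs(p - pos) < min_sep]
            if near:
                continue
        taken.add(key)
        placed.append(key)
        chosen.append((chrom, pos, gene_id, strand, region))
    return chosen


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------


def simulate(cfg: SimConfig | None = None, **overrides) -> Simulation:
    """Run the complete simulation for ``cfg`` (or SimConfig(**overrides))."""
    if cfg is None:
        cfg = SimConfig(**overrides)
    elif overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    sequences, annotation = _reference_arrays(cfg)
    rng = np.random.default_rng([cfg.seed, 1])
    pools = _segment_pools(cfg, annotation)

    taken: set[tuple[str, int]] = set()
    n_sites = cfg.n_shared + cfg.n_tumor_specific + cfg.n_normal_specific
    site_rows = _draw_positions(
        rng, pools, list(cfg.region_weights), n_sites, taken, None, cfg.min_site_separation
    )
    all_weights = [(r, w) for r, w in cfg.region_weights]
    snp_rows = _draw_positions(rng, pools, all_weights, cfg.n_snps, taken, None, 0)
    var_rows = _draw_positions(rng, pools, all_weights, cfg.n_dna_variants, taken, None, 0)
    bg_rows = _draw_positions(rng, pools, all_weights, cfg.n_background, taken, None, 0)

    sites = pd.DataFrame(site_rows, columns=["chrom", "pos0", "gene_id", "strand", "region"])
    groups = (
        ["shared"] * cfg.n_shared
        + ["tumor_specific"] * cfg.n_tumor_specific
        + ["normal_specific"] * cfg.n_normal_specific
    )
    sites["group"] = groups
    sites["fst_planted"] = False
    sites["diff_planted"] = False
    sites.loc[: cfg.n_fst - 1, "fst_planted"] = True
    sites.loc[cfg.n_fst : cfg.n_fst + cfg.n_shared_diff - 1, "diff_planted"] = True

    # true per-condition editing means
    base = rng.beta(cfg.level_alpha, cfg.level_beta, size=n_sites)
    lvl_n = base.copy()
    lvl_t = base.copy()
    fst_idx = sites.index[sites.fst_planted].to_numpy()
    lvl_n[fst_idx] = cfg.fst_levels[0]
    lvl_t[fst_idx] = cfg.fst_levels[1]
    diff_idx = sites.index[sites.diff_planted].to_numpy()
    diff_base = rng.uniform(*cfg.diff_base_range, size=len(diff_idx))
    lvl_n[diff_idx] = diff_base
    lvl_t[diff_idx] = np.clip(diff_base + cfg.shared_effect, 0, 0.9)
    is_ts = (sites.group == "tumor_specific").to_numpy()
    is_ns = (sites.group == "normal_specific").to_numpy()
    lvl_n[is_ts] = 0.0
    lvl_t[is_ns] = 0.0
    sites["level_normal"] = lvl_n
    sites["level_tumor"] = lvl_t
    sites["motif"] = rng.random(n_sites) < cfg.motif_bias

    # imprint center/motif bases onto the reference (on the edited strand)
    for row in sites.itertuples():
        seq = sequences[row.chrom]
        minus = row.strand == "-"
        seq[row.pos0] = "T" if minus else "A"
        if row.motif:
            up = rng.choice(np.array(["A", "C", "T"]))  # G depleted at -1 on the edited strand
            if minus:
                seq[row.pos0 + 1] = COMPLEMENT[up]
                seq[row.pos0 - 1] = "C"  # complement of downstream G
            else:
                seq[row.pos0 - 1] = up
                seq[row.pos0 + 1] = "G"
    reference = {name: "".join(arr) for name, arr in sequences.items()}

    ref_base = np.array([reference[c][p] for c, p in zip(sites.chrom, sites.pos0)])
    sites["ref"] = ref_base
    sites["alt"] = np.where(ref_base == "A", "G", "C")  # raw plus-strand alt (T>C on minus genes)
    sites["pos"] = sites["pos0"] + 1

    def _variant_frame(rows):
        df = pd.DataFrame(rows, columns=["chrom", "pos0", "gene_id", "strand", "region"])
        df["pos"] = df["pos0"] + 1
        df["ref"] = [reference[c][p] for c, p in zip(df.chrom, df.pos0)]
        alts = []
        for r in df.ref:
            options = [b for b in "ACGT" if b != r]
            alts.append(options[int(rng.integers(3))])
        df["alt"] = alts if len(df) else pd.Series(dtype=str)
        return df

    snps = _variant_frame(snp_rows)
    dna_variants = _variant_frame(var_rows)
    background = pd.DataFrame(bg_rows, columns=["chrom", "pos0", "gene_id", "strand", "region"])
    background["pos"] = background["pos0"] + 1
    background["ref"] = [reference[c][p] for c, p in zip(background.chrom, background.pos0)]

    # samples and ADAR multipliers
    n_samples = 2 * cfg.n_pairs
    pair_ids = [f"P{i + 1:02d}" for i in range(cfg.n_pairs)]
    sample_ids = [f"T{i + 1:02d}" for i in range(cfg.n_pairs)] + [f"N{i + 1:02d}" for i in range(cfg.n_pairs)]
    conditions = ["tumor"] * cfg.n_pairs + ["normal"] * cfg.n_pairs
    adar1 = np.exp(rng.normal(0.0, cfg.adar_expr_sd, size=n_samples))
    adar1[: cfg.n_pairs] *= cfg.adar_tumor_shift
    editing_mult = adar1 ** cfg.adar_coupling
    samples = pd.DataFrame(
        {
            "condition": conditions,
            "pair_id": pair_ids + pair_ids,
            "adar1_multiplier": adar1,
            "editing_multiplier": editing_mult,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # true per-sample editing fractions phi (sites x samples)
    mu = np.where(
        np.array(conditions) == "tumor", lvl_t[:, None], lvl_n[:, None]
    )
    if cfg.sample_dispersion > 0:
        kappa = 1.0 / cfg.sample_dispersion
        mu_c = np.clip(mu, 1e-9, 1 - 1e-9)
        phi = rng.beta(mu_c * kappa, (1 - mu_c) * kappa)
        phi[mu == 0] = 0.0
    else:
        phi = mu.copy()
    phi = np.clip(phi * editing_mult[None, :], 0.0, 0.99)

    # assemble all simulated positions
    positions = pd.concat(
        [
            sites[["chrom", "pos0", "pos", "ref", "alt"]].assign(kind="edit"),
            snps[["chrom", "pos0", "pos", "ref", "alt"]].assign(kind="snp"),
            dna_variants[["chrom", "pos0", "pos", "ref", "alt"]].assign(kind="dna_variant"),
            background[["chrom", "pos0", "pos", "ref"]].assign(alt="", kind="background"),
        ],
        ignore_index=True,
    )
    n_pos = len(positions)
    edit_rows = np.arange(len(sites))
    kind = positions["kind"].to_numpy()

    rna_alt_p = np.zeros((n_pos, n_samples))
    rna_alt_p[: len(sites)] = phi
    rna_alt_p[kind == "snp"] = 0.5
    rna_alt_p[kind == "dna_variant"] = 0.5
    dna_alt_p = np.zeros((n_pos, n_samples))
    dna_alt_p[kind == "snp"] = 0.5
    dna_alt_p[kind == "dna_variant"] = 0.5

    low_quality_idx = (
        rng.choice(np.flatnonzero(kind == "background"), size=cfg.n_low_quality, replace=False)
        if cfg.n_low_quality and (kind == "background").sum() >= cfg.n_low_quality
        else np.array([], dtype=int)
    )

    def _counts(depth_mean: float, alt_p: np.ndarray):
        r = 1.0 / cfg.depth_dispersion
        p = r / (r + depth_mean)
        depth = rng.negative_binomial(r, p, size=(n_pos, n_samples))
        alt = rng.binomial(depth, alt_p)
        n_err = rng.binomial(depth - alt, cfg.error_rate)
        err_split = rng.multinomial(n_err.ravel(), [1 / 3] * 3).reshape(n_pos, n_samples, 3)
        qual = np.clip(rng.normal(cfg.mean_quality, cfg.quality_sd, size=(n_pos, n_samples)), 0, 60)
        if len(low_quality_idx):
            qual[low_quality_idx] = 25.0
        return depth, alt, err_split, qual

    rna_depth, rna_alt, rna_err, rna_qual = _counts(cfg.rna_depth_mean, rna_alt_p)
    dna_depth, dna_alt, dna_err, dna_qual = _counts(cfg.dna_depth_mean, dna_alt_p)

    base_index = {b: i for i, b in enumerate("ACGT")}
    ref_idx = positions["ref"].map(base_index).to_numpy()
    alt_idx = positions["alt"].map(lambda b: base_index.get(b, -1)).to_numpy()
    err_targets = np.array([[j for j in range(4) if j != r] for r in ref_idx])  # (n_pos, 3)

    def _assemble(depth, alt, err_split):
        counts = np.zeros((n_pos, n_samples, 4), dtype=int)
        err_total = err_split.sum(axis=2)
        np.put_along_axis(
            counts, ref_idx[:, None, None], (depth - alt - err_total)[:, :, None], axis=2
        )
        has_alt = alt_idx >= 0
        safe_alt = np.where(has_alt, alt_idx, 0)
        cur = np.take_along_axis(counts, safe_alt[:, None, None], axis=2)
        np.put_along_axis(
            counts, safe_alt[:, None, None], cur + np.where(has_alt[:, None], alt, 0)[:, :, None], axis=2
        )
        for t in range(3):
            tgt = err_targets[:, t]
            cur = np.take_along_axis(counts, tgt[:, None, None], axis=2)
            np.put_along_axis(counts, tgt[:, None, None], cur + err_split[:, :, t][:, :, None], axis=2)
        return counts

    rna_counts = _assemble(rna_depth, rna_alt, rna_err)
    dna_counts = _assemble(dna_depth, dna_alt, dna_err)

    order = np.lexsort((positions["pos"].to_numpy(), positions["chrom"].to_numpy()))
    rna_tables: dict[str, SiteCountsTable] = {}
    dna_tables: dict[str, SiteCountsTable] = {}
    for j, sample_id in enumerate(sample_ids):
        for assay, counts, depth, qual, store in (
            ("RNA", rna_counts, rna_depth, rna_qual, rna_tables),
            ("DNA", dna_counts, dna_depth, dna_qual, dna_tables),
        ):
            keep = order[depth[order, j] > 0]
            df = pd.DataFrame(
                {
                    "chrom": positions["chrom"].to_numpy()[keep],
                    "pos": positions["pos"].to_numpy()[keep],
                    "ref": positions["ref"].to_numpy()[keep],
                    "strand": "unknown",
                    "depth": depth[keep, j],
                    "mean_quality": np.round(qual[keep, j], 2),
                    "n_a": counts[keep, j, 0],
                    "n_c": counts[keep, j, 1],
                    "n_g": counts[keep, j, 2],
                    "n_t": counts[keep, j, 3],
                }
            )
            store[sample_id] = SiteCountsTable(sample_id, assay, df)

    expression, de_truth = _simulate_expression(cfg, rng, annotation, sites, samples)
    splicing = _simulate_splicing(cfg, rng, annotation, sites)
    repeats, in_repeat = _simulate_repeats(cfg, rng, sites)
    sites["in_repeat"] = in_repeat

    site_cols = [
        "chrom", "pos", "ref", "alt", "strand", "gene_id", "region", "group",
        "level_normal", "level_tumor", "motif", "fst_planted", "diff_planted", "in_repeat",
    ]
    return Simulation(
        cfg=cfg,
        reference=reference,
        annotation=annotation,
        sites=sites[site_cols].copy(),
        samples=samples,
        snps=snps[["chrom", "pos", "ref", "alt"]].copy(),
        dna_variants=dna_variants[["chrom", "pos", "ref", "alt"]].copy(),
        rna=rna_tables,
        dna=dna_tables,
        expression=expression,
        de_truth=de_truth,
        splicing_events=splicing,
        repeats=repeats,
    )


def _simulate_expression(cfg, rng, annotation, sites, samples):
    gene_ids = sorted(annotation.genes)
    if not gene_ids:
        return pd.DataFrame(index=pd.Index([], name="gene_id")), pd.DataFrame(
            columns=["gene_id", "log2fc"]
        )
    genes_with_sites = sorted(set(sites.gene_id) - {""})
    site_free = [g for g in gene_ids if g not in set(genes_with_sites)]
    n_de1 = min(cfg.n_de_genes, len(genes_with_sites))
    n_de2 = min(cfg.n_de_genes_site_free, len(site_free))
    de_genes = list(rng.choice(genes_with_sites, size=n_de1, replace=False)) if n_de1 else []
    de_genes += list(rng.choice(site_free, size=n_de2, replace=False)) if n_de2 else []
    lfc = {g: cfg.de_log2fc * (1 if i % 2 == 0 else -1) for i, g in enumerate(de_genes)}

    base = np.exp(rng.normal(np.log(200), 1.0, size=len(gene_ids)))
    is_tumor = (samples.condition == "tumor").to_numpy()
    noise = np.exp(rng.normal(0, cfg.expr_noise_sd, size=(len(gene_ids), len(samples))))
    values = base[:, None] * noise
    for i, g in enumerate(gene_ids):
        if g in lfc:
            values[i, is_tumor] *= 2.0 ** lfc[g]
    expr = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples.index)
    # deaminase genes: ADAR (ADAR1) follows the per-sample activity multiplier
    adar = pd.DataFrame(
        {
            s: [
                500.0 * samples.loc[s, "adar1_multiplier"],
                100.0 * float(np.exp(rng.normal(0, cfg.adar_expr_sd))),
                20.0 * float(np.exp(rng.normal(0, cfg.adar_expr_sd))),
            ]
            for s in samples.index
        },
        index=pd.Index(["ADAR", "ADARB1", "ADARB2"], name="gene_id"),
    )
    expr = pd.concat([adar, expr])
    de_truth = pd.DataFrame(
        {"gene_id": de_genes, "log2fc": [lfc[g] for g in de_genes]}
    ).sort_values("gene_id").reset_index(drop=True)
    return np.round(expr, 4), de_truth


_EVENT_TYPES = np.array(["SE", "A5SS", "A3SS", "MXE", "RI"])


def _simulate_splicing(cfg, rng, annotation, sites):
    """rMATS-style significant events; a ``splice_overlap_frac`` fraction is
    constructed to contain at least one planted site (preferring
    condition-specific sites, whose downstream classification is robust)."""
    n_events = cfg.n_splice_events
    n_pos = int(round(cfg.splice_overlap_frac * n_events))
    specific = sites[sites.group != "shared"]
    pool = specific if len(specific) >= n_pos else sites
    rows = []
    if n_pos:
        chosen = pool.iloc[rng.choice(len(pool), size=min(n_pos, len(pool)), replace=False)]
        for row in chosen.itertuples():
            half = int(rng.integers(300, 500))
            span = (max(row.pos - 1 - half, 0), row.pos - 1 + half)
            rows.append((row.chrom, span, row.gene_id or "NA", True))
    site_pos = {c: sites.loc[sites.chrom == c, "pos"].to_numpy() - 1 for c in sites.chrom.unique()}
    attempts = 0
    while len(rows) < n_events:
        attempts += 1
        if attempts > 100 * n_events + 1000:
            break
        chrom = f"chr{int(rng.integers(cfg.n_chroms)) + 1}"
        half = int(rng.integers(300, 500))
        mid = int(rng.integers(cfg.edge_margin + half, cfg.chrom_length - cfg.edge_margin - half))
        near = site_pos.get(chrom, np.array([]))
        if len(near) and np.min(np.abs(near - mid)) <= half + 5:
            continue
        gene_id, _s, _r = annotation.classify(chrom, mid + 1)
        rows.append((chrom, (mid - half, mid + half), gene_id or "NA", False))
    event_types = rng.choice(_EVENT_TYPES, size=len(rows), p=[0.5, 0.125, 0.125, 0.125, 0.125])
    out = []
    for i, ((chrom, (s, e), gene_id, contains), etype) in enumerate(zip(rows, event_types)):
        exon_third = (e - s) // 3
        if etype == "RI":
            exon_start, exon_end = s, e
            up_es = up_ee = down_es = down_ee = -1
        else:
            exon_start, exon_end = s + exon_third, e - exon_third
            up_es, up_ee = s, s + exon_third // 2
            down_es, down_ee = e - exon_third // 2, e
        out.append(
            {
                "event_id": f"EV{i + 1:04d}",
                "gene_id": gene_id,
                "chrom": chrom,
                "strand": "+",
                "event_type": etype,
                "exon_start": exon_start,
                "exon_end": exon_end,
                "upstream_es": up_es,
                "upstream_ee": up_ee,
                "downstream_es": down_es,
                "downstream_ee": down_ee,
                "inc_level_difference": float(np.round(rng.uniform(0.1, 0.5) * (1 if rng.random() < 0.5 else -1), 4)),
                "pvalue": float(np.format_float_scientific(rng.uniform(1e-6, 0.04), precision=4)),
                "contains_planted_site": contains,
            }
        )
    return pd.DataFrame(out)


def _simulate_repeats(cfg, rng, sites):
    """Alu-like repeat intervals covering a configured fraction of planted sites."""
    n_cov = int(round(cfg.repeat_site_frac * len(sites)))
    covered = set(rng.choice(len(sites), size=n_cov, replace=False)) if n_cov else set()
    intervals = []
    for i in sorted(covered):
        row = sites.iloc[i]
        intervals.append((row.chrom, max(int(row.pos) - 151, 0), int(row.pos) + 150))
    for _ in range(20):
        chrom = f"chr{int(rng.integers(cfg.n_chroms)) + 1}"
        start = int(rng.integers(0, cfg.chrom_length - 300))
        intervals.append((chrom, start, start + 300))
    merged = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(end, merged[-1][2]))
        else:
            merged.append((chrom, start, end))
    repeats = pd.DataFrame(merged, columns=["chrom", "start", "end"])
    in_repeat = np.zeros(len(sites), dtype=bool)
    for i, row in enumerate(sites.itertuples()):
        sub = repeats[(repeats.chrom == row.chrom)]
        in_repeat[i] = bool(((sub.start <= row.pos - 1) & (row.pos - 1 < sub.end)).any())
    return repeats, in_repeat
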