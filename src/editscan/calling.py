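"""Per-sample RNA-DNA-difference calling and the high-confidence filter cascade.

A candidate is any position where the RNA shows at least one non-reference
read while the matched DNA is consistent with homozygous reference.  The
cascade then applies, in a fixed order, the stringent requirements of the
study design: mean base quality > 30, per-sample read depth >= 10, a single
RNA variant allele, no DNA-variant evidence, not a known SNP position, and
an editing level in [0.1, 1).  Each rejected candidate carries exactly the
first filter it failed, so flag counts partition the candidate set.

Filtering is per sample ("each site in each sample"): a site may pass in
some samples and be missing in others; :func:`merge_samples` unions the
passing sites into an :class:`EditingMatrix` and counts per-condition
sample coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IntegrityError
from .io import BASES, AnnotationIndex, SiteCountsTable, SnpMask

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

PASSED = "passed"
FLAG_ORDER = (
    "low_quality_removed",
    "low_depth_removed",
    "multi_allelic_removed",
    "dna_variant_removed",
    "snp_removed",
    "level_out_of_range_removed",
)
NO_DNA = "no_dna_evidence"
ALL_STATUSES = (PASSED,) + FLAG_ORDER + (NO_DNA,)


@dataclass(frozen=True)
class Thresholds:
    """Filter cascade thresholds.

    Defaults follow the study design: ``min_base_quality`` 30 (exclusive),
    ``min_depth`` 10 (inclusive), level in [0.1, 1).  The DNA-variant rule
    (alt fraction > 0.01 or alt count >= 2) and the minimum DNA depth are
    robustness choices exposed here because the source protocol leaves them
    open; a second RNA variant allele needs >= 2 reads to count, so single
    sequencing-error reads do not discard a site as multi-allelic.
    """

    min_base_quality: float = 30.0
    min_depth: int = 10
    min_level: float = 0.1
    max_level: float = 1.0  # exclusive
    dna_alt_fraction: float = 0.01
    dna_alt_count: int = 2
    min_dna_depth: int = 5
    min_second_allele_count: int = 2

    def describe(self) -> str:
        return (
            f"quality>{self.min_base_quality}, depth>={self.min_depth}, "
            f"level in [{self.min_level},{self.max_level}), "
            f"dna variant if frac>{self.dna_alt_fraction} or count>={self.dna_alt_count}, "
            f"dna depth>={self.min_dna_depth}, 2nd allele counts from {self.min_second_allele_count} reads"
        )


_COUNT_OF = {b: f"n_{b.lower()}" for b in BASES}


def call_candidates(
    rna: SiteCountsTable, dna: SiteCountsTable, thresholds: Thresholds | None = None
) -> pd.DataFrame:
    """Join RNA and DNA evidence and return all candidate RDD positions.

    A candidate is a position with >= 1 non-reference RNA read.  Candidates
    whose DNA evidence is absent or below ``min_dna_depth`` are flagged
    ``no_dna_evidence`` (excluded downstream, logged).  The returned frame
    carries both assays' counts plus the chosen variant allele (the
    most-supported non-reference RNA base) and the second-allele count.
    """
    thresholds = thresholds or Thresholds()
    r = rna.df.rename(columns={"depth": "rna_depth", "mean_quality": "rna_quality"})
    d = dna.df[["chrom", "pos", "depth", "n_a", "n_c", "n_g", "n_t"]].rename(
        columns={
            "depth": "dna_depth",
            "n_a": "dna_a",
            "n_c": "dna_c",
            "n_g": "dna_g",
            "n_t": "dna_t",
        }
    )
    m = r.merge(d, on=["chrom", "pos"], how="left")
    rna_counts = m[["n_a", "n_c", "n_g", "n_t"]].to_numpy(dtype=float)
    ref_idx = m["ref"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
    nonref = rna_counts.copy()
    nonref[np.arange(len(m)), ref_idx] = -1
    alt_order = np.argsort(nonref, axis=1, kind="stable")
    alt_idx = alt_order[:, -1]
    second_idx = alt_order[:, -2]
    m["alt"] = np.array(BASES)[alt_idx]
    m["rna_alt_count"] = nonref[np.arange(len(m)), alt_idx].astype(int)
    m["second_allele_count"] = np.where(
        nonref[np.arange(len(m)), second_idx] > 0, nonref[np.arange(len(m)), second_idx], 0
    ).astype(int)
    m["rna_ref_count"] = rna_counts[np.arange(len(m)), ref_idx].astype(int)
    dna_counts = m[["dna_a", "dna_c", "dna_g", "dna_t"]].to_numpy()
    m["dna_alt_count"] = np.where(
        np.isnan(dna_counts[np.arange(len(m)), alt_idx]),
        np.nan,
        dna_counts[np.arange(len(m)), alt_idx],
    )
    m["dna_depth"] = m["dna_depth"].fillna(0).astype(int)

    candidates = m[m["rna_alt_count"] >= 1].copy()
    candidates["level"] = candidates["rna_alt_count"] / (
        candidates["rna_alt_count"] + candidates["rna_ref_count"]
    )
    candidates["status"] = ""
    no_dna = candidates["dna_depth"] < thresholds.min_dna_depth
    candidates.loc[no_dna, "status"] = NO_DNA
    if no_dna.any():
        log.info("%s: %d candidates lack DNA evidence and were excluded", rna.sample_id, int(no_dna.sum()))
    candidates["sample_id"] = rna.sample_id
    cols = [
        "sample_id", "chrom", "pos", "ref", "alt", "rna_depth", "rna_quality",
        "rna_ref_count", "rna_alt_count", "second_allele_count", "level",
        "dna_depth", "dna_alt_count", "status",
    ]
    return candidates[cols].reset_index(drop=True)


def apply_filters(
    candidates: pd.DataFrame,
    snp_mask: SnpMask | None = None,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Apply the filter cascade; each candidate gets its first-failing flag.

    Order of application: quality -> depth -> multi-allelic -> DNA variant ->
    SNP -> level.  Candidates already flagged ``no_dna_evidence`` keep that
    status.  The applied thresholds are logged.
    """
    thresholds = thresholds or Thresholds()
    log.info("filter cascade: %s", thresholds.describe())
    out = candidates.copy()
    status = out["status"].to_numpy(dtype=object).copy()
    undecided = status == ""

    def _flag(mask: np.ndarray, flag: str) -> None:
        nonlocal undecided
        hit = undecided & mask.to_numpy(dtype=bool)
        status[hit] = flag
        undecided = undecided & ~hit

    _flag(out["rna_quality"] <= thresholds.min_base_quality, "low_quality_removed")
    _flag(out["rna_depth"] < thresholds.min_depth, "low_depth_removed")
    _flag(out["second_allele_count"] >= thresholds.min_second_allele_count, "multi_allelic_removed")
    dna_frac = out["dna_alt_count"].fillna(0) / out["dna_depth"].replace(0, np.nan)
    is_dna_variant = (dna_frac.fillna(0) > thresholds.dna_alt_fraction) | (
        out["dna_alt_count"].fillna(0) >= thresholds.dna_alt_count
    )
    _flag(is_dna_variant, "dna_variant_removed")
    if snp_mask is not None and len(snp_mask):
        in_mask = pd.Series(
            [(c, p) in snp_mask for c, p in zip(out["chrom"], out["pos"])], index=out.index
        )
    else:
        in_mask = pd.Series(False, index=out.index)
    _flag(in_mask, "snp_removed")
    _flag(
        (out["level"] < thresholds.min_level) | (out["level"] >= thresholds.max_level),
        "level_out_of_range_removed",
    )
    status[undecided] = PASSED
    out["status"] = status
    return out


def resolve_strand(sites: pd.DataFrame, annotation: AnnotationIndex | None) -> pd.DataFrame:
    """Assign gene strand and strand-resolved edit type to called sites.

    Under an unstranded counting strategy a minus-strand gene reports the
    reverse-complement mismatch, so a raw T>C inside a minus-strand gene is
    the A-to-I edit A>G.  Sites outside genes, or hit by genes on both
    strands, keep strand ``unknown`` and the raw mismatch type.
    """
    out = sites.copy()
    if annotation is None:
        out["strand"] = "unknown"
        out["gene_id"] = ""
        out["region"] = "intergenic"
        out["edit_type"] = out["ref"] + ">" + out["alt"]
        return out
    keys = out[["chrom", "pos"]].drop_duplicates()
    resolved = {}
    for row in keys.itertuples(index=False):
        gene_id, _strand, region = annotation.classify(row.chrom, int(row.pos))
        strand = annotation.gene_strand(row.chrom, int(row.pos))
        resolved[(row.chrom, int(row.pos))] = (gene_id or "", strand, region)
    mapped = [resolved[(c, int(p))] for c, p in zip(out["chrom"], out["pos"])]
    out["gene_id"] = [m[0] for m in mapped]
    out["strand"] = [m[1] for m in mapped]
    out["region"] = [m[2] for m in mapped]
    minus = out["strand"] == "-"
    ref_res = np.where(minus, out["ref"].map(COMPLEMENT), out["ref"])
    alt_res = np.where(minus, out["alt"].map(COMPLEMENT), out["alt"])
    out["edit_type"] = pd.Series(ref_res, index=out.index) + ">" + pd.Series(alt_res, index=out.index)
    return out


def call_sample(
    rna: SiteCountsTable,
    dna: SiteCountsTable,
    snp_mask: SnpMask | None = None,
    annotation: AnnotationIndex | None = None,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Full per-sample calling: candidates -> filter cascade -> strand resolution."""
    if rna.sample_id != dna.sample_id:
        log.warning("RNA sample %s paired with DNA sample %s", rna.sample_id, dna.sample_id)
    candidates = call_candidates(rna, dna, thresholds)
    filtered = apply_filters(candidates, snp_mask, thresholds)
    return resolve_strand(filtered, annotation)


# ---------------------------------------------------------------------------
# merged matrix
# ---------------------------------------------------------------------------


@dataclass
class EditingMatrix:
    """Sites x samples editing levels with depths, counts and metadata.

    ``sites`` is indexed by ``chrom:pos`` site ids and carries chrom, pos,
    ref, alt, strand, edit_type, gene_id and region.  ``level``/``depth``/
    ``alt_count``/``ref_count`` share that index with one column per sample;
    entries are missing (NaN) where the site did not pass in that sample.
    ``samples`` is indexed by sample id with condition and pair_id columns.
    """

    sites: pd.DataFrame
    level: pd.DataFrame
    depth: pd.DataFrame
    alt_count: pd.DataFrame
    ref_count: pd.DataFrame
    samples: pd.DataFrame
    log_: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)

    def condition_samples(self, condition: str) -> list[str]:
        return list(self.samples.index[self.samples["condition"] == condition])

    def sample_coverage(self) -> pd.DataFrame:
        """Per-site number of samples with a passing observation, per condition."""
        observed = self.level.notna()
        return pd.DataFrame(
            {
                "tumor": observed[self.condition_samples("tumor")].sum(axis=1),
                "normal": observed[self.condition_samples("normal")].sum(axis=1),
            },
            index=self.level.index,
        )


def merge_samples(per_sample: dict[str, pd.DataFrame], samples: pd.DataFrame) -> EditingMatrix:
    """Union passing sites across samples into an :class:`EditingMatrix`.

    ``per_sample`` maps sample_id -> the output of :func:`call_sample`; only
    rows with status ``passed`` enter the matrix.  A duplicated (chrom, pos)
    within one sample raises :class:`IntegrityError`.
    """
    frames = []
    for sample_id, df in per_sample.items():
        passing = df[df["status"] == PASSED].copy()
        if passing.duplicated(subset=["chrom", "pos"]).any():
            dup = passing[passing.duplicated(subset=["chrom", "pos"])].iloc[0]
            raise IntegrityError(f"sample {sample_id}: duplicate site {dup.chrom}:{dup.pos}")
        passing["sample_id"] = sample_id
        frames.append(passing)
    sample_ids = list(samples.index)
    if not frames:
        empty_sites = pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "strand", "edit_type", "gene_id", "region"]
        )
        empty = pd.DataFrame(index=pd.Index([], name="site_id"), columns=sample_ids, dtype=float)
        return EditingMatrix(empty_sites, empty, empty.copy(), empty.copy(), empty.copy(), samples)
    allp = pd.concat(frames, ignore_index=True)
    allp["pos"] = allp["pos"].astype(int)  # empty frames in the concat upcast to float
    allp["site_id"] = allp["chrom"].astype(str) + ":" + allp["pos"].astype(str)

    order = allp.sort_values(["chrom", "pos"])["site_id"].drop_duplicates()
    meta_cols = ["chrom", "pos", "ref", "alt", "strand", "edit_type", "gene_id", "region"]
    sites = (
        allp.groupby("site_id")[meta_cols]
        .agg(
            {
                "chrom": "first",
                "pos": "first",
                "ref": "first",
                "alt": lambda s: s.mode().iloc[0],
                "strand": "first",
                "edit_type": lambda s: s.mode().iloc[0],
                "gene_id": "first",
                "region": "first",
            }
        )
        .reindex(order)
    )
    sites.index.name = "site_id"

    def _pivot(col: str) -> pd.DataFrame:
        wide = allp.pivot(index="site_id", columns="sample_id", values=col)
        return wide.reindex(index=order, columns=sample_ids)

    return EditingMatrix(
        sites=sites,
        level=_pivot("level"),
        depth=_pivot("rna_depth"),
        alt_count=_pivot("rna_alt_count"),
        ref_count=_pivot("rna_ref_count"),
        samples=samples.copy(),
    )


def flag_summary(filtered: pd.DataFrame) -> pd.Series:
    """Candidate counts by status; statuses partition the candidate set."""
    return filtered["status"].value_counts().reindex(ALL_STATUSES, fill_value=0)
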