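"""Intersections of DREs with expression and splicing evidence.

* eDREs: DREs in differentially expressed genes (|log2FC| >= 1, padj <
  0.05), grouped by editing mode; the genes are edDEGs.  A paired
  median-log2-fold-change differential-expression stand-in is provided for
  studies without an external DESeq2 table (it is a documented stand-in,
  not a DESeq2 reimplementation).
* sDREs: DREs whose position falls inside the defining span of a
  significantly different alternative-splicing event (exons plus flanking
  introns, per event type); the genes are edDSGs.
* edited/unedited sequence-pair extraction around a site for external RNA
  secondary-structure prediction, and bookkeeping of externally computed
  minimum-free-energy differences.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .adar import ExpressionMatrix
from .calling import EditingMatrix
from .context import _revcomp
from .io import _ref_fetch

log = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI")


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def paired_log2fc_deg(expr: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Paired fold-change differential-expression stand-in.

    Per gene: the median over pairs of log2((tumor + 1)/(normal + 1)) and a
    paired two-sided t-test on log2(value + 1), BH-corrected across genes.
    Output columns: gene_id (index), log2fc, pvalue, padj.
    """
    meta = expr.samples
    pairs = sorted(set(meta["pair_id"]))
    tumor_of = {meta.loc[s, "pair_id"]: s for s in meta.index if meta.loc[s, "condition"] == "tumor"}
    normal_of = {meta.loc[s, "pair_id"]: s for s in meta.index if meta.loc[s, "condition"] == "normal"}
    pairs = [p for p in pairs if p in tumor_of and p in normal_of]
    if len(pairs) < 2:
        raise ValueError("need at least 2 complete pairs for the paired fold-change stand-in")
    logv = np.log2(expr.values + pseudocount)
    t_cols = logv[[tumor_of[p] for p in pairs]].to_numpy()
    n_cols = logv[[normal_of[p] for p in pairs]].to_numpy()
    diff = t_cols - n_cols
    log2fc = np.median(diff, axis=1)
    res = stats.ttest_rel(t_cols, n_cols, axis=1)
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    out = pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvals, "padj": stats.false_discovery_control(pvals, method="bh")},
        index=expr.values.index,
    )
    return out


def read_deg_table(path) -> pd.DataFrame:
    """Read an external DEG table (gene_id, log2fc, padj; extra columns kept)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "log2fc", "padj"):
        if col not in df.columns:
            raise ValueError(f"DEG table missing column {col!r}")
    return df.set_index("gene_id")


def intersect_expression(
    dre_table: pd.DataFrame,
    deg_table: pd.DataFrame,
    min_abs_log2fc: float = 1.0,
    max_padj: float = 0.05,
) -> dict:
    """Join DREs with DEGs at the gene level to produce eDREs and edDEGs.

    ``deg_table`` is indexed by gene_id with log2fc and padj columns.  A
    complete gene-id namespace mismatch (DREs in genes, none resolvable in
    the DEG table) raises an error listing a sample of unmatched ids.
    Returns the eDRE site table plus per-group gene and site counts.
    """
    dres = dre_table[dre_table["is_dre"]].copy()
    genic = dres[dres["gene_id"] != ""]
    if len(genic) and not set(genic["gene_id"]) & set(deg_table.index):
        sample = sorted(set(genic["gene_id"]))[:10]
        raise ValueError(f"gene-id namespaces do not overlap; unmatched DRE genes include {sample}")
    degs = deg_table[(deg_table["log2fc"].abs() >= min_abs_log2fc) & (deg_table["padj"] < max_padj)]
    edre = genic[genic["gene_id"].isin(degs.index)].copy()
    edre = edre.join(degs[["log2fc", "padj"]], on="gene_id")
    edre["layer"] = "eDRE"
    by_group = (
        edre.groupby("group")
        .agg(n_sites=("gene_id", "size"), n_genes=("gene_id", "nunique"))
        .reindex(["shared", "tumor_specific", "normal_specific"], fill_value=0)
    )
    ed_degs = sorted(edre["gene_id"].unique())
    log.info("eDRE intersection: %d sites in %d edDEGs", len(edre), len(ed_degs))
    return {"edre": edre, "eddeg_genes": ed_degs, "by_group": by_group}


def editing_expression_correlation(
    matrix: EditingMatrix, expr: ExpressionMatrix, site_id: str, min_obs: int = 5
) -> dict | None:
    """Spearman correlation between a site's editing level and its gene's
    expression across samples; None for degenerate or under-observed input."""
    if site_id not in matrix.sites.index:
        raise KeyError(f"unknown site {site_id!r}")
    gene_id = matrix.sites.loc[site_id, "gene_id"]
    if not gene_id or gene_id not in expr.values.index:
        return None
    levels = matrix.level.loc[site_id].dropna()
    shared = [s for s in levels.index if s in expr.values.columns]
    if len(shared) < max(min_obs, 3):
        return None
    e = expr.values.loc[gene_id, shared]
    lv = levels.loc[shared]
    if lv.nunique() < 2 or e.nunique() < 2:
        return None
    res = stats.spearmanr(lv, e)
    return {"rho": float(res.statistic), "p": float(res.pvalue), "n": len(shared), "gene_id": gene_id}


# ---------------------------------------------------------------------------
# splicing
# ---------------------------------------------------------------------------


def event_span(event) -> tuple[int, int]:
    """Defining genomic span of a splicing event (0-based half-open).

    SE: skipped exon plus both flanking introns (upstream exon start to
    downstream exon end); MXE: both exclusive exons plus internal introns;
    A5SS/A3SS: the alternative splice-site region plus its intron; RI: the
    retained-intron block.  Causal edits sit in flanking introns, so spans
    include them.
    """
    etype = event.event_type
    if etype not in EVENT_TYPES:
        raise ValueError(f"unknown splicing event type {etype!r}")
    if etype == "RI":
        return int(event.exon_start), int(event.exon_end)
    coords = [
        int(c)
        for c in (
            event.exon_start, event.exon_end, event.upstream_es, event.upstream_ee,
            event.downstream_es, event.downstream_ee,
        )
        if int(c) >= 0
    ]
    return min(coords), max(coords)


def read_splicing_events(path) -> pd.DataFrame:
    """Read an rMATS-dialect splicing-event TSV."""
    df = pd.read_csv(path, sep="\t")
    required = {
        "gene_id", "chrom", "strand", "event_type", "exon_start", "exon_end",
        "upstream_es", "upstream_ee", "downstream_es", "downstream_ee",
        "inc_level_difference", "pvalue",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"splicing table missing columns {sorted(missing)}")
    bad = set(df["event_type"]) - set(EVENT_TYPES)
    if bad:
        raise ValueError(f"unknown splicing event types {sorted(bad)}")
    return df


def intersect_splicing(dre_table: pd.DataFrame, events: pd.DataFrame, matrix: EditingMatrix | None = None) -> dict:
    """DREs inside splicing-event spans (sDREs) and per-event-type summaries.

    Returns the sDRE table (one row per DRE x containing event), the
    fraction of events containing at least one DRE, per-event-type counts,
    and per-type editing-level summaries (mean DRE level per condition when
    a matrix is supplied).
    """
    bad = set(events["event_type"]) - set(EVENT_TYPES)
    if bad:
        raise ValueError(f"unknown splicing event types {sorted(bad)}")
    dres = dre_table[dre_table["is_dre"]]
    rows = []
    events_hit = np.zeros(len(events), dtype=bool)
    for chrom, sub_events in events.groupby("chrom"):
        sub_dres = dres[dres["chrom"] == chrom]
        if sub_dres.empty:
            continue
        pos0 = sub_dres["pos"].to_numpy() - 1
        for i, event in sub_events.iterrows():
            start, end = event_span(event)
            inside = (pos0 >= start) & (pos0 < end)
            if inside.any():
                events_hit[events.index.get_loc(i)] = True
                for site_id in sub_dres.index[inside]:
                    rows.append(
                        {
                            "site_id": site_id,
                            "event_id": event.get("event_id", str(i)),
                            "event_type": event["event_type"],
                            "event_gene": event["gene_id"],
                            "inc_level_difference": event["inc_level_difference"],
                            "event_pvalue": event["pvalue"],
                            "layer": "sDRE",
                        }
                    )
    sdre = pd.DataFrame(rows, columns=[
        "site_id", "event_id", "event_type", "event_gene", "inc_level_difference", "event_pvalue", "layer",
    ])
    fraction = float(events_hit.mean()) if len(events) else np.nan
    by_type = sdre.groupby("event_type").size().reindex(EVENT_TYPES, fill_value=0).rename("n_sdre").to_frame()
    levels_by_type = None
    if matrix is not None and len(sdre):
        lv = matrix.level
        tum, nor = matrix.condition_samples("tumor"), matrix.condition_samples("normal")
        recs = []
        for etype, sub in sdre.groupby("event_type"):
            ids = [s for s in sub["site_id"].unique() if s in lv.index]
            recs.append(
                {
                    "event_type": etype,
                    "n_sites": len(ids),
                    "mean_level_tumor": float(lv.loc[ids, tum].stack().mean()) if ids else np.nan,
                    "mean_level_normal": float(lv.loc[ids, nor].stack().mean()) if ids else np.nan,
                }
            )
        levels_by_type = pd.DataFrame(recs).set_index("event_type")
    log.info("sDRE intersection: %d/%d events contain a DRE (%.3f)", int(events_hit.sum()), len(events), fraction)
    return {
        "sdre": sdre,
        "fraction_events_with_dre": fraction,
        "by_type": by_type,
        "levels_by_type": levels_by_type,
        "eddsg_genes": sorted(set(sdre["event_gene"]) - {"NA", ""}),
    }


# ---------------------------------------------------------------------------
# structure pairs
# ---------------------------------------------------------------------------


def extract_structure_pairs(site, reference, window: int = 250) -> tuple:
    """Unedited and edited (center A -> G) sequence windows around a site.

    ``site`` needs chrom, pos (1-based) and strand attributes/keys.  Returns
    two Biopython ``SeqRecord`` objects on the edited strand (minus-strand
    sites are reverse-complemented), identical except at the center, where
    the unedited record carries A and the edited one G.  Windows are clipped
    at contig edges with a warning; a center base other than A after strand
    resolution is an error.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    chrom = site["chrom"] if isinstance(site, dict) else site.chrom
    pos = int(site["pos"] if isinstance(site, dict) else site.pos)
    strand = site["strand"] if isinstance(site, dict) else site.strand
    seq = _ref_fetch(reference, chrom)
    p0 = pos - 1
    lo, hi = max(0, p0 - window), min(len(seq), p0 + window + 1)
    if lo != p0 - window or hi != p0 + window + 1:
        log.warning("structure window for %s:%d clipped at a contig edge", chrom, pos)
    raw = seq[lo:hi]
    center = p0 - lo
    if strand == "-":
        raw_un = _revcomp(raw)
        center = len(raw) - 1 - center
    else:
        raw_un = raw
    if raw_un[center] != "A":
        raise ValueError(
            f"{chrom}:{pos} center base is {raw_un[center]!r} after strand resolution, expected A"
        )
    raw_ed = raw_un[:center] + "G" + raw_un[center + 1 :]
    stem = f"{chrom}_{pos}_{strand if strand in '+-' else 'u'}"
    unedited = SeqRecord(Seq(raw_un), id=f"{stem}_unedited", description=f"window +-{window}")
    edited = SeqRecord(Seq(raw_ed), id=f"{stem}_edited", description=f"window +-{window}")
    return unedited, edited


def write_structure_pairs(sites: pd.DataFrame, reference, path, window: int = 250) -> int:
    """Write unedited/edited FASTA pairs for a table of sites; returns the
    number of pairs written."""
    from Bio import SeqIO

    records = []
    for row in sites.itertuples():
        unedited, edited = extract_structure_pairs(row, reference, window)
        records.extend([unedited, edited])
    SeqIO.write(records, str(path), "fasta")
    return len(records) // 2


def delta_mfe_report(mfe_table: pd.DataFrame, threshold: float = 1.0) -> dict:
    """Summarize externally computed minimum-free-energy results.

    ``mfe_table`` columns: site_id, mfe_unedited, mfe_edited (kcal/mol).
    Reports the fraction of sites whose |delta MFE| meets the threshold.
    """
    for col in ("site_id", "mfe_unedited", "mfe_edited"):
        if col not in mfe_table.columns:
            raise ValueError(f"MFE table missing column {col!r}")
    delta = (mfe_table["mfe_edited"] - mfe_table["mfe_unedited"]).astype(float)
    out = mfe_table.copy()
    out["delta_mfe"] = delta
    frac = float((delta.abs() >= threshold).mean()) if len(delta) else np.nan
    return {"table": out, "fraction_above_threshold": frac, "threshold": threshold}
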