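"""Editing-frequency F_ST between tumor and normal sample groups.

Editing frequencies are treated as biallelic allele frequencies with one
observation per sample: each sample contributes its editing level
alt/(ref+alt) as the "population allele frequency" of one sampled unit.
The default estimator is the Weir-Cockerham variance-components theta for
two populations with the heterozygosity terms dropped (no genotypes exist
for an editing fraction), i.e. F_ST = a / (a + b) with

    nbar = (n1 + n2) / 2
    nc   = n1 + n2 - (n1^2 + n2^2) / (n1 + n2)
    pbar = (n1 p1 + n2 p2) / (n1 + n2)
    s2   = [n1 (p1 - pbar)^2 + n2 (p2 - pbar)^2] / nbar
    a    = (nbar / nc) * [s2 - (pbar qbar - s2 / 2) / (nbar - 1)]
    b    = (nbar / (nbar - 1)) * (pbar qbar - s2 / 2)

where p1, p2 are the group means of the per-sample frequencies.  Negative
estimates are preserved raw and clamped to 0 in the headline column.  The
Hudson alternative uses pooled read counts per condition.

Sites with F_ST at or above a threshold (0.25 by default) are flagged as
candidates for positive selection on the editing frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import EditingMatrix

log = logging.getLogger(__name__)


@dataclass
class FstRecord:
    site_id: str
    fst_raw: float
    fst: float
    p_tumor: float
    p_normal: float
    n_tumor: int
    n_normal: int
    positive_selected: bool


def weir_cockerham_fst(freqs_a, freqs_b) -> float:
    """Weir-Cockerham theta for two groups of per-sample frequencies.

    Returns the raw estimate (may be negative; NaN when undefined).
    Refuses groups with fewer than 2 samples, where the variance
    components are undefined.
    """
    pa = np.asarray(freqs_a, dtype=float)
    pb = np.asarray(freqs_b, dtype=float)
    pa, pb = pa[~np.isnan(pa)], pb[~np.isnan(pb)]
    n1, n2 = len(pa), len(pb)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples for the W-C estimator")
    p1, p2 = pa.mean(), pb.mean()
    n = n1 + n2
    nbar = n / 2.0
    nc = n - (n1 * n1 + n2 * n2) / n
    pbar = (n1 * p1 + n2 * p2) / n
    qbar = 1.0 - pbar
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    a = (nbar / nc) * (s2 - (pbar * qbar - s2 / 2.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pbar * qbar - s2 / 2.0)
    denom = a + b
    if denom == 0.0:
        return 0.0 if a == 0.0 else np.nan
    return float(a / denom)


def hudson_fst(edited_a: int, total_a: int, edited_b: int, total_b: int) -> float:
    """Hudson-style F_ST from pooled read counts per condition.

    Uses the ratio-of-averages form with the within-group sampling
    correction; raw output lies in [-1, 1].
    """
    if total_a < 2 or total_b < 2:
        raise ValueError("each condition needs at least 2 pooled reads")
    p1, p2 = edited_a / total_a, edited_b / total_b
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (total_a - 1) - p2 * (1 - p2) / (total_b - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den == 0.0:
        return 0.0 if num == 0.0 else np.nan
    return float(np.clip(num / den, -1.0, 1.0))


def fst_per_site(
    matrix: EditingMatrix, site_ids=None, estimator: str = "weir_cockerham", min_samples: int = 2
) -> pd.DataFrame:
    """Per-site F_ST between tumor and normal per-sample editing frequencies.

    Sites with fewer than ``min_samples`` passing observations in either
    condition are reported missing.  ``fst`` is the headline estimate
    clamped to [0, 1]; ``fst_raw`` preserves the raw estimator output.
    """
    if estimator not in ("weir_cockerham", "hudson"):
        raise ValueError(f"unknown estimator {estimator!r}")
    ids = matrix.sites.index if site_ids is None else site_ids
    tum = matrix.condition_samples("tumor")
    nor = matrix.condition_samples("normal")
    rows = []
    for site_id in ids:
        lt = matrix.level.loc[site_id, tum].dropna()
        ln = matrix.level.loc[site_id, nor].dropna()
        raw = np.nan
        if len(lt) >= max(min_samples, 2) and len(ln) >= max(min_samples, 2):
            if estimator == "weir_cockerham":
                raw = weir_cockerham_fst(lt.to_numpy(), ln.to_numpy())
            else:
                et = int(matrix.alt_count.loc[site_id, tum].sum())
                ut = int(matrix.ref_count.loc[site_id, tum].sum())
                en = int(matrix.alt_count.loc[site_id, nor].sum())
                un = int(matrix.ref_count.loc[site_id, nor].sum())
                raw = hudson_fst(et, et + ut, en, en + un)
        rows.append(
            {
                "site_id": site_id,
                "fst_raw": raw,
                "fst": float(np.clip(raw, 0.0, 1.0)) if not np.isnan(raw) else np.nan,
                "p_tumor": lt.mean() if len(lt) else np.nan,
                "p_normal": ln.mean() if len(ln) else np.nan,
                "n_tumor": len(lt),
                "n_normal": len(ln),
            }
        )
    return pd.DataFrame(rows).set_index("site_id")


def selection_scan(
    dre_table: pd.DataFrame,
    matrix: EditingMatrix,
    threshold: float = 0.25,
    estimator: str = "weir_cockerham",
    immune_genes: set | None = None,
) -> dict:
    """Flag sites under candidate positive selection (F_ST >= threshold).

    Operates on any site table carrying the matrix's site ids (typically
    the DRE table).  Returns the table with ``fst``/``fst_raw``/
    ``positive_selected`` filled plus per-chromosome, per-gene and
    per-group hotspot summaries; when an ``immune_genes`` set is supplied,
    the flagged genes intersecting it are listed.
    """
    fst = fst_per_site(matrix, dre_table.index, estimator=estimator)
    table = dre_table.copy()
    table["fst_raw"] = fst["fst_raw"]
    table["fst"] = fst["fst"]
    table["positive_selected"] = table["fst"] >= threshold
    flagged = table[table["positive_selected"].fillna(False)]
    summaries = {
        "by_chromosome": flagged.groupby("chrom").size().rename("n_selected").to_frame(),
        "by_gene": flagged[flagged["gene_id"] != ""].groupby("gene_id").size().rename("n_selected").to_frame(),
    }
    if "group" in table.columns:
        summaries["by_group"] = flagged.groupby("group").size().rename("n_selected").to_frame()
    if immune_genes is not None:
        hits = sorted(set(flagged["gene_id"]) & set(immune_genes))
        summaries["immune_genes"] = pd.DataFrame({"gene_id": hits})
    log.info(
        "selection scan: %d/%d sites flagged at F_ST >= %s",
        int(table["positive_selected"].sum()), len(table), threshold,
    )
    return {"table": table, "summaries": summaries}


def export_pseudo_vcf(table: pd.DataFrame, matrix: EditingMatrix, path) -> None:
    """Export sites with per-sample editing frequencies as a VCF whose sample
    columns carry pseudo-genotype dosages, for cross-checking with external
    F_ST tools."""
    samples = list(matrix.samples.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=editscan-fst-export\n")
        fh.write('##FORMAT=<ID=EF,Number=1,Type=Float,Description="Editing frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for site_id, row in table.iterrows():
            levels = matrix.level.loc[site_id]
            fields = [
                str(row["chrom"]), str(int(row["pos"])), site_id, str(row["ref"]), str(row["alt"]),
                ".", "PASS", ".", "EF",
            ] + [("." if pd.isna(levels[s]) else f"{levels[s]:.4f}") for s in samples]
            fh.write("\t".join(fields) + "\n")
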