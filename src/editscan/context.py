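"""Sequence-context and genomic-distribution analyses of editing sites.

The neighbor-nucleotide profile compares base frequencies at offsets
-k..+k around strand-resolved A-to-I sites against a background of
adenosines from the same genes, the pattern that distinguishes ADAR
substrates (G depleted immediately upstream, G enriched immediately
downstream).  Minus-strand sites contribute reverse-complemented windows,
so the center base is always A on the edited strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BASES, AnnotationIndex, _ref_fetch

log = logging.getLogger(__name__)

_COMPLEMENT_TABLE = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


@dataclass
class ContextProfile:
    """Base frequencies around edited sites vs matched background adenosines.

    ``edited_freq`` and ``background_freq`` are (offset x base) frequency
    tables whose rows sum to 1; ``enrichment`` is the per-offset, per-base
    log2 ratio (with a +0.5 pseudocount on raw counts).  Offset 0 is the
    edited adenosine itself.
    """

    edited_freq: pd.DataFrame
    background_freq: pd.DataFrame
    enrichment: pd.DataFrame
    n_sites: int
    n_background: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for offset in self.edited_freq.index:
            for base in BASES:
                rows.append(
                    {
                        "offset": offset,
                        "base": base,
                        "edited_freq": self.edited_freq.loc[offset, base],
                        "background_freq": self.background_freq.loc[offset, base],
                        "log2_enrichment": self.enrichment.loc[offset, base],
                    }
                )
        return pd.DataFrame(rows)


def _window_freqs(windows: list[str], k: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    offsets = list(range(-k, k + 1))
    if not windows:
        freq = pd.DataFrame(np.nan, index=offsets, columns=list(BASES))
        return freq, pd.DataFrame(0, index=offsets, columns=list(BASES))
    arr = np.frombuffer("".join(windows).encode(), dtype="S1").reshape(len(windows), 2 * k + 1)
    counts = pd.DataFrame(
        {base: (arr == base.encode()).sum(axis=0) for base in BASES}, index=offsets
    )
    freq = counts.div(counts.sum(axis=1), axis=0)
    return freq, counts


def extract_windows(
    sites: pd.DataFrame, reference, k: int
) -> list[str]:
    """Strand-resolved +-k windows around sites (chrom, pos 1-based, strand).

    Minus-strand windows are reverse-complemented.  Windows running past a
    contig edge are skipped with a log notice.
    """
    windows = []
    skipped = 0
    for chrom, sub in sites.groupby("chrom", sort=True):
        seq = _ref_fetch(reference, chrom)
        for row in sub.itertuples():
            p0 = int(row.pos) - 1
            if p0 - k < 0 or p0 + k + 1 > len(seq):
                skipped += 1
                continue
            w = seq[p0 - k : p0 + k + 1]
            windows.append(_revcomp(w) if row.strand == "-" else w)
    if skipped:
        log.info("context: %d sites skipped (window beyond contig edge)", skipped)
    return windows


def gene_background_adenosines(
    annotation: AnnotationIndex, reference, gene_ids, site_positions: pd.DataFrame,
    k: int = 5, max_background: int | None = None, seed: int = 0,
) -> pd.DataFrame:
    """All gene-strand adenosine positions in the given genes whose +-k
    windows avoid every edited site (so background windows never contain an
    edited adenosine); a seeded subsample when a ``max_background`` cap is
    set."""
    site_by_chrom = {
        chrom: np.sort(sub["pos"].to_numpy())
        for chrom, sub in site_positions.groupby("chrom")
    }
    rows = []
    for gene_id in sorted(set(gene_ids) - {""}):
        gene = annotation.genes.get(gene_id)
        if gene is None:
            continue
        seq = _ref_fetch(reference, gene.chrom)[gene.start : gene.end]
        target = "A" if gene.strand == "+" else "T"
        hits = np.flatnonzero(np.frombuffer(seq.encode(), dtype="S1") == target.encode())
        pos = gene.start + hits + 1  # 1-based
        nearby = site_by_chrom.get(gene.chrom)
        if nearby is not None and len(nearby):
            idx = np.searchsorted(nearby, pos)
            left = np.abs(pos - nearby[np.clip(idx - 1, 0, len(nearby) - 1)])
            right = np.abs(nearby[np.clip(idx, 0, len(nearby) - 1)] - pos)
            pos = pos[np.minimum(left, right) > k]
        for p in pos:
            rows.append((gene.chrom, int(p), gene.strand))
    bg = pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
    if max_background is not None and len(bg) > max_background:
        rng = np.random.default_rng(seed)
        bg = bg.iloc[np.sort(rng.choice(len(bg), size=max_background, replace=False))]
    return bg.reset_index(drop=True)


def context_profile(
    sites: pd.DataFrame,
    reference,
    annotation: AnnotationIndex,
    k: int = 5,
    max_background: int | None = None,
    seed: int = 0,
) -> ContextProfile:
    """Neighbor-base preference profile of strand-resolved A-to-I sites.

    ``sites`` needs chrom, pos (1-based), strand and gene_id columns; only
    A>G sites after strand resolution belong here (the center base must be
    A on the edited strand).  The background is every other gene-strand
    adenosine in the same genes, which controls for gene base composition.
    """
    a2i = sites
    windows = extract_windows(a2i, reference, k)
    bg = gene_background_adenosines(
        annotation, reference, a2i["gene_id"], a2i[["chrom", "pos"]], k, max_background, seed
    )
    bg_windows = extract_windows(bg, reference, k)
    edited_freq, edited_counts = _window_freqs(windows, k)
    background_freq, bg_counts = _window_freqs(bg_windows, k)
    pe = (edited_counts + 0.5).div(edited_counts.sum(axis=1) + 2.0, axis=0)
    pb = (bg_counts + 0.5).div(bg_counts.sum(axis=1) + 2.0, axis=0)
    enrichment = np.log2(pe / pb)
    return ContextProfile(
        edited_freq=edited_freq,
        background_freq=background_freq,
        enrichment=enrichment,
        n_sites=len(windows),
        n_background=len(bg_windows),
    )


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------


def region_distribution(sites: pd.DataFrame, annotation: AnnotationIndex | None = None) -> pd.DataFrame:
    """Counts and fractions of sites per region class.

    Uses the ``region`` column when present, otherwise classifies positions
    with the annotation's precedence rule.  Fractions sum to 1 over the
    reported classes (all zero for an empty site list).
    """
    from .io import REGION_PRECEDENCE

    classes = sorted(REGION_PRECEDENCE, key=REGION_PRECEDENCE.get, reverse=True)
    if "region" in sites.columns:
        regions = sites["region"]
    elif annotation is not None:
        regions = pd.Series(
            [annotation.classify(c, int(p))[2] for c, p in zip(sites["chrom"], sites["pos"])],
            index=sites.index,
        )
    else:
        raise ValueError("need a region column or an annotation")
    counts = regions.value_counts().reindex(classes, fill_value=0)
    total = counts.sum()
    return pd.DataFrame(
        {"count": counts, "fraction": counts / total if total else 0.0}
    ).rename_axis("region")


def chromosome_distribution(
    sites: pd.DataFrame,
    reference=None,
    annotation: AnnotationIndex | None = None,
    normalization: str = "raw",
) -> pd.DataFrame:
    """Per-chromosome site counts, optionally normalized per Mb or per gene.

    The output follows the chromosome order of the reference when one is
    given; a site on a contig absent from the reference is an error.
    """
    if normalization not in ("raw", "per-Mb", "per-gene"):
        raise ValueError(f"unknown normalization {normalization!r}")
    counts = sites["chrom"].value_counts()
    if reference is not None:
        chroms = list(reference.keys())
        missing = set(counts.index) - set(chroms)
        if missing:
            raise ValueError(f"sites on contigs absent from the reference: {sorted(missing)}")
        counts = counts.reindex(chroms, fill_value=0)
    out = pd.DataFrame({"count": counts}).rename_axis("chrom")
    if normalization == "per-Mb":
        if reference is None:
            raise ValueError("per-Mb normalization needs a reference")
        lengths = pd.Series({c: len(_ref_fetch(reference, c)) for c in out.index})
        out["per_mb"] = out["count"] / (lengths / 1e6)
    elif normalization == "per-gene":
        if annotation is None:
            raise ValueError("per-gene normalization needs an annotation")
        spans = annotation.gene_spans()
        n_genes = spans.groupby("chrom").size().reindex(out.index).replace(0, np.nan)
        out["per_gene"] = out["count"] / n_genes
    return out


def repeat_overlap(sites: pd.DataFrame, repeats: pd.DataFrame | None) -> pd.DataFrame | None:
    """Fraction of sites inside repeat intervals (chrom, start, end; 0-based
    half-open), overall and per group when a ``group`` column is present.
    Returns None (with a notice) when no repeat intervals are supplied."""
    if repeats is None or len(repeats) == 0:
        log.info("no repeat intervals supplied; repeat overlap skipped")
        return None
    flags = np.zeros(len(sites), dtype=bool)
    for i, row in enumerate(sites.itertuples()):
        sub = repeats[repeats.chrom == row.chrom]
        flags[i] = bool(((sub.start <= row.pos - 1) & (row.pos - 1 < sub.end)).any())
    out = {"all": flags.mean() if len(flags) else np.nan}
    if "group" in sites.columns:
        for group, sub in sites.assign(_in=flags).groupby("group"):
            out[group] = sub["_in"].mean()
    return pd.DataFrame({"fraction_in_repeats": pd.Series(out)})


def motif_windows_fasta(sites: pd.DataFrame, reference, path, flank: int = 25) -> int:
    """Export +-flank windows around sites as FASTA for external motif tools
    (e.g. MEME with widths 30/50).  Returns the number of records written."""
    windows = []
    names = []
    for chrom, sub in sites.groupby("chrom", sort=True):
        seq = _ref_fetch(reference, chrom)
        for row in sub.itertuples():
            p0 = int(row.pos) - 1
            if p0 - flank < 0 or p0 + flank + 1 > len(seq):
                continue
            w = seq[p0 - flank : p0 + flank + 1]
            windows.append(_revcomp(w) if row.strand == "-" else w)
            names.append(f"{chrom}:{row.pos}:{row.strand}")
    with open(path, "w") as fh:
        for name, w in zip(names, windows):
            fh.write(f">{name}\n{w}\n")
    return len(windows)
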