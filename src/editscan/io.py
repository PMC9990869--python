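"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* Internal coordinates are 0-based half-open everywhere; all user-facing
  tables are 1-based closed, matching the REDItools output convention.
* Site-count tables use a REDItools-style TSV dialect with columns
  ``chrom, pos, ref, strand, depth, mean_quality, base_counts`` where
  ``base_counts`` holds the four comma-joined A,C,G,T read counts.
* Region classes are ``exonic, intronic, 5'UTR, 3'UTR, intergenic``.  When a
  position hits overlapping annotations the precedence is
  exonic > 3'UTR > 5'UTR > intronic > intergenic, with gene ties broken by
  lexicographic gene id.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .errors import FormatError, IntegrityError

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
COUNT_COLUMNS = ["n_a", "n_c", "n_g", "n_t"]
SITE_COUNT_HEADER = ["chrom", "pos", "ref", "strand", "depth", "mean_quality", "base_counts"]

REGION_EXONIC = "exonic"
REGION_INTRONIC = "intronic"
REGION_UTR5 = "5'UTR"
REGION_UTR3 = "3'UTR"
REGION_INTERGENIC = "intergenic"

#: precedence when one position hits several annotation classes (highest wins)
REGION_PRECEDENCE = {
    REGION_EXONIC: 4,
    REGION_UTR3: 3,
    REGION_UTR5: 2,
    REGION_INTRONIC: 1,
    REGION_INTERGENIC: 0,
}

_STRAND_TOKENS = {"+": "+", "-": "-", ".": "unknown", "unknown": "unknown"}


# ---------------------------------------------------------------------------
# site counts
# ---------------------------------------------------------------------------


@dataclass
class SiteCountsTable:
    """Per-position base counts for one sample and one assay (RNA or DNA).

    ``df`` columns: chrom, pos (1-based int), ref, strand, depth,
    mean_quality, n_a, n_c, n_g, n_t.  ``depth`` always equals the sum of the
    four base counts.
    """

    sample_id: str
    assay: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.assay not in ("RNA", "DNA"):
            raise ValueError(f"assay must be RNA or DNA, got {self.assay!r}")

    def __len__(self) -> int:
        return len(self.df)


def read_site_counts(
    path: str | os.PathLike,
    assay: str,
    sample_id: str | None = None,
    reference=None,
) -> SiteCountsTable:
    """Read a REDItools-style per-site base-count TSV.

    Parameters
    ----------
    path : file path
    assay : {"RNA", "DNA"}
    sample_id : defaults to the file stem
    reference : optional mapping/pyfaidx.Fasta; when given, the ``ref``
        column is checked against the reference base at each position.

    Raises
    ------
    FormatError
        missing columns (the message names the first missing column).
    IntegrityError
        depth does not equal the base-count sum, or a malformed row; the
        message carries 1-based line numbers (header is line 1).
    """
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(path))[0]
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in SITE_COUNT_HEADER:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df = df[SITE_COUNT_HEADER].copy()
    if df.empty:
        empty = pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "pos": pd.Series(dtype=int),
                "ref": pd.Series(dtype=str),
                "strand": pd.Series(dtype=str),
                "depth": pd.Series(dtype=int),
                "mean_quality": pd.Series(dtype=float),
                **{c: pd.Series(dtype=int) for c in COUNT_COLUMNS},
            }
        )
        return SiteCountsTable(sample_id, assay, empty)

    lines = df.index.to_numpy() + 2  # 1-based file line numbers

    counts = df["base_counts"].str.split(",", expand=True)
    if counts.shape[1] != 4:
        bad = lines[counts.isna().any(axis=1).to_numpy()]
        raise IntegrityError(f"{path}: base_counts must hold 4 comma-joined integers (lines {[int(x) for x in bad[:10]]})")
    try:
        counts = counts.astype(int)
        out = pd.DataFrame(
            {
                "chrom": df["chrom"].astype(str),
                "pos": df["pos"].astype(int),
                "ref": df["ref"].astype(str).str.upper(),
                "strand": df["strand"].astype(str),
                "depth": df["depth"].astype(int),
                "mean_quality": df["mean_quality"].astype(float),
            }
        )
    except ValueError as exc:
        raise IntegrityError(f"{path}: malformed numeric field ({exc})") from exc
    for col, name in zip(counts.columns, COUNT_COLUMNS):
        out[name] = counts[col].to_numpy()

    bad_ref = ~out["ref"].isin(BASES)
    if bad_ref.any():
        raise IntegrityError(f"{path}: ref base must be one of A/C/G/T (lines {[int(x) for x in lines[bad_ref.to_numpy()][:10]]})")
    bad_pos = out["pos"] < 1
    if bad_pos.any():
        raise IntegrityError(f"{path}: pos must be >= 1 (lines {[int(x) for x in lines[bad_pos.to_numpy()][:10]]})")
    bad_strand = ~out["strand"].isin(_STRAND_TOKENS)
    if bad_strand.any():
        raise IntegrityError(f"{path}: unknown strand token (lines {[int(x) for x in lines[bad_strand.to_numpy()][:10]]})")
    out["strand"] = out["strand"].map(_STRAND_TOKENS)
    if (out[COUNT_COLUMNS] < 0).any().any():
        raise IntegrityError(f"{path}: negative base count")
    mismatch = out["depth"] != out[COUNT_COLUMNS].sum(axis=1)
    if mismatch.any():
        raise IntegrityError(
            f"{path}: depth does not equal the base-count sum (lines {[int(x) for x in lines[mismatch.to_numpy()][:10]]})"
        )
    if reference is not None:
        for chrom, sub in out.groupby("chrom", sort=False):
            seq = _ref_fetch(reference, chrom)
            ref_bases = np.frombuffer(seq.encode(), dtype="S1")[sub["pos"].to_numpy() - 1]
            obs = sub["ref"].to_numpy().astype("S1")
            bad = ref_bases != obs
            if bad.any():
                raise IntegrityError(
                    f"{path}: ref column disagrees with reference FASTA on {chrom} "
                    f"(lines {[int(x) for x in lines[sub.index.to_numpy()[bad]][:10]]})"
                )
    return SiteCountsTable(sample_id, assay, out.reset_index(drop=True))


def write_site_counts(table: SiteCountsTable, path: str | os.PathLike) -> None:
    """Write a :class:`SiteCountsTable` back to the TSV dialect (round-trip safe)."""
    df = table.df
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "ref": df["ref"],
            "strand": df["strand"],
            "depth": df["depth"],
            "mean_quality": df["mean_quality"].map(lambda q: format(float(q), "g")),
            "base_counts": (
                df["n_a"].astype(str)
                + ","
                + df["n_c"].astype(str)
                + ","
                + df["n_g"].astype(str)
                + ","
                + df["n_t"].astype(str)
            )
            if len(df)
            else pd.Series(dtype=str),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def _ref_fetch(reference, chrom: str) -> str:
    """Fetch a whole contig as an upper-case string from dict/pyfaidx inputs."""
    seq = reference[chrom]
    return str(seq[:]).upper() if not isinstance(seq, str) else seq.upper()


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted
    cds: tuple[int, int] | None = None  # 0-based half-open span


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based
    end: int  # half-open
    transcripts: list[Transcript] = field(default_factory=list)


class AnnotationIndex:
    """Gene/region model resolving genomic positions to gene, strand and region class.

    Built from GFF3 or BED12 via :func:`read_annotation`, or directly from
    :class:`Gene` records.  Internal coordinates are 0-based half-open.
    """

    def __init__(self, genes: list[Gene]):
        self.genes: dict[str, Gene] = {}
        self._feature_trees: dict[str, IntervalTree] = {}
        self._gene_trees: dict[str, IntervalTree] = {}
        for gene in genes:
            if gene.gene_id in self.genes:
                raise IntegrityError(f"duplicate gene id {gene.gene_id!r}")
            for tx in gene.transcripts:
                for (s, e) in tx.exons:
                    if s < gene.start or e > gene.end:
                        raise IntegrityError(
                            f"exon [{s},{e}) of {tx.transcript_id} outside gene span of {gene.gene_id}"
                        )
            self.genes[gene.gene_id] = gene
            gtree = self._gene_trees.setdefault(gene.chrom, IntervalTree())
            gtree.addi(gene.start, gene.end, gene.gene_id)
            ftree = self._feature_trees.setdefault(gene.chrom, IntervalTree())
            for seg_start, seg_end, region in _region_segments(gene):
                ftree.addi(seg_start, seg_end, (gene.gene_id, region))

    # -- queries ------------------------------------------------------------

    def query(self, chrom: str, pos: int) -> list[tuple[str, str, str]]:
        """All (gene_id, strand, region_class) pairs hit by a 1-based position."""
        p0 = pos - 1
        hits: dict[tuple[str, str], str] = {}
        for iv in self._feature_trees.get(chrom, IntervalTree()).at(p0):
            gene_id, region = iv.data
            key = (gene_id, region)
            hits[key] = region
        genic = {gene_id for (gene_id, _r) in hits}
        for iv in self._gene_trees.get(chrom, IntervalTree()).at(p0):
            if iv.data not in genic:
                hits[(iv.data, REGION_INTRONIC)] = REGION_INTRONIC
        out = [(g, self.genes[g].strand, r) for (g, r) in hits]
        out.sort(key=lambda t: (-REGION_PRECEDENCE[t[2]], t[0]))
        return out

    def classify(self, chrom: str, pos: int) -> tuple[str | None, str, str]:
        """Single (gene_id, strand, region_class) for a 1-based position.

        Precedence: exonic > 3'UTR > 5'UTR > intronic; ties by gene id.
        Positions outside all genes are (None, 'unknown', 'intergenic').
        """
        hits = self.query(chrom, pos)
        if not hits:
            return None, "unknown", REGION_INTERGENIC
        return hits[0]

    def gene_strand(self, chrom: str, pos: int) -> str:
        """Strand for strand resolution: the common strand of all genes hit,
        or 'unknown' when the position is intergenic or genes disagree."""
        strands = {s for (_g, s, _r) in self.query(chrom, pos)}
        if len(strands) == 1:
            return strands.pop()
        return "unknown"

    def gene_spans(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand, "start": g.start, "end": g.end}
            for g in self.genes.values()
        ]
        df = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])
        return df.sort_values("gene_id").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.genes)


def _region_segments(gene: Gene):
    """Yield (start, end, region_class) exonic/UTR segments of a gene (0-based half-open).

    Exon parts outside the CDS become 5'/3' UTR according to the gene strand;
    transcripts without a CDS contribute plain exonic segments.  Introns are
    implicit (gene span minus feature segments).
    """
    for tx in gene.transcripts:
        for (s, e) in tx.exons:
            if tx.cds is None:
                yield s, e, REGION_EXONIC
                continue
            cs, ce = tx.cds
            left = (REGION_UTR5 if gene.strand == "+" else REGION_UTR3)
            right = (REGION_UTR3 if gene.strand == "+" else REGION_UTR5)
            if e <= cs:
                yield s, e, left
            elif s >= ce:
                yield s, e, right
            else:
                if s < cs:
                    yield s, cs, left
                yield max(s, cs), min(e, ce), REGION_EXONIC
                if e > ce:
                    yield ce, e, right


def read_annotation(path: str | os.PathLike) -> AnnotationIndex:
    """Read gene models from GFF3 (1-based closed) or BED12 (0-based half-open).

    The dialect is chosen from the file extension (.gff/.gff3 vs .bed); an
    unknown extension raises :class:`FormatError`.
    """
    name = str(path).lower()
    if name.endswith((".gff", ".gff3")):
        return _read_gff3(path)
    if name.endswith(".bed"):
        return _read_bed12(path)
    raise FormatError(f"{path}: unknown annotation dialect (expected .gff3/.gff or .bed)")


def _read_gff3(path) -> AnnotationIndex:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for grec in db.features_of_type("gene", order_by="start"):
        gene = Gene(
            gene_id=grec.id,
            chrom=grec.seqid,
            strand=grec.strand if grec.strand in "+-" else "+",
            start=grec.start - 1,
            end=grec.end,
        )
        transcripts = list(db.children(grec, featuretype=("mRNA", "transcript"), order_by="start"))
        if not transcripts:
            transcripts = [grec]  # exons attached directly to the gene
        for trec in transcripts:
            exons = sorted((e.start - 1, e.end) for e in db.children(trec, featuretype="exon"))
            cds_parts = sorted((c.start - 1, c.end) for c in db.children(trec, featuretype="CDS"))
            cds = (cds_parts[0][0], cds_parts[-1][1]) if cds_parts else None
            if exons:
                gene.transcripts.append(Transcript(trec.id, exons, cds))
        genes.append(gene)
    if not genes:
        log.warning("%s: no gene features found", path)
    return AnnotationIndex(genes)


def _read_bed12(path) -> AnnotationIndex:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 requires 12 columns, got {len(fields)}")
            chrom, start, end, gene_name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if fields[5] in "+-" else "+"
            thick_start, thick_end = int(fields[6]), int(fields[7])
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{lineno}: blockCount disagrees with block lists")
            exons = [(start + off, start + off + size) for off, size in zip(starts, sizes)]
            cds = (thick_start, thick_end) if thick_end > thick_start else None
            gene = Gene(gene_name, chrom, strand, start, end)
            gene.transcripts.append(Transcript(gene_name + ".t1", exons, cds))
            genes.append(gene)
    return AnnotationIndex(genes)


def write_gff3(index: AnnotationIndex, path: str | os.PathLike) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS rows, 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id in sorted(index.genes):
            g = index.genes[gene_id]
            fh.write(
                f"{g.chrom}\teditscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for tx in g.transcripts:
                fh.write(
                    f"{g.chrom}\teditscan\tmRNA\t{tx.exons[0][0] + 1}\t{tx.exons[-1][1]}\t.\t{g.strand}\t.\t"
                    f"ID={tx.transcript_id};Parent={g.gene_id}\n"
                )
                for i, (s, e) in enumerate(tx.exons, start=1):
                    fh.write(
                        f"{g.chrom}\teditscan\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={tx.transcript_id}.e{i};Parent={tx.transcript_id}\n"
                    )
                if tx.cds is not None:
                    cs, ce = tx.cds
                    for i, (s, e) in enumerate(tx.exons, start=1):
                        os_, oe = max(s, cs), min(e, ce)
                        if os_ < oe:
                            fh.write(
                                f"{g.chrom}\teditscan\tCDS\t{os_ + 1}\t{oe}\t.\t{g.strand}\t0\t"
                                f"ID={tx.transcript_id}.c{i};Parent={tx.transcript_id}\n"
                            )


# ---------------------------------------------------------------------------
# SNP mask
# ---------------------------------------------------------------------------


class SnpMask:
    """Set of SNV positions to exclude; membership is exact on (chrom, 1-based pos).

    Matching is on position only (no allele bookkeeping): any reported SNV at
    the position masks it.
    """

    def __init__(self, positions=(), n_indels_skipped: int = 0):
        self.positions: set[tuple[str, int]] = set(positions)
        self.n_indels_skipped = n_indels_skipped

    @classmethod
    def from_vcf(cls, path: str | os.PathLike) -> "SnpMask":
        positions = set()
        n_indels = 0
        try:
            vcf = pysam.VariantFile(str(path))
        except (OSError, ValueError) as exc:
            raise FormatError(f"{path}: unreadable VCF ({exc})") from exc
        with vcf:
            for rec in vcf.fetch() if vcf.index is not None else vcf:
                alts = rec.alts or ()
                snv_alts = [a for a in alts if a is not None and len(a) == 1 and len(rec.ref or "") == 1]
                if snv_alts:
                    positions.add((rec.chrom, rec.pos))
                if len(snv_alts) < len(alts):
                    n_indels += 1
        log.info("SNP mask: %d positions, %d indel records skipped", len(positions), n_indels)
        return cls(positions, n_indels)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.positions

    def __len__(self) -> int:
        return len(self.positions)


def read_snp_mask(path: str | os.PathLike) -> SnpMask:
    """Read a VCF into a :class:`SnpMask` (SNVs only; indels skipped and counted)."""
    return SnpMask.from_vcf(path)


def write_snv_vcf(df: pd.DataFrame, path: str | os.PathLike, source: str = "editscan") -> None:
    """Write SNVs (columns chrom, pos [1-based], ref, alt) as a minimal VCF 4.2 body."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in df.sort_values(["chrom", "pos"]).itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a (small) FASTA into chromosome -> upper-case sequence strings."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
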