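"""Neighbor-base context profiles and genomic distribution summaries."""

import numpy as np
import pandas as pd
import pytest

from editscan.context import (
    chromosome_distribution,
    context_profile,
    region_distribution,
    repeat_overlap,
)
from editscan.io import AnnotationIndex, Gene, Transcript
from editscan.simulate import SimConfig, simulate

COMP = str.maketrans("ACGT", "TGCA")


def _single_gene_annotation(chrom="chr1", strand="+", start=0, end=100):
    gene = Gene("G001", chrom, strand, start, end)
    gene.transcripts.append(Transcript("G001.t", [(start, end)], None))
    return AnnotationIndex([gene])


class TestContextProfile:
    def test_single_site_window_read_off(self):
        #                0123456789012
        reference = {"chr1": "ACGTAAGTACGCC"}
        ann = _single_gene_annotation(end=13)
        sites = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [6], "strand": ["+"], "gene_id": ["G001"]}
        )
        prof = context_profile(sites, reference, ann, k=5)
        window = "ACGTAAGTACG"  # positions 1..11 centered on pos 6 (A at index 5)
        for offset in range(-5, 6):
            base = window[offset + 5]
            assert prof.edited_freq.loc[offset, base] == 1.0

    def test_minus_strand_uses_reverse_complement(self):
        seq = "ACGTAAGTACGCC"
        reference = {"chr1": seq}
        ann = _single_gene_annotation(strand="-", end=13)
        # center must be A on the minus strand => T on the plus strand (pos 8, 1-based)
        sites = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [8], "strand": ["-"], "gene_id": ["G001"]}
        )
        prof = context_profile(sites, reference, ann, k=2)
        window = seq[5:10].translate(COMP)[::-1]
        assert window[2] == "A"
        for offset in range(-2, 3):
            assert prof.edited_freq.loc[offset, window[offset + 2]] == 1.0

    def test_edge_windows_skipped(self):
        reference = {"chr1": "AAAA"}
        ann = _single_gene_annotation(end=4)
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [1], "strand": ["+"], "gene_id": ["G001"]})
        prof = context_profile(sites, reference, ann, k=5)
        assert prof.n_sites == 0

    def test_motif_extremes_on_simulation(self):
        sim = simulate(SimConfig(
            seed=21, motif_bias=1.0, n_shared=120, n_tumor_specific=0, n_normal_specific=0,
            n_shared_diff=0, n_fst=0, n_background=0, n_snps=0, n_dna_variants=0,
            n_splice_events=0, n_genes=12, chrom_length=60_000,
        ))
        genic = sim.sites[sim.sites.gene_id != ""]
        prof = context_profile(genic, sim.reference, sim.annotation, k=5)
        assert prof.edited_freq.loc[-1, "G"] == 0.0
        assert prof.edited_freq.loc[1, "G"] == 1.0
        assert prof.edited_freq.loc[0, "A"] == 1.0

    def test_reverse_complement_strand_flip_invariance(self):
        sim = simulate(SimConfig(
            seed=22, n_shared=80, n_tumor_specific=40, n_normal_specific=40,
            n_shared_diff=0, n_fst=0, n_background=0, n_snps=0, n_dna_variants=0,
            n_splice_events=0, n_genes=12, chrom_length=60_000,
        ))
        genic = sim.sites[sim.sites.gene_id != ""]
        prof = context_profile(genic, sim.reference, sim.annotation, k=5)

        flipped_ref = {c: s.translate(COMP)[::-1] for c, s in sim.reference.items()}
        length = {c: len(s) for c, s in sim.reference.items()}
        genes = []
        for g in sim.annotation.genes.values():
            L = length[g.chrom]
            fg = Gene(g.gene_id, g.chrom, "-" if g.strand == "+" else "+", L - g.end, L - g.start)
            for tx in g.transcripts:
                exons = sorted((L - e, L - s) for (s, e) in tx.exons)
                cds = (L - tx.cds[1], L - tx.cds[0]) if tx.cds else None
                fg.transcripts.append(Transcript(tx.transcript_id, exons, cds))
            genes.append(fg)
        flipped_ann = AnnotationIndex(genes)
        flipped_sites = genic.copy()
        flipped_sites["pos"] = [length[c] - p + 1 for c, p in zip(genic.chrom, genic.pos)]
        flipped_sites["strand"] = ["+" if s == "-" else "-" for s in genic.strand]
        prof2 = context_profile(flipped_sites, flipped_ref, flipped_ann, k=5)
        pd.testing.assert_frame_equal(prof.edited_freq, prof2.edited_freq)
        pd.testing.assert_frame_equal(prof.background_freq, prof2.background_freq)


class TestDistributions:
    def test_region_fractions(self):
        sites = pd.DataFrame({"region": ["intronic", "exonic"], "chrom": "chr1", "pos": [1, 2]})
        out = region_distribution(sites)
        assert out.loc["intronic", "fraction"] == 0.5
        assert out.loc["exonic", "fraction"] == 0.5
        assert out["fraction"].sum() == pytest.approx(1.0)

    def test_region_empty(self):
        out = region_distribution(pd.DataFrame({"region": [], "chrom": [], "pos": []}))
        assert (out["count"] == 0).all()

    def test_all_intronic(self):
        sites = pd.DataFrame({"region": ["intronic"] * 5, "chrom": "chr1", "pos": range(5)})
        assert region_distribution(sites).loc["intronic", "fraction"] == 1.0

    def test_chromosome_counts_and_normalizations(self):
        reference = {"chr1": "A" * 2_000_000, "chr2": "A" * 1_000_000}
        sites = pd.DataFrame({"chrom": ["chr1"] * 4 + ["chr2"] * 2, "pos": range(6)})
        out = chromosome_distribution(sites, reference, normalization="per-Mb")
        assert out.loc["chr1", "count"] == 4
        assert out.loc["chr1", "per_mb"] == pytest.approx(2.0)
        assert out.loc["chr2", "per_mb"] == pytest.approx(2.0)

    def test_unknown_contig_is_error(self):
        sites = pd.DataFrame({"chrom": ["chrX"], "pos": [1]})
        with pytest.raises(ValueError, match="chrX"):
            chromosome_distribution(sites, {"chr1": "AAA"})

    def test_empty_sites_zero_counts(self):
        out = chromosome_distribution(pd.DataFrame({"chrom": [], "pos": []}), {"chr1": "AAA"})
        assert out.loc["chr1", "count"] == 0


class TestRepeats:
    def test_half_in_half_out(self):
        repeats = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        sites = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [50, 500]})
        out = repeat_overlap(sites, repeats)
        assert out.loc["all", "fraction_in_repeats"] == 0.5

    def test_no_repeat_file_skips(self):
        assert repeat_overlap(pd.DataFrame({"chrom": [], "pos": []}), None) is None

    def test_planted_repeat_fraction_recovered(self, default_sim):
        out = repeat_overlap(default_sim.sites, default_sim.repeats)
        expected = default_sim.sites.in_repeat.mean()
        assert out.loc["all", "fraction_in_repeats"] == pytest.approx(expected)
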