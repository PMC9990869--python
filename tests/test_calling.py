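"""Candidate calling, filter cascade, strand resolution and sample merge."""

import numpy as np
import pandas as pd
import pytest

from editscan.calling import (
    ALL_STATUSES,
    PASSED,
    Thresholds,
    apply_filters,
    call_candidates,
    call_sample,
    flag_summary,
    merge_samples,
    resolve_strand,
)
from editscan.errors import IntegrityError
from editscan.io import SiteCountsTable, SnpMask


def _table(rows, assay="RNA", sample_id="s1"):
    """rows: (chrom, pos, ref, depth, quality, (a,c,g,t))"""
    df = pd.DataFrame(
        {
            "chrom": [r[0] for r in rows],
            "pos": [r[1] for r in rows],
            "ref": [r[2] for r in rows],
            "strand": "unknown",
            "depth": [r[3] for r in rows],
            "mean_quality": [float(r[4]) for r in rows],
            "n_a": [r[5][0] for r in rows],
            "n_c": [r[5][1] for r in rows],
            "n_g": [r[5][2] for r in rows],
            "n_t": [r[5][3] for r in rows],
        }
    )
    return SiteCountsTable(sample_id, assay, df)


class TestCandidates:
    def test_simple_candidate_with_level(self):
        rna = _table([("chr1", 100, "A", 50, 35, (45, 0, 5, 0))])
        dna = _table([("chr1", 100, "A", 60, 35, (60, 0, 0, 0))], assay="DNA")
        cand = call_candidates(rna, dna)
        assert len(cand) == 1
        row = cand.iloc[0]
        assert row.alt == "G" and row.level == pytest.approx(0.1)
        assert row.dna_alt_count == 0

    def test_heterozygous_dna_flagged_later(self):
        rna = _table([("chr1", 100, "A", 50, 35, (45, 0, 5, 0))])
        dna = _table([("chr1", 100, "A", 60, 35, (30, 0, 30, 0))], assay="DNA")
        out = apply_filters(call_candidates(rna, dna))
        assert out.iloc[0].status == "dna_variant_removed"

    def test_no_mismatch_is_not_a_candidate(self):
        rna = _table([("chr1", 100, "A", 50, 35, (50, 0, 0, 0))])
        dna = _table([("chr1", 100, "A", 60, 35, (60, 0, 0, 0))], assay="DNA")
        assert len(call_candidates(rna, dna)) == 0

    def test_missing_dna_row_excluded_as_no_dna_evidence(self):
        rna = _table([("chr1", 100, "A", 50, 35, (45, 0, 5, 0))])
        dna = _table([("chr1", 999, "A", 60, 35, (60, 0, 0, 0))], assay="DNA")
        cand = call_candidates(rna, dna)
        assert cand.iloc[0].status == "no_dna_evidence"
        out = apply_filters(cand)
        assert out.iloc[0].status == "no_dna_evidence"  # flag preserved


DNA_REF = [("chr1", 100, "A", 60, 35, (60, 0, 0, 0))]


class TestFilterCascade:
    @pytest.mark.parametrize(
        "rna_row, expected",
        [
            (("chr1", 100, "A", 9, 35, (5, 0, 4, 0)), "low_depth_removed"),
            (("chr1", 100, "A", 50, 29.0, (45, 0, 5, 0)), "low_quality_removed"),
            (("chr1", 100, "A", 50, 35, (40, 5, 5, 0)), "multi_allelic_removed"),
            (("chr1", 100, "A", 20, 35, (0, 0, 20, 0)), "level_out_of_range_removed"),
            (("chr1", 100, "A", 50, 35, (46, 0, 4, 0)), "level_out_of_range_removed"),
            (("chr1", 100, "A", 50, 35, (45, 0, 5, 0)), PASSED),
            (("chr1", 100, "A", 50, 35, (45, 1, 5, 0)), PASSED),  # 1 stray read tolerated
        ],
    )
    def test_first_failing_flag(self, rna_row, expected):
        rna = _table([rna_row])
        dna = _table(DNA_REF, assay="DNA")
        out = apply_filters(call_candidates(rna, dna))
        assert out.iloc[0].status == expected

    def test_snp_removed(self):
        rna = _table([("chr1", 100, "A", 50, 35, (45, 0, 5, 0))])
        dna = _table(DNA_REF, assay="DNA")
        out = apply_filters(call_candidates(rna, dna), snp_mask=SnpMask({("chr1", 100)}))
        assert out.iloc[0].status == "snp_removed"

    def test_order_low_depth_beats_level(self):
        """depth 9 and level 0.5: depth is checked first."""
        rna = _table([("chr1", 100, "A", 9, 35, (4, 0, 5, 0))])
        dna = _table(DNA_REF, assay="DNA")
        out = apply_filters(call_candidates(rna, dna))
        assert out.iloc[0].status == "low_depth_removed"

    def test_statuses_partition_candidates(self, default_sim):
        sample_id = "T01"
        cand = call_candidates(default_sim.rna[sample_id], default_sim.dna[sample_id])
        out = apply_filters(cand, default_sim.snp_mask)
        counts = flag_summary(out)
        assert counts.sum() == len(cand)
        assert set(out.status) <= set(ALL_STATUSES)

    @pytest.mark.parametrize("param, stricter", [("min_depth", 20), ("min_base_quality", 35.0)])
    def test_raising_thresholds_never_gains_sites(self, default_sim, param, stricter):
        sample_id = "T01"
        cand = call_candidates(default_sim.rna[sample_id], default_sim.dna[sample_id])
        base = apply_filters(cand, default_sim.snp_mask, Thresholds())
        strict = apply_filters(cand, default_sim.snp_mask, Thresholds(**{param: stricter}))
        base_pass = set(base.loc[base.status == PASSED, "pos"])
        strict_pass = set(strict.loc[strict.status == PASSED, "pos"])
        assert strict_pass <= base_pass


class TestStrandResolution:
    @pytest.fixture()
    def annotation(self, tmp_path):
        from editscan.io import read_annotation

        path = tmp_path / "a.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\ts\tgene\t1\t200\t.\t+\t.\tID=GP\n"
            "chr1\ts\tmRNA\t1\t200\t.\t+\t.\tID=GP.t;Parent=GP\n"
            "chr1\ts\texon\t1\t200\t.\t+\t.\tID=GP.e;Parent=GP.t\n"
            "chr1\ts\tgene\t301\t500\t.\t-\t.\tID=GM\n"
            "chr1\ts\tmRNA\t301\t500\t.\t-\t.\tID=GM.t;Parent=GM\n"
            "chr1\ts\texon\t301\t500\t.\t-\t.\tID=GM.e;Parent=GM.t\n"
        )
        return read_annotation(path)

    def test_minus_strand_complements_mismatch(self, annotation):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [400], "ref": ["T"], "alt": ["C"]})
        out = resolve_strand(sites, annotation)
        assert out.iloc[0].edit_type == "A>G" and out.iloc[0].strand == "-"

    def test_plus_strand_keeps_raw_type(self, annotation):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "ref": ["A"], "alt": ["G"]})
        out = resolve_strand(sites, annotation)
        assert out.iloc[0].edit_type == "A>G" and out.iloc[0].strand == "+"

    def test_intergenic_stays_unknown(self, annotation):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [250], "ref": ["A"], "alt": ["G"]})
        out = resolve_strand(sites, annotation)
        assert out.iloc[0].strand == "unknown" and out.iloc[0].edit_type == "A>G"


def _passing_frame(sample_id, positions):
    n = len(positions)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": "chr1",
            "pos": positions,
            "ref": "A",
            "alt": "G",
            "strand": "+",
            "edit_type": "A>G",
            "gene_id": "G001",
            "region": "intronic",
            "rna_depth": 50,
            "rna_quality": 36.0,
            "rna_ref_count": 40,
            "rna_alt_count": 10,
            "second_allele_count": 0,
            "level": 0.2,
            "dna_depth": 50,
            "dna_alt_count": 0.0,
            "status": [PASSED] * n,
        }
    )


def _samples(n_t, n_n):
    ids = [f"T{i+1:02d}" for i in range(n_t)] + [f"N{i+1:02d}" for i in range(n_n)]
    return pd.DataFrame(
        {
            "condition": ["tumor"] * n_t + ["normal"] * n_n,
            "pair_id": [f"P{i+1:02d}" for i in range(n_t)] + [f"P{i+1:02d}" for i in range(n_n)],
        },
        index=pd.Index(ids, name="sample_id"),
    )


class TestMerge:
    def test_condition_coverage_counts(self):
        samples = _samples(4, 4)
        per_sample = {s: _passing_frame(s, [100]) for s in ["T01", "T02", "T03"]}
        per_sample.update({s: _passing_frame(s, []) for s in ["T04", "N01", "N02", "N03", "N04"]})
        m = merge_samples(per_sample, samples)
        cov = m.sample_coverage()
        assert cov.loc["chr1:100", "tumor"] == 3 and cov.loc["chr1:100", "normal"] == 0

    def test_disjoint_sites_give_missing_cells(self):
        samples = _samples(1, 1)
        m = merge_samples(
            {"T01": _passing_frame("T01", [100]), "N01": _passing_frame("N01", [200])}, samples
        )
        assert np.isnan(m.level.loc["chr1:100", "N01"]) and np.isnan(m.level.loc["chr1:200", "T01"])

    def test_empty_input_empty_matrix(self):
        m = merge_samples({}, _samples(1, 1))
        assert len(m) == 0 and m.level.shape == (0, 2)

    def test_duplicate_site_in_sample_rejected(self):
        samples = _samples(1, 1)
        with pytest.raises(IntegrityError, match="duplicate"):
            merge_samples({"T01": _passing_frame("T01", [100, 100])}, samples)


class TestRecoveryOnSimulation:
    def test_a_to_g_dominance(self, default_matrix):
        assert (default_matrix.sites.edit_type == "A>G").mean() > 0.9

    def test_full_call_matches_pipeline_components(self, default_sim):
        out = call_sample(
            default_sim.rna["N01"], default_sim.dna["N01"], default_sim.snp_mask,
            default_sim.annotation,
        )
        assert (out.columns[:2] == ["sample_id", "chrom"]).all()
        assert (out.status == PASSED).sum() > 0
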