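"""eDRE/sDRE intersections, DEG stand-in, structure-pair extraction."""

import numpy as np
import pandas as pd
import pytest
from helpers import toy_matrix

from editscan.adar import ExpressionMatrix
from editscan.integrate import (
    delta_mfe_report,
    editing_expression_correlation,
    event_span,
    extract_structure_pairs,
    intersect_expression,
    intersect_splicing,
    paired_log2fc_deg,
    write_structure_pairs,
)


def _dre_table(genes, positions=None, chrom="chr1"):
    n = len(genes)
    positions = positions or [1000 + 10 * i for i in range(n)]
    idx = [f"{chrom}:{p}" for p in positions]
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "G",
            "strand": "+",
            "gene_id": genes,
            "group": ["tumor_specific"] * n,
            "is_dre": True,
        },
        index=pd.Index(idx, name="site_id"),
    )


def _deg_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj"]).set_index("gene_id")


class TestExpressionIntersection:
    def test_direct_join(self):
        dre = _dre_table(["GA", "GB"])
        deg = _deg_table([("GA", 2.0, 0.001), ("GC", -3.0, 0.001)])
        res = intersect_expression(dre, deg)
        assert list(res["edre"]["gene_id"]) == ["GA"]
        assert res["eddeg_genes"] == ["GA"]
        assert res["by_group"].loc["tumor_specific", "n_genes"] == 1

    def test_gene_absent_from_deg_is_not_edre(self):
        dre = _dre_table(["GA"])
        deg = _deg_table([("GA", 0.5, 0.001)])  # below fold-change threshold
        assert len(intersect_expression(dre, deg)["edre"]) == 0

    def test_namespace_mismatch_raises(self):
        dre = _dre_table(["GA", "GB"])
        deg = _deg_table([("ENSG000001", 2.0, 0.001)])
        with pytest.raises(ValueError, match="GA"):
            intersect_expression(dre, deg)

    def test_planted_overlap_genes_recovered_exactly(self, default_sim, default_results):
        truth_genes = set(default_sim.de_truth.gene_id) & set(default_sim.sites.gene_id)
        assert len(truth_genes) == default_sim.cfg.n_de_genes
        assert set(default_results["edre"]["eddeg_genes"]) == truth_genes

    def test_rejoin_soundness(self, default_results):
        """eDRE output equals an independent re-join of the two input tables."""
        dre = default_results["dre_table"]
        deg = default_results["deg_table"]
        sig = deg[(deg.log2fc.abs() >= 1) & (deg.padj < 0.05)]
        expected = {
            i for i, row in dre.iterrows()
            if row["is_dre"] and row["gene_id"] and row["gene_id"] in sig.index
        }
        assert set(default_results["edre"]["edre"].index) == expected


class TestDegStandIn:
    def test_recovers_planted_de_genes(self, default_sim, default_results):
        deg = default_results["deg_table"]
        called = set(deg[(deg.log2fc.abs() >= 1) & (deg.padj < 0.05)].index)
        assert called == set(default_sim.de_truth.gene_id)

    def test_sign_matches_planted_direction(self, default_sim, default_results):
        deg = default_results["deg_table"]
        for row in default_sim.de_truth.itertuples():
            assert np.sign(deg.loc[row.gene_id, "log2fc"]) == np.sign(row.log2fc)


def _event(chrom="chr1", etype="SE", up_es=900, down_ee=1500, exon=(1100, 1200)):
    return pd.DataFrame(
        [
            {
                "event_id": "EV1",
                "gene_id": "GA",
                "chrom": chrom,
                "strand": "+",
                "event_type": etype,
                "exon_start": exon[0],
                "exon_end": exon[1],
                "upstream_es": up_es,
                "upstream_ee": up_es + 50,
                "downstream_es": down_ee - 50,
                "downstream_ee": down_ee,
                "inc_level_difference": 0.3,
                "pvalue": 1e-4,
            }
        ]
    )


class TestSplicingIntersection:
    def test_dre_in_upstream_intron_is_sdre(self):
        dre = _dre_table(["GA"], positions=[1001])  # inside [900, 1500)
        res = intersect_splicing(dre, _event())
        assert len(res["sdre"]) == 1 and res["sdre"].iloc[0].event_type == "SE"
        assert res["fraction_events_with_dre"] == 1.0

    def test_one_bp_outside_span_is_not_sdre(self):
        res_out = intersect_splicing(_dre_table(["GA"], positions=[1501]), _event())
        assert len(res_out["sdre"]) == 0
        # last position inside the half-open span
        res_in = intersect_splicing(_dre_table(["GA"], positions=[1500]), _event())
        assert len(res_in["sdre"]) == 1

    def test_ri_span_is_the_retained_block(self):
        ev = _event(etype="RI", exon=(1100, 1200)).iloc[0]
        assert event_span(ev) == (1100, 1200)

    def test_unknown_event_type_raises(self):
        ev = _event()
        ev.loc[0, "event_type"] = "XX"
        with pytest.raises(ValueError, match="XX"):
            intersect_splicing(_dre_table(["GA"]), ev)

    def test_planted_overlap_fraction_recovered(self, default_sim, default_results):
        planted = default_sim.splicing_events["contains_planted_site"].mean()
        observed = default_results["sdre"]["fraction_events_with_dre"]
        assert observed == pytest.approx(planted, abs=0.02)

    def test_rejoin_soundness(self, default_results, default_sim):
        """Every sDRE row traces to exactly one DRE and one event row."""
        sdre = default_results["sdre"]["sdre"]
        dre = default_results["dre_table"]
        events = default_sim.splicing_events.set_index("event_id")
        dres = dre[dre["is_dre"]]
        for row in sdre.itertuples():
            assert row.site_id in dres.index
            ev = events.loc[row.event_id]
            start, end = event_span(ev)
            pos0 = dres.loc[row.site_id, "pos"] - 1
            assert ev.chrom == dres.loc[row.site_id, "chrom"]
            assert start <= pos0 < end


class TestStructurePairs:
    REF = {"chr1": "ACGTAAGTACGTTTTT"}

    def test_plus_strand_pair_differs_only_at_center(self):
        site = {"chrom": "chr1", "pos": 6, "strand": "+"}
        unedited, edited = extract_structure_pairs(site, self.REF, window=5)
        assert len(unedited) == len(edited) == 11
        diff = [i for i, (a, b) in enumerate(zip(unedited.seq, edited.seq)) if a != b]
        assert diff == [5]
        assert unedited.seq[5] == "A" and edited.seq[5] == "G"

    def test_minus_strand_reverse_complement(self):
        site = {"chrom": "chr1", "pos": 8, "strand": "-"}  # plus-strand T
        unedited, edited = extract_structure_pairs(site, self.REF, window=3)
        assert str(unedited.seq) == "CGTACTT"  # revcomp of plus-strand AAGTACG
        assert str(edited.seq)[3] == "G"

    def test_clipped_at_contig_edge(self):
        site = {"chrom": "chr1", "pos": 5, "strand": "+"}
        unedited, edited = extract_structure_pairs(site, self.REF, window=250)
        assert len(unedited) == len(edited) == len(self.REF["chr1"])

    def test_non_adenosine_center_rejected(self):
        with pytest.raises(ValueError, match="expected A"):
            extract_structure_pairs({"chrom": "chr1", "pos": 2, "strand": "+"}, self.REF)

    def test_hamming_distance_exactly_one_for_all_sites(self, default_sim, tmp_path):
        sites = default_sim.sites[default_sim.sites.gene_id != ""].head(30)
        n = write_structure_pairs(sites, default_sim.reference, tmp_path / "pairs.fa", window=50)
        from Bio import SeqIO

        records = list(SeqIO.parse(str(tmp_path / "pairs.fa"), "fasta"))
        assert len(records) == 2 * n
        for un, ed in zip(records[::2], records[1::2]):
            assert sum(a != b for a, b in zip(un.seq, ed.seq)) == 1


class TestCorrelationAndMfe:
    def test_editing_expression_correlation_signs(self):
        m = toy_matrix(np.linspace(0.1, 0.45, 5).reshape(1, -1), np.linspace(0.5, 0.9, 5).reshape(1, -1))
        expr = ExpressionMatrix(
            pd.DataFrame(
                {s: [v] for s, v in zip(m.samples.index, np.linspace(100, 10, 10))},
                index=pd.Index(["G001"], name="gene_id"),
            ),
            m.samples,
        )
        out = editing_expression_correlation(m, expr, m.sites.index[0], min_obs=5)
        assert out["rho"] == pytest.approx(-1.0)

    def test_degenerate_inputs_return_none(self):
        m = toy_matrix(np.full((1, 3), 0.3), np.full((1, 3), 0.3))
        expr = ExpressionMatrix(
            pd.DataFrame({s: [5.0] for s in m.samples.index}, index=pd.Index(["G001"], name="gene_id")),
            m.samples,
        )
        assert editing_expression_correlation(m, expr, m.sites.index[0], min_obs=5) is None
        # n = 2 refused
        m2 = toy_matrix(np.array([[0.2]]), np.array([[0.4]]))
        expr2 = ExpressionMatrix(
            pd.DataFrame({s: [5.0] for s in m2.samples.index}, index=pd.Index(["G001"], name="gene_id")),
            m2.samples,
        )
        assert editing_expression_correlation(m2, expr2, m2.sites.index[0]) is None

    def test_delta_mfe_fraction(self):
        table = pd.DataFrame(
            {
                "site_id": ["s1", "s2", "s3", "s4"],
                "mfe_unedited": [-10.0, -10.0, -10.0, -10.0],
                "mfe_edited": [-14.0, -10.2, -8.0, -10.0],
            }
        )
        out = delta_mfe_report(table, threshold=1.0)
        assert out["fraction_above_threshold"] == pytest.approx(0.5)
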