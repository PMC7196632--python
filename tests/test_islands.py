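"""PII-nadE island pipeline: filters, boundaries, and end-to-end recovery."""

import numpy as np
import pandas as pd
import pytest

from nadhub import islands as isl
from nadhub import simulate as sim


def _meta(acc, species, level="complete", category="na"):
    return {"assembly_accession": acc, "taxid": 1, "species_taxid": species,
            "assembly_level": level, "refseq_category": category,
            "organism_name": acc}


def _hit(pid, start, end, evalue=1e-40, genome="G1", contig="c1"):
    return {"query_id": "q", "genome": genome, "contig_id": contig,
            "start": start, "end": end, "strand": "+", "evalue": evalue,
            "bitscore": 100.0, "subject_protein_id": pid}


CONTIGS = pd.DataFrame([{"genome": "G1", "contig_id": "c1", "length": 40_000}])


class TestDedupeGenomes:
    def test_type_strain_wins(self):
        metas = pd.DataFrame([
            _meta("GCF_B", 7, "complete", "na"),
            _meta("GCF_A", 7, "scaffold", "type strain"),
        ])
        out = isl.dedupe_genomes(metas)
        assert list(out["assembly_accession"]) == ["GCF_A"]

    def test_one_per_species_is_identity(self):
        metas = pd.DataFrame([_meta("GCF_A", 1), _meta("GCF_B", 2)])
        out = isl.dedupe_genomes(metas)
        assert sorted(out["assembly_accession"]) == ["GCF_A", "GCF_B"]

    def test_level_priority_then_accession_tiebreak(self):
        metas = pd.DataFrame([
            _meta("GCF_C", 7, "scaffold"),
            _meta("GCF_B", 7, "scaffold"),
            _meta("GCF_A", 7, "scaffold"),
        ])
        assert list(isl.dedupe_genomes(metas)["assembly_accession"]) == ["GCF_A"]
        metas2 = pd.DataFrame([
            _meta("GCF_Z", 7, "complete"),
            _meta("GCF_A", 7, "contig"),
        ])
        assert list(isl.dedupe_genomes(metas2)["assembly_accession"]) == ["GCF_Z"]


class TestCallIslands:
    def test_window_arithmetic(self):
        hits = pd.DataFrame([_hit("p1", 15_000, 15_300)])
        out = isl.call_islands(hits, CONTIGS)
        assert out.iloc[0]["window_start"] == 5_000
        assert out.iloc[0]["window_end"] == 25_300

    def test_truncated_window_discarded(self):
        hits = pd.DataFrame([_hit("p1", 4_000, 4_300)])
        assert isl.call_islands(hits, CONTIGS).empty

    def test_evalue_boundary_inclusive(self):
        hits = pd.DataFrame([_hit("p1", 15_000, 15_300, evalue=1e-5),
                             _hit("p2", 16_000, 16_300, evalue=1.0001e-5)])
        out = isl.call_islands(hits, CONTIGS)
        assert list(out["pii_protein_id"]) == ["p1"]

    def test_unknown_contig_raises(self):
        hits = pd.DataFrame([_hit("p1", 15_000, 15_300, contig="nope")])
        with pytest.raises(KeyError):
            isl.call_islands(hits, CONTIGS)

    def test_flank_shrink_monotone(self):
        hits = pd.DataFrame([_hit("p1", 15_000, 15_300),
                             _hit("p2", 9_000, 9_300)])
        wide = isl.call_islands(hits, CONTIGS, flank=10_000)
        narrow = isl.call_islands(hits, CONTIGS, flank=8_000)
        assert set(wide["pii_protein_id"]) <= set(narrow["pii_protein_id"])


class TestPairing:
    ISLANDS = isl.call_islands(pd.DataFrame([_hit("pii1", 19_830, 20_170)]),
                               CONTIGS)  # PII midpoint at 20,000

    def _pair(self, nade_mid, evalue=1e-40, length=2000):
        start = nade_mid - length // 2
        hits = pd.DataFrame([_hit("n1", start, start + length, evalue=evalue)])
        return isl.pair_nade_with_pii(hits, self.ISLANDS)

    def test_distance_1999_kept(self):
        out = self._pair(20_000 - 1_999)
        assert len(out) == 1
        assert out.iloc[0]["midpoint_distance"] == 1_999

    def test_distance_2000_discarded_strict(self):
        assert self._pair(20_000 + 2_000).empty

    def test_overlapping_midpoints_distance_zero(self):
        out = self._pair(20_000)
        assert out.iloc[0]["midpoint_distance"] == 0

    def test_weak_evalue_discarded(self):
        assert self._pair(20_000, evalue=1e-4).empty

    def test_outside_island_discarded(self):
        hits = pd.DataFrame([_hit("n1", 35_000, 37_000)])
        assert isl.pair_nade_with_pii(hits, self.ISLANDS).empty

    def test_equidistant_tie_to_lower_coordinate(self):
        islands = isl.call_islands(pd.DataFrame([
            _hit("piiA", 14_830, 15_170),   # midpoint 15,000
            _hit("piiB", 16_830, 17_170),   # midpoint 17,000
        ]), CONTIGS)
        hits = pd.DataFrame([_hit("n1", 15_000, 16_999)])  # midpoint 15,999... 16,000
        out = isl.pair_nade_with_pii(hits, islands)
        # nadE midpoint 15999 -> distances 999 and 1001; closest is piiA
        assert out.iloc[0]["pii_protein_id"] == "piiA"
        hits2 = pd.DataFrame([_hit("n2", 15_001, 17_000)])  # midpoint 16,000
        out2 = isl.pair_nade_with_pii(hits2, islands)
        assert out2.iloc[0]["pii_protein_id"] == "piiA"  # tie -> lower coord


class TestDereplicate:
    PAIRS = pd.DataFrame([
        {"genome": "G1", "contig_id": "c1", "nade_protein_id": "n1",
         "nade_start": 100, "nade_end": 200, "nade_midpoint": 150,
         "pii_protein_id": "p1", "pii_midpoint": 300, "midpoint_distance": 150,
         "nade_evalue": 1e-40},
        {"genome": "G2", "contig_id": "c1", "nade_protein_id": "n2",
         "nade_start": 100, "nade_end": 200, "nade_midpoint": 150,
         "pii_protein_id": "p2", "pii_midpoint": 300, "midpoint_distance": 150,
         "nade_evalue": 1e-40},
    ])

    def test_identical_sequences_collapse(self):
        seqs = {"n1": "MKV", "n2": "MKV"}
        out = isl.dereplicate(self.PAIRS, sequences=seqs)
        assert len(out) == 1
        assert out.iloc[0]["nade_protein_id"] == "n1"  # canonical order kept

    def test_all_unique_identity(self):
        seqs = {"n1": "MKV", "n2": "MKW"}
        assert len(isl.dereplicate(self.PAIRS, sequences=seqs)) == 2

    def test_duplicate_ids_without_sequences(self):
        pairs = self.PAIRS.copy()
        pairs.loc[1, "nade_protein_id"] = "n1"
        out = isl.dereplicate(pairs)
        assert len(out) == 1


class TestTaxonomyRollup:
    def test_counts_and_unclassified(self):
        pairs = pd.DataFrame({"genome": ["G1", "G2", "G3"]})
        lineages = pd.DataFrame([
            {"taxid": 10, "phylum": "Proteobacteria", "class": "Betaproteobacteria"},
            {"taxid": 11, "phylum": "Proteobacteria", "class": "Betaproteobacteria"},
        ])
        rollup = isl.taxonomy_rollup(pairs, lineages,
                                     {"G1": 10, "G2": 11, "G3": 99})
        classes = dict(zip(rollup["class"]["class"], rollup["class"]["count"]))
        assert classes == {"Betaproteobacteria": 2, "unclassified": 1}
        assert rollup["class"]["count"].sum() == len(pairs)


class TestPipelineEndToEnd:
    def test_recall_and_precision_are_one(self, genome_set):
        gs = genome_set
        res = isl.run_pipeline(gs.metas, gs.contigs, gs.pii_hits, gs.nade_hits,
                               lineages=gs.lineages,
                               genome_taxids=gs.genome_taxids)
        found = set(res.pairs["nade_protein_id"])
        expected = {e["nade_protein_id"]
                    for e in gs.truth.params["expected_pairs"]}
        assert found == expected
        assert np.all(res.pairs["midpoint_distance"] < 2000)

    def test_rollup_matches_generator_truth(self, genome_set):
        gs = genome_set
        res = isl.run_pipeline(gs.metas, gs.contigs, gs.pii_hits, gs.nade_hits,
                               lineages=gs.lineages,
                               genome_taxids=gs.genome_taxids)
        got = dict(zip(res.rollup["class"]["class"], res.rollup["class"]["count"]))
        got.pop("unclassified", None)
        assert got == gs.truth.params["class_counts"]

    def test_order_independence(self, genome_set):
        gs = genome_set
        shuffled = gs.nade_hits.sample(frac=1.0, random_state=0)
        a = isl.run_pipeline(gs.metas, gs.contigs, gs.pii_hits, gs.nade_hits)
        b = isl.run_pipeline(gs.metas, gs.contigs, gs.pii_hits, shuffled)
        pd.testing.assert_frame_equal(a.pairs.reset_index(drop=True),
                                      b.pairs.reset_index(drop=True))


class TestOutfmt6Reader:
    def test_minus_strand_and_coordinates(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q1\tc1\t95.0\t100\t5\t0\t1\t100\t500\t201\t1e-30\t180\n")
        df = isl.read_hits_outfmt6(path, {"c1": "G1"})
        row = df.iloc[0]
        assert (row["start"], row["end"], row["strand"]) == (201, 500, "-")
        assert row["genome"] == "G1"
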