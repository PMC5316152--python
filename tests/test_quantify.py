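"""Read-position assignment and region counting."""

import numpy as np
import pandas as pd
import pytest

from helpers import brute_count
from ribotrans.errors import InputError, ParameterError
from ribotrans.io import read_bed6, write_bed6
from ribotrans.models import GeneModel
from ribotrans.quantify import (
    AlignmentRecord,
    assign_position,
    build_count_table,
    count_gene,
    count_library,
)

ALL_LIBS = [(c, a) for c in ("SD", "MetR") for a in ("mRNA", "footprint")]


class TestAssignPosition:
    @pytest.mark.parametrize(
        "strand,start,end,assay,offset,expected",
        [
            ("+", 100, 128, "footprint", 15, 115),
            ("-", 100, 128, "footprint", 15, 112),
            ("+", 100, 150, "mRNA", 15, 100),
            ("-", 100, 150, "mRNA", 15, 149),
            ("+", 100, 128, "footprint", 0, 100),
        ],
    )
    def test_assignment_convention(self, strand, start, end, assay, offset, expected):
        read = AlignmentRecord("chrT", start, end, strand)
        assert assign_position(read, assay, offset) == expected

    def test_offset_beyond_read_length_rejected(self):
        read = AlignmentRecord("chrT", 100, 128, "+")
        with pytest.raises(ParameterError):
            assign_position(read, "footprint", offset=28)


class TestCountGene:
    def test_cds_hit_downstream_of_exclusion(self):
        model = GeneModel("g", "chrT", "+", 0, 60, 300, 360)
        read = AlignmentRecord("chrT", 55, 83, "+", weight=2)  # footprint P-site 70
        assert count_gene([read], model, "footprint") == (2, 0, 0)

    def test_position_inside_tss_window_not_counted(self):
        model = GeneModel("g", "chrT", "+", 0, 21, 300, 360)
        read = AlignmentRecord("chrT", 15, 43, "+")  # P-site 30 < 50 nt from TSS
        assert count_gene([read], model, "footprint") == (0, 0, 0)

    def test_utr5_counting_ignores_exclusion_window(self):
        model = GeneModel("g", "chrT", "+", 0, 60, 300, 360)
        read = AlignmentRecord("chrT", 15, 43, "+")  # P-site 30, in 5'UTR, < 50 from TSS
        assert count_gene([read], model, "footprint") == (0, 1, 0)

    def test_wrong_strand_reads_ignored(self):
        model = GeneModel("g", "chrT", "+", 0, 60, 300, 360)
        read = AlignmentRecord("chrT", 100, 128, "-")
        assert count_gene([read], model, "footprint") == (0, 0, 0)


class TestCountLibrary:
    def test_matches_brute_force_on_synthetic_reads(self, mixed_strand_dataset):
        data = mixed_strand_dataset
        bed = data.beds[("MetR", "footprint")]
        counts, _ = count_library(bed, data.genome.models, "footprint")
        for model in data.genome.models[::7]:  # spot-check a spread of genes
            assert tuple(counts.loc[model.gene_id]) == brute_count(bed, model, "footprint")

    def test_row_order_is_immaterial(self, mixed_strand_dataset):
        data = mixed_strand_dataset
        bed = data.beds[("SD", "mRNA")]
        shuffled = bed.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a, _ = count_library(bed, data.genome.models, "mRNA")
        b, _ = count_library(shuffled, data.genome.models, "mRNA")
        pd.testing.assert_frame_equal(a, b)

    def test_zero_offset_footprint_equals_mrna(self, mixed_strand_dataset):
        data = mixed_strand_dataset
        bed = data.beds[("SD", "footprint")]
        a, _ = count_library(bed, data.genome.models, "footprint", offset=0)
        b, _ = count_library(bed, data.genome.models, "mRNA")
        pd.testing.assert_frame_equal(a, b)

    def test_mirroring_coordinates_preserves_counts(self):
        """Reflecting the locus and flipping strands must not change counts."""
        model = GeneModel("g", "chrT", "+", 100, 160, 460, 560)
        rng = np.random.default_rng(5)
        starts = rng.integers(80, 560, 300)
        bed = pd.DataFrame(
            {"chrom": "chrT", "start": starts, "end": starts + 28,
             "name": "g", "score": 1, "strand": "+"}
        )
        L = 1000  # reflection pivot
        mirrored_model = GeneModel("g", "chrT", "-", L - 100, L - 160, L - 460, L - 560)
        mirrored = bed.copy()
        mirrored["start"] = L - bed["end"]
        mirrored["end"] = L - bed["start"]
        mirrored["strand"] = "-"
        a, _ = count_library(bed, [model], "footprint")
        b, _ = count_library(mirrored, [mirrored_model], "footprint")
        pd.testing.assert_frame_equal(a, b)

    def test_ambiguous_positions_assigned_to_neither_gene(self):
        g1 = GeneModel("g1", "chrT", "+", 100, 160, 460, 500)
        g2 = GeneModel("g2", "chrT", "+", 450, 480, 780, 800)  # overlaps g1's tail
        bed = pd.DataFrame(
            {"chrom": "chrT", "start": [470, 200], "end": [520, 250],
             "name": "r", "score": [3, 1], "strand": "+"}
        )
        counts, diag = count_library(bed, [g1, g2], "mRNA")
        assert diag["ambiguous"] == 3
        assert counts.loc["g1", "cds_count"] == 1
        assert counts["utr3_count"].sum() == 0 and counts.loc["g2"].sum() == 0


class TestBuildCountTable:
    def test_empty_beds_are_degenerate(self, mixed_strand_dataset):
        empty = pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"]).astype(
            {"start": "int64", "end": "int64", "score": "int64"}
        )
        table = build_count_table({k: empty for k in ALL_LIBS}, mixed_strand_dataset.genome.models)
        assert table.is_degenerate()
        assert (table.counts[["cds_count", "utr5_count", "utr3_count"]] == 0).all().all()

    def test_matches_generator_tallies(self, mixed_strand_dataset):
        data = mixed_strand_dataset
        table = build_count_table(data.beds, data.genome.models)
        key = ["gene_id", "condition", "assay"]
        a = data.counts.counts.sort_values(key, ignore_index=True)
        b = table.counts.sort_values(key, ignore_index=True)
        pd.testing.assert_frame_equal(a, b)
        assert table.library_totals == data.counts.library_totals

    def test_missing_library_rejected(self, mixed_strand_dataset):
        beds = dict(mixed_strand_dataset.beds)
        del beds[("SD", "mRNA")]
        with pytest.raises(ParameterError):
            build_count_table(beds, mixed_strand_dataset.genome.models)

    def test_count_table_roundtrips_through_tsv(self, tmp_path, mixed_strand_dataset):
        from ribotrans.quantify import CountTable

        table = build_count_table(mixed_strand_dataset.beds, mixed_strand_dataset.genome.models)
        path = tmp_path / "counts.tsv"
        table.to_tsv(path)
        back = CountTable.from_tsv(path)
        pd.testing.assert_frame_equal(table.counts, back.counts)
        assert table.library_totals == back.library_totals


class TestBedIO:
    def test_malformed_line_reported_with_location(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chrT\t10\t38\tr1\t1\t+\nchrT\t50\t40\tr2\t1\t+\n")
        with pytest.raises(InputError, match="line 2"):
            read_bed6(path)

    def test_roundtrip(self, tmp_path, mixed_strand_dataset):
        bed = mixed_strand_dataset.beds[("SD", "footprint")]
        path = tmp_path / "fp.bed"
        write_bed6(bed, path)
        back = read_bed6(path)
        pd.testing.assert_frame_equal(bed.reset_index(drop=True), back)
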