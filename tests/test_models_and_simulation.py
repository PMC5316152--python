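"""Gene-model invariants and synthetic-data generator behavior."""

import hashlib
import io

import numpy as np
import pandas as pd
import pytest

from ribotrans.codons import STOP_CODONS
from ribotrans.errors import GenerationError, ModelError, ParameterError
from ribotrans.models import GeneModel, models_to_frame, read_gene_models, write_gene_models
from ribotrans.simulate import (
    EffectConfig,
    LengthParams,
    simulate_dataset,
    simulate_gene_models,
    simulate_reads,
)


class TestGeneModel:
    def test_plus_strand_regions_and_lengths(self, plus_gene):
        assert plus_gene.utr5_len == 60
        assert plus_gene.cds_len == 300
        assert plus_gene.utr3_len == 100
        assert plus_gene.region_of(1000) == "utr5"
        assert plus_gene.region_of(1060) == "cds"
        assert plus_gene.region_of(1360) == "utr3"
        assert plus_gene.region_of(1460) is None
        assert plus_gene.transcript_pos(1060) == 60

    def test_minus_strand_mirrors_plus(self, minus_gene):
        assert minus_gene.utr5_len == 60
        assert minus_gene.cds_len == 300
        assert minus_gene.region_of(1459) == "utr5"
        assert minus_gene.region_of(1399) == "cds"
        assert minus_gene.region_of(1099) == "utr3"
        # 5'-most base of the transcript is genomic tss-1
        assert minus_gene.transcript_pos(1459) == 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(tss=100, cds_start=50, cds_end=350, utr3_end=400),   # disordered
            dict(tss=0, cds_start=60, cds_end=361, utr3_end=400),     # CDS % 3 != 0
        ],
    )
    def test_invalid_coordinates_rejected(self, kwargs):
        with pytest.raises(ModelError):
            GeneModel("bad", "chrT", "+", **kwargs)

    def test_model_table_roundtrip(self, tmp_path, plus_gene, minus_gene):
        path = tmp_path / "models.tsv"
        write_gene_models([plus_gene, minus_gene], path)
        back = read_gene_models(path)
        assert back == [plus_gene, minus_gene]


class TestSimulateGeneModels:
    def test_fixed_lengths_are_honored(self):
        params = LengthParams(utr5_mean=60, utr5_min=60, utr3_mean=20, utr3_min=20,
                              cds_codons_log2_sd=0.0, cds_codons_log2_mean=np.log2(100),
                              cds_codons_min=100)
        genome = simulate_gene_models(1, params, seed=0)
        model = genome.models[0]
        assert model.cds_start - model.tss == 60
        assert model.cds_len == 300

    def test_generated_genes_satisfy_all_invariants(self):
        genome = simulate_gene_models(500, LengthParams(minus_strand_fraction=0.4), seed=9)
        assert len(genome.models) == 500
        spans = sorted(m.span for m in genome.models)
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            assert hi1 <= lo2, "genes must not overlap"
        for model in genome.models:
            # GeneModel construction already enforces ordering and CDS % 3
            assert model.utr5_len >= 0
            assert model.cds_len >= 30
            seq = genome.sequences[model.gene_id]
            assert len(seq) == model.cds_len
            assert seq.startswith("ATG")
            assert seq[-3:] in STOP_CODONS
            internal = {seq[i: i + 3] for i in range(3, len(seq) - 3, 3)}
            assert not (internal & STOP_CODONS), "no internal stop codons"

    def test_same_seed_is_byte_identical(self, tmp_path):
        for name in ("a", "b"):
            simulate_gene_models(60, seed=123).write(tmp_path / name)
        for fname in ("models.tsv", "cds.fasta"):
            a = (tmp_path / "a" / fname).read_bytes()
            b = (tmp_path / "b" / fname).read_bytes()
            assert hashlib.sha256(a).digest() == hashlib.sha256(b).digest()

    def test_bad_parameters_rejected(self):
        with pytest.raises(ParameterError):
            simulate_gene_models(0)
        with pytest.raises(ParameterError):
            simulate_gene_models(10, LengthParams(utr5_mean=-5.0))


class TestSimulateReads:
    def test_null_config_plants_nothing(self):
        cfg = EffectConfig(mean_depth=50, seed=1)
        data = simulate_dataset(30, cfg, emit_reads=False)
        assert (data.truth["true_tx_fc"] == 1).all()
        assert (data.truth["true_te_fc"] == 1).all()
        assert (data.truth["true_class"] == "none").all()
        assert not data.truth["in_kqe_set"].any()

    def test_total_reads_match_expectation(self):
        n_genes, depth = 400, 100
        data = simulate_dataset(n_genes, EffectConfig(mean_depth=depth), seed=8, emit_reads=False)
        expected = n_genes * depth
        for total in data.counts.library_totals.values():
            # NB totals: var per gene = mu + 0.5 mu^1.5; 5 SD band
            sd = np.sqrt(n_genes * (depth + 0.5 * depth**1.5))
            assert abs(total - expected) < 5 * sd

    def test_class_configuration_sets_truth_labels(self):
        cfg = EffectConfig(mean_depth=100, n_class1=4, n_class2=3, n_class3=2, seed=3)
        data = simulate_dataset(60, cfg, LengthParams(utr5_min=25), emit_reads=False)
        counts = data.truth["true_class"].value_counts()
        assert counts.get("class1", 0) == 4
        assert counts.get("class2", 0) == 3
        assert counts.get("class3", 0) == 2
        planted = data.truth[data.truth["true_class"] != "none"]
        assert (planted["true_te_fc"] == cfg.te_effect).all()

    def test_seed_determinism_of_beds_and_truth(self, tmp_path):
        cfg = EffectConfig(mean_depth=80, frac_tx_up=0.1, seed=77)
        hashes = []
        for name in ("x", "y"):
            data = simulate_dataset(40, cfg, seed=77)
            paths = data.write(tmp_path / name)
            digest = hashlib.sha256()
            for path in sorted(p for p in (tmp_path / name).iterdir()):
                digest.update(path.read_bytes())
            hashes.append(digest.hexdigest())
        assert hashes[0] == hashes[1]

    def test_overdispersion_exceeds_poisson(self):
        # index of dispersion across replicate draws of the same gene means
        totals = []
        for seed in range(30):
            data = simulate_dataset(1, EffectConfig(mean_depth=500, dispersion_slope=1.0),
                                    LengthParams(cds_codons_log2_sd=0.0), seed=1000 + seed,
                                    emit_reads=False)
            sub = data.counts.counts
            totals.append(int(sub.loc[(sub.condition == "SD") & (sub.assay == "mRNA"), "cds_count"].iloc[0]))
        totals = np.array(totals)
        assert totals.var(ddof=1) / totals.mean() > 1.5

    def test_overlapping_models_rejected(self):
        a = GeneModel("a", "chrT", "+", 100, 160, 460, 500)
        b = GeneModel("b", "chrT", "+", 400, 460, 760, 800)
        genome = simulate_gene_models(2, seed=0)
        genome.models[:] = [a, b]
        with pytest.raises(GenerationError):
            simulate_reads(genome, EffectConfig(mean_depth=10))

    def test_kqe_slope_decrements_te_truth(self):
        genome = simulate_gene_models(50, seed=4)
        cfg = EffectConfig(mean_depth=50, kqe_slope=2.0, seed=4)
        data = simulate_reads(genome, cfg, emit_reads=False)
        expected = 2.0 ** (-2.0 * genome.kqe_freq.to_numpy())
        assert np.allclose(data.truth["true_te_fc"].to_numpy(), expected)
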