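"""End-to-end orchestration: simulate -> count -> diffexp -> te -> modules -> utr -> codons.

Every threshold the analysis uses is a named configuration field with a
documented default; stage outputs are plain TSV files written with a fixed
float format, so a rerun with the same configuration and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import codons as _codons
from . import diffexpr, efficiency, genesets, utr
from . import simulate as sim
from . import io as _io
from .errors import ParameterError, PipelineError
from .models import ASSAYS, CONDITIONS, read_gene_models
from .quantify import build_count_table

logger = logging.getLogger("ribotrans")

_BED_KEYS = {
    "bed_sd_mrna": ("SD", "mRNA"),
    "bed_metr_mrna": ("MetR", "mRNA"),
    "bed_sd_fp": ("SD", "footprint"),
    "bed_metr_fp": ("MetR", "footprint"),
}


@dataclass
class PipelineConfig:
    """All inputs, outputs and thresholds of one pipeline run."""

    outdir: str = "ribotrans_out"
    seed: int = 0
    simulate: bool = True
    n_genes: int = 2000
    effect: sim.EffectConfig = field(default_factory=sim.EffectConfig)
    lengths: sim.LengthParams = field(default_factory=sim.LengthParams)
    # external inputs, used when simulate is False
    models_path: str | None = None
    cds_fasta: str | None = None
    gmt_path: str | None = None
    bed_sd_mrna: str | None = None
    bed_metr_mrna: str | None = None
    bed_sd_fp: str | None = None
    bed_metr_fp: str | None = None
    # thresholds (analysis defaults)
    offset: int = 15
    tss_exclusion: int = 50
    min_total: int = 128
    k: int = 100
    pseudocount: float = 0.5
    sigma_floor: float = 0.05
    te_z_cutoff: float = 2.0
    module_z_cutoff: float = 2.5
    min_module_size: int = 15
    delta: float = 1.0
    min_evidence: int = 16
    fc_cutoff: float = 4.0   # headline tally: |footprint fold change| beyond this
    te_fc_cutoff: float = 2.0
    exclude_ids: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for name in ("offset", "tss_exclusion", "min_total", "k", "min_module_size", "min_evidence"):
            if getattr(self, name) < 0:
                raise ParameterError(f"config field {name} must be >= 0")
        for name in ("te_z_cutoff", "module_z_cutoff", "delta", "fc_cutoff", "te_fc_cutoff", "sigma_floor"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"config field {name} must be > 0")
        if not self.simulate:
            for name in _BED_KEYS:
                if getattr(self, name) is None:
                    raise ParameterError(f"config field {name} is required when simulate is false")
            if self.models_path is None:
                raise ParameterError("config field models_path is required when simulate is false")

    def to_yaml(self, path) -> None:
        # json round-trip turns tuples into lists, which YAML can represent
        data = json.loads(json.dumps(dataclasses.asdict(self)))
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        effect = sim.EffectConfig(**raw.pop("effect", {}))
        if isinstance(effect.class1_fractions, list):
            effect.class1_fractions = tuple(effect.class1_fractions)
        if isinstance(effect.class2_fractions, list):
            effect.class2_fractions = tuple(effect.class2_fractions)
        if isinstance(effect.class3_fractions, list):
            effect.class3_fractions = tuple(effect.class3_fractions)
        lengths = sim.LengthParams(**raw.pop("lengths", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config fields: {sorted(unknown)}")
        return cls(effect=effect, lengths=lengths, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in dependency order and return the summary dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "FAILED"
    if marker.exists():
        marker.unlink()
    summary: dict = {"seed": config.seed, "stages": []}

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as exc:
                marker.write_text(f"stage {name} failed: {exc}\n")
                raise PipelineError(f"stage {name} failed: {exc}") from exc
            logger.info("stage %s done", name)
            summary["stages"].append(name)
            return result
        return wrap

    # --- inputs -----------------------------------------------------------
    gmt = None
    if config.simulate:
        def _simulate():
            cfg = dataclasses.replace(config.effect, seed=config.seed)
            data = sim.simulate_dataset(config.n_genes, cfg, config.lengths)
            return data, data.write(outdir)
        data, beds = stage("simulate")(_simulate)
        models = data.genome.models
        sequences = data.genome.sequences
        truth = data.truth
        planted_up = set(truth.loc[truth["true_te_fc"] > 1, "gene_id"])
        planted = {"planted_te_up": planted_up} if len(planted_up) >= config.min_module_size else {}
        gmt = sim.simulate_gene_sets(
            [m.gene_id for m in models], seed=config.seed, planted=planted
        )
        _io.write_gmt(gmt, outdir / "modules.gmt")
    else:
        models = stage("load_models")(lambda: read_gene_models(config.models_path))
        sequences = _io.read_fasta(config.cds_fasta) if config.cds_fasta else None
        beds = {key: getattr(config, name) for name, key in _BED_KEYS.items()}
        if config.gmt_path:
            gmt = _io.read_gmt(config.gmt_path)

    # --- counting ---------------------------------------------------------
    counts = stage("count")(
        lambda: build_count_table(beds, models, config.offset, config.tss_exclusion)
    )
    counts.to_tsv(outdir / "counts.tsv")

    # --- fold changes -----------------------------------------------------
    fc = {}
    for assay in ASSAYS:
        fc[assay] = stage(f"diffexp_{assay}")(
            lambda assay=assay: diffexpr.fold_change_table(
                counts, assay, config.min_total, config.k,
                config.pseudocount, config.sigma_floor,
            )
        )
        _io.write_tsv(fc[assay], outdir / f"fc_{'fp' if assay == 'footprint' else 'mrna'}.tsv")

    # --- translational efficiency ----------------------------------------
    te = stage("te")(lambda: efficiency.te_table(fc["mRNA"], fc["footprint"]))
    _io.write_tsv(te, outdir / "te.tsv")

    # --- modules ----------------------------------------------------------
    module_tallies = {}
    if gmt:
        for assay in ASSAYS:
            values = fc[assay].set_index("gene_id")["log2F"]
            scored, skipped = stage(f"modules_{assay}")(
                lambda values=values: genesets.score_all_modules(
                    values, gmt, config.min_module_size, assay
                )
            )
            _io.write_tsv(scored, outdir / f"modules_{'fp' if assay == 'footprint' else 'mrna'}.tsv")
            for module_id, reason in skipped.items():
                logger.info("module %s skipped (%s): %s", module_id, assay, reason)
            module_tallies[assay] = {
                "scored": len(scored),
                "beyond_cutoff_up": int(((scored["z"] > config.module_z_cutoff)).sum()),
                "beyond_cutoff_down": int(((scored["z"] < -config.module_z_cutoff)).sum()),
                "skipped": len(skipped),
            }

    # --- 5'UTR occupancy --------------------------------------------------
    utr_frame = stage("utr")(
        lambda: utr.build_utr_table(
            counts, te, models, config.delta, config.te_z_cutoff,
            config.min_evidence, config.pseudocount,
        )
    )
    _io.write_tsv(utr_frame, outdir / "utr.tsv")
    ratio_summary = utr.group_ratio_summary(utr_frame, counts, config.exclude_ids)
    _io.write_tsv(ratio_summary, outdir / "utr_group_summary.tsv")

    # --- codons -----------------------------------------------------------
    corr_results = []
    if sequences:
        stats_frame = stage("codons")(lambda: _codons.codon_table(sequences))
        _io.write_tsv(stats_frame, outdir / "codon_stats.tsv")
        for variable in ("K", "Q", "E", "KQE", "M"):
            try:
                res = _codons.correlate_frequency_te(stats_frame, te, variable)
                corr_results.append(dataclasses.asdict(res))
            except Exception as exc:  # degenerate inputs reported, not fatal
                logger.warning("correlation %s not computed: %s", variable, exc)
        if corr_results:
            _io.write_tsv(pd.DataFrame(corr_results), outdir / "codon_correlations.tsv")

    # --- summary ----------------------------------------------------------
    fp = fc["footprint"]
    summary.update(
        {
            "n_genes_input": len(models),
            "library_totals": {f"{c}/{a}": counts.library_totals[(c, a)] for c in CONDITIONS for a in ASSAYS},
            "n_scored": {a: len(fc[a]) for a in ASSAYS},
            "n_fp_fc_up": int((fp["F"] > config.fc_cutoff).sum()),
            "n_fp_fc_down": int((fp["F"] < 1.0 / config.fc_cutoff).sum()),
            "n_te_fc_up": int((te["te_ratio"] > config.te_fc_cutoff).sum()),
            "n_te_fc_down": int((te["te_ratio"] < 1.0 / config.te_fc_cutoff).sum()),
            "n_te_z_up": int((te["te_z"] > config.te_z_cutoff).sum()),
            "n_te_z_down": int((te["te_z"] < -config.te_z_cutoff).sum()),
            "loading_classes": utr_frame["loading_class"].value_counts().to_dict(),
            "modules": module_tallies,
            "codon_correlations": corr_results,
        }
    )
    with open(outdir / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
    return summary
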