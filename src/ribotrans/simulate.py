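"""Seeded synthetic data with planted ground truth.

The generator emulates one ribosome-profiling / RNA-seq experiment on a
budding-yeast-like transcriptome: two conditions (SD, MetR) x two assays
(mRNA, footprint), one library each.  It produces

* non-overlapping gene models on a synthetic reference, with 5'UTR, CDS
  and 3'UTR lengths drawn from configurable distributions;
* CDS sequences (ATG start, no internal stop, terminal stop) whose
  per-gene KQE codon content varies around a configurable mean;
* per-gene read counts drawn negative-binomially with mean-dependent
  dispersion (variance = mu + phi mu^2 with phi = dispersion_slope /
  sqrt(mu)), so that count noise shrinks with coverage the way the local
  sigma estimator assumes;
* read positions: mRNA 5' ends uniform over the CDS; footprint P-sites
  uniform over the CDS except a per-gene, per-condition fraction placed
  uniformly in the 5'UTR (used to plant the three loading classes);
* a truth table of every planted effect, for recovery testing.

Planted effects: transcriptional fold changes multiply both assays'
MetR means; TE fold changes multiply only the footprint MetR mean; the
KQE effect decrements log2(TE fold) by ``kqe_slope`` times the gene's
KQE codon frequency for the designated gene set (all genes by default).
The same :class:`EffectConfig` and seed always reproduce the output
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .errors import GenerationError, ParameterError
from .models import ASSAYS, CONDITIONS, GeneModel, write_gene_models
from .quantify import CountTable

_KQE_CODONS = np.array(["AAA", "AAG", "CAA", "CAG", "GAA", "GAG"])
_STOPS = {"TAA", "TAG", "TGA"}
_OTHER_CODONS = np.array(
    sorted(
        {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"}
        - _STOPS
        - set(_KQE_CODONS.tolist())
    )
)

TRUTH_COLUMNS = ["gene_id", "true_tx_fc", "true_te_fc", "true_class", "in_kqe_set"]


@dataclass
class LengthParams:
    """Gene-architecture distributions for the synthetic transcriptome.

    Defaults sketch a yeast-like genome: short, roughly exponential UTRs
    (median 5'UTR a few tens of nt) and log-normal CDS lengths around
    ~450 codons.
    """

    utr5_mean: float = 60.0
    utr5_min: int = 0
    utr3_mean: float = 120.0
    utr3_min: int = 20
    cds_codons_log2_mean: float = 8.8   # 2**8.8 ~ 446 codons
    cds_codons_log2_sd: float = 0.6
    cds_codons_min: int = 10
    kqe_freq_mean: float = 0.18
    kqe_freq_sd: float = 0.05
    intergenic_gap: int = 200
    minus_strand_fraction: float = 0.0
    chrom: str = "chrSim"

    def validate(self) -> None:
        if self.utr5_mean < self.utr5_min or self.utr5_min < 0:
            raise ParameterError("5'UTR length parameters must satisfy 0 <= min <= mean")
        if self.utr3_mean < self.utr3_min or self.utr3_min < 0:
            raise ParameterError("3'UTR length parameters must satisfy 0 <= min <= mean")
        if self.cds_codons_min < 10 or self.cds_codons_log2_sd < 0:
            raise ParameterError("CDS length parameters invalid (need >= 10 codons, sd >= 0)")
        if not (0 < self.kqe_freq_mean < 1) or self.kqe_freq_sd <= 0:
            raise ParameterError("KQE frequency parameters must be in (0, 1) with sd > 0")
        if self.intergenic_gap < 100:
            raise ParameterError("intergenic gap must be >= 100 nt (room for read ends)")
        if not 0 <= self.minus_strand_fraction <= 1:
            raise ParameterError("minus_strand_fraction must be in [0, 1]")


@dataclass
class EffectConfig:
    """Planted effects and noise model for one simulated experiment.

    ``mean_depth`` is the mean read count per gene per library (one
    condition x assay).  Fractions are of the total gene number; effect
    folds apply symmetrically (down = 1/effect).  ``utr5_read_fraction_*``
    set the baseline share of footprint reads whose P-site falls in the
    5'UTR; the three ``class*_fractions`` pairs override it (SD, MetR)
    for the genes planted in each loading class, which also receive the
    TE effect.  ``kqe_slope`` > 0 depresses log2(TE fold) by slope x
    freq_KQE for the genes in ``kqe_set`` (None = all genes).
    """

    mean_depth: float = 200.0
    dispersion_slope: float = 0.5
    expr_log2_sd: float = 0.75
    frac_tx_up: float = 0.0
    frac_tx_down: float = 0.0
    tx_effect: float = 4.0
    frac_te_up: float = 0.0
    frac_te_down: float = 0.0
    te_effect: float = 4.0
    utr5_read_fraction_sd: float = 0.008
    utr5_read_fraction_metr: float = 0.008
    n_class1: int = 0
    n_class2: int = 0
    n_class3: int = 0
    class1_fractions: tuple[float, float] = (0.30, 0.05)
    class2_fractions: tuple[float, float] = (0.05, 0.40)
    class3_fractions: tuple[float, float] = (0.10, 0.10)
    kqe_slope: float = 0.0
    kqe_set: list[str] | None = None
    collapse_positions: bool = True
    footprint_length: int = 28
    mrna_length: int = 50
    psite_offset: int = 15
    tss_exclusion: int = 50
    seed: int = 0

    def validate(self) -> None:
        fractions = [
            self.frac_tx_up, self.frac_tx_down, self.frac_te_up, self.frac_te_down,
            self.utr5_read_fraction_sd, self.utr5_read_fraction_metr,
            *self.class1_fractions, *self.class2_fractions, *self.class3_fractions,
        ]
        if any(not 0 <= f <= 1 for f in fractions):
            raise ParameterError("all fractions must lie in [0, 1]")
        if self.tx_effect <= 0 or self.te_effect <= 0:
            raise ParameterError("effect folds must be > 0")
        if self.mean_depth <= 0:
            raise ParameterError("mean_depth must be > 0")
        if self.dispersion_slope < 0:
            raise ParameterError("dispersion_slope must be >= 0")
        if min(self.n_class1, self.n_class2, self.n_class3) < 0:
            raise ParameterError("class gene counts must be >= 0")
        if self.footprint_length <= self.psite_offset:
            raise ParameterError("footprint length must exceed the P-site offset")


@dataclass
class SyntheticGenome:
    models: list[GeneModel]
    sequences: dict[str, str]
    kqe_freq: pd.Series  # realized per-gene KQE codon frequency

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_models(self.models, outdir / "models.tsv")
        _io.write_fasta(self.sequences, outdir / "cds.fasta")


@dataclass
class SimulatedData:
    genome: SyntheticGenome
    beds: dict[tuple[str, str], pd.DataFrame]
    counts: CountTable  # the generator's own per-region tallies (oracle)
    truth: pd.DataFrame

    def write(self, outdir) -> dict[tuple[str, str], Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genome.write(outdir)
        paths = {}
        for (condition, assay), bed in self.beds.items():
            path = outdir / f"{condition.lower()}_{'fp' if assay == 'footprint' else 'mrna'}.bed"
            _io.write_bed6(bed, path)
            paths[(condition, assay)] = path
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.10g")
        return paths


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    total = mean * (1 - mean) / sd**2 - 1
    if total <= 0:
        raise ParameterError(f"KQE frequency sd {sd} too large for mean {mean}")
    return mean * total, (1 - mean) * total


def simulate_gene_models(
    n_genes: int,
    length_params: LengthParams | None = None,
    seed: int = 0,
) -> SyntheticGenome:
    """Generate non-overlapping gene models and their CDS sequences."""
    if n_genes < 1:
        raise ParameterError(f"n_genes must be >= 1, got {n_genes}")
    params = length_params or LengthParams()
    params.validate()
    rng = np.random.default_rng(seed)

    utr5 = params.utr5_min + rng.geometric(
        1.0 / (params.utr5_mean - params.utr5_min + 1.0), n_genes
    ) - 1
    utr3 = params.utr3_min + rng.geometric(
        1.0 / (params.utr3_mean - params.utr3_min + 1.0), n_genes
    ) - 1
    codons = np.maximum(
        params.cds_codons_min,
        np.rint(2 ** rng.normal(params.cds_codons_log2_mean, params.cds_codons_log2_sd, n_genes)),
    ).astype(np.int64)
    cds_len = 3 * codons
    minus = rng.random(n_genes) < params.minus_strand_fraction

    span = utr5 + cds_len + utr3
    starts = params.intergenic_gap + np.concatenate(
        [[0], np.cumsum(span + params.intergenic_gap)[:-1]]
    )
    width = int(np.ceil(np.log10(max(n_genes, 10))))
    gene_ids = [f"gene{str(i).zfill(width)}" for i in range(n_genes)]

    models: list[GeneModel] = []
    for i in range(n_genes):
        lo = int(starts[i])
        hi = int(starts[i] + span[i])
        if not minus[i]:
            models.append(GeneModel(
                gene_ids[i], params.chrom, "+",
                tss=lo, cds_start=lo + int(utr5[i]),
                cds_end=lo + int(utr5[i] + cds_len[i]), utr3_end=hi,
            ))
        else:
            models.append(GeneModel(
                gene_ids[i], params.chrom, "-",
                tss=hi, cds_start=hi - int(utr5[i]),
                cds_end=hi - int(utr5[i] + cds_len[i]), utr3_end=lo,
            ))

    a, b = _beta_params(params.kqe_freq_mean, params.kqe_freq_sd)
    target_freq = rng.beta(a, b, n_genes)
    sequences: dict[str, str] = {}
    realized = np.empty(n_genes)
    stops = np.array(sorted(_STOPS))
    for i in range(n_genes):
        n_middle = int(codons[i]) - 2  # total codons minus ATG and stop
        u = rng.random(n_middle)
        is_kqe = u < target_freq[i]
        picks = np.where(
            is_kqe,
            _KQE_CODONS[rng.integers(0, len(_KQE_CODONS), n_middle)],
            _OTHER_CODONS[rng.integers(0, len(_OTHER_CODONS), n_middle)],
        )
        stop = stops[rng.integers(0, 3)]
        sequences[gene_ids[i]] = "ATG" + "".join(picks) + stop
        realized[i] = is_kqe.sum() / (int(codons[i]) - 1)  # sense codons incl. ATG
    return SyntheticGenome(
        models=models,
        sequences=sequences,
        kqe_freq=pd.Series(realized, index=pd.Index(gene_ids, name="gene_id"), name="freq_KQE"),
    )


def _check_non_overlapping(models: list[GeneModel]) -> None:
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for m in models:
        lo, hi = m.span
        by_chrom.setdefault(m.chrom, []).append((lo, hi, m.gene_id))
    for chrom, spans in by_chrom.items():
        spans.sort()
        for (lo1, hi1, g1), (lo2, hi2, g2) in zip(spans, spans[1:]):
            if lo2 < hi1:
                raise GenerationError(f"overlapping genes on {chrom}: {g1} and {g2}")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, slope: float) -> np.ndarray:
    """Negative binomial with variance mu + (slope/sqrt(mu)) * mu^2."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if slope <= 0:
        out[pos] = rng.poisson(mu[pos])
    else:
        m = mu[pos]
        size = np.sqrt(m) / slope  # NB size r = 1/phi
        out[pos] = rng.negative_binomial(size, size / (size + m))
    return out


def _uniform_positions(
    rng: np.random.Generator, lo: np.ndarray, hi: np.ndarray, counts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(gene_index, genomic position) arrays with counts[i] uniform draws in [lo_i, hi_i)."""
    idx = np.repeat(np.arange(len(counts)), counts)
    u = rng.random(idx.size)
    pos = lo[idx] + np.floor(u * (hi - lo)[idx]).astype(np.int64)
    return idx, pos


def simulate_reads(
    genome: SyntheticGenome,
    cfg: EffectConfig,
    emit_reads: bool = True,
) -> SimulatedData:
    """Simulate the four read libraries plus truth table for one genome.

    With ``emit_reads=False`` the BED frames are skipped (``beds`` empty)
    but counts, tallies and truth are drawn identically — useful for
    count-level statistical studies that do not touch the file pipeline.
    """
    cfg.validate()
    models = genome.models
    _check_non_overlapping(models)
    n = len(models)
    rng = np.random.default_rng(cfg.seed)
    gene_ids = np.array([m.gene_id for m in models])

    plus = np.array([m.strand == "+" for m in models])
    tss = np.array([m.tss for m in models], dtype=np.int64)
    utr5_lo = np.array([m.region_intervals()["utr5"][0] for m in models], dtype=np.int64)
    utr5_hi = np.array([m.region_intervals()["utr5"][1] for m in models], dtype=np.int64)
    cds_lo = np.array([m.region_intervals()["cds"][0] for m in models], dtype=np.int64)
    cds_hi = np.array([m.region_intervals()["cds"][1] for m in models], dtype=np.int64)
    utr5_len = np.array([m.utr5_len for m in models], dtype=np.int64)
    chrom = np.array([m.chrom for m in models])

    # --- planted effects ------------------------------------------------
    n_class = cfg.n_class1 + cfg.n_class2 + cfg.n_class3
    available = np.ones(n, dtype=bool)
    true_class = np.full(n, "none", dtype=object)
    if n_class > 0:
        eligible = np.flatnonzero(utr5_len >= 20)
        if len(eligible) < n_class:
            raise GenerationError(
                f"need {n_class} genes with 5'UTR >= 20 nt for class planting, "
                f"only {len(eligible)} available"
            )
        chosen = rng.choice(eligible, size=n_class, replace=False)
        for label, count, offset in (
            ("class1", cfg.n_class1, 0),
            ("class2", cfg.n_class2, cfg.n_class1),
            ("class3", cfg.n_class3, cfg.n_class1 + cfg.n_class2),
        ):
            true_class[chosen[offset : offset + count]] = label
        available[chosen] = False

    def _draw(frac_or_n: float, pool: np.ndarray) -> np.ndarray:
        count = int(round(frac_or_n * n))
        count = min(count, len(pool))
        return rng.choice(pool, size=count, replace=False) if count else np.array([], dtype=int)

    te_up = _draw(cfg.frac_te_up, np.flatnonzero(available))
    available[te_up] = False
    te_down = _draw(cfg.frac_te_down, np.flatnonzero(available))
    available[te_down] = False
    tx_up = _draw(cfg.frac_tx_up, np.flatnonzero(available))
    available[tx_up] = False
    tx_down = _draw(cfg.frac_tx_down, np.flatnonzero(available))

    true_tx_fc = np.ones(n)
    true_tx_fc[tx_up] = cfg.tx_effect
    true_tx_fc[tx_down] = 1.0 / cfg.tx_effect
    true_te_fc = np.ones(n)
    true_te_fc[te_up] = cfg.te_effect
    true_te_fc[te_down] = 1.0 / cfg.te_effect
    true_te_fc[true_class != "none"] = cfg.te_effect

    in_kqe = np.zeros(n, dtype=bool)
    if cfg.kqe_slope != 0.0:
        if cfg.kqe_set is None:
            in_kqe[:] = True
        else:
            in_kqe = np.isin(gene_ids, np.array(list(cfg.kqe_set)))
        freq = genome.kqe_freq.reindex(gene_ids).to_numpy()
        if np.any(np.isnan(freq[in_kqe])):
            raise GenerationError("kqe_slope set but KQE frequencies missing for some genes")
        true_te_fc = np.where(
            in_kqe, true_te_fc * 2.0 ** (-cfg.kqe_slope * freq), true_te_fc
        )

    # --- per-gene 5'UTR footprint fractions -----------------------------
    frac_sd = np.full(n, cfg.utr5_read_fraction_sd)
    frac_metr = np.full(n, cfg.utr5_read_fraction_metr)
    for label, (f_sd, f_metr) in (
        ("class1", cfg.class1_fractions),
        ("class2", cfg.class2_fractions),
        ("class3", cfg.class3_fractions),
    ):
        sel = true_class == label
        frac_sd[sel] = f_sd
        frac_metr[sel] = f_metr
    no_utr = utr5_len == 0
    frac_sd[no_utr] = 0.0
    frac_metr[no_utr] = 0.0

    # --- per-gene library means ------------------------------------------
    expr = 2.0 ** rng.normal(0.0, cfg.expr_log2_sd, n)
    rel = expr / expr.mean()
    mu = {
        ("SD", "mRNA"): cfg.mean_depth * rel,
        ("MetR", "mRNA"): cfg.mean_depth * rel * true_tx_fc,
        ("SD", "footprint"): cfg.mean_depth * rel,
        ("MetR", "footprint"): cfg.mean_depth * rel * true_tx_fc * true_te_fc,
    }

    beds: dict[tuple[str, str], pd.DataFrame] = {}
    tallies = []
    totals: dict[tuple[str, str], int] = {}
    for condition in CONDITIONS:
        for assay in ASSAYS:
            counts = _nb_draw(rng, mu[(condition, assay)], cfg.dispersion_slope)
            if assay == "mRNA":
                g_idx, psite = _uniform_positions(rng, cds_lo, cds_hi, counts)
            else:
                frac = frac_sd if condition == "SD" else frac_metr
                n_utr = rng.binomial(counts, frac)
                g_utr, p_utr = _uniform_positions(rng, utr5_lo, utr5_hi, n_utr)
                g_cds, p_cds = _uniform_positions(rng, cds_lo, cds_hi, counts - n_utr)
                g_idx = np.concatenate([g_utr, g_cds])
                psite = np.concatenate([p_utr, p_cds])
            if emit_reads:
                beds[(condition, assay)] = _reads_frame(
                    cfg, assay, chrom[g_idx], gene_ids[g_idx], psite, plus[g_idx]
                )
            totals[(condition, assay)] = int(len(g_idx))
            tallies.append(
                _tally(condition, assay, gene_ids, g_idx, psite, plus, tss,
                       utr5_lo, utr5_hi, cds_lo, cds_hi, cfg.tss_exclusion)
            )

    counts_frame = pd.concat(tallies, ignore_index=True)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_tx_fc": true_tx_fc,
            "true_te_fc": true_te_fc,
            "true_class": true_class,
            "in_kqe_set": in_kqe,
        }
    )
    return SimulatedData(
        genome=genome,
        beds=beds,
        counts=CountTable(counts=counts_frame, library_totals=totals),
        truth=truth,
    )


def _reads_frame(
    cfg: EffectConfig,
    assay: str,
    chroms: np.ndarray,
    names: np.ndarray,
    psite: np.ndarray,
    plus: np.ndarray,
) -> pd.DataFrame:
    """BED6 frame whose assigned positions recover the given P-sites/5' ends."""
    if assay == "mRNA":
        start = np.where(plus, psite, psite + 1 - cfg.mrna_length)
        end = start + cfg.mrna_length
    else:
        start = np.where(
            plus, psite - cfg.psite_offset, psite + cfg.psite_offset + 1 - cfg.footprint_length
        )
        end = start + cfg.footprint_length
    if len(start) and start.min() < 0:
        raise GenerationError("read would start before the reference origin; increase the gap")
    frame = pd.DataFrame(
        {
            "chrom": chroms,
            "start": start,
            "end": end,
            "name": names,
            "score": np.ones(len(start), dtype=np.int64),
            "strand": np.where(plus, "+", "-"),
        }
    )
    if cfg.collapse_positions and len(frame):
        frame = (
            frame.groupby(["chrom", "start", "end", "strand"], as_index=False)
            .agg(name=("name", "first"), score=("score", "sum"))
        )
        frame = frame[["chrom", "start", "end", "name", "score", "strand"]]
    return frame.sort_values(["chrom", "start", "end", "strand"], ignore_index=True)


def _tally(
    condition: str,
    assay: str,
    gene_ids: np.ndarray,
    g_idx: np.ndarray,
    psite: np.ndarray,
    plus: np.ndarray,
    tss: np.ndarray,
    utr5_lo: np.ndarray,
    utr5_hi: np.ndarray,
    cds_lo: np.ndarray,
    cds_hi: np.ndarray,
    tss_exclusion: int,
) -> pd.DataFrame:
    """The generator's own per-region tallies of the emitted positions."""
    n = len(gene_ids)
    in_cds = (psite >= cds_lo[g_idx]) & (psite < cds_hi[g_idx])
    tdist = np.where(plus[g_idx], psite - tss[g_idx], tss[g_idx] - 1 - psite)
    in_utr5 = (psite >= utr5_lo[g_idx]) & (psite < utr5_hi[g_idx])
    cds_counts = np.bincount(g_idx[in_cds & (tdist >= tss_exclusion)], minlength=n)
    utr5_counts = np.bincount(g_idx[in_utr5], minlength=n)
    in_utr3 = ~(in_cds | in_utr5)
    utr3_counts = np.bincount(g_idx[in_utr3], minlength=n)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "condition": condition,
            "assay": assay,
            "cds_count": cds_counts,
            "utr5_count": utr5_counts,
            "utr3_count": utr3_counts,
        }
    )


def simulate_dataset(
    n_genes: int,
    cfg: EffectConfig | None = None,
    length_params: LengthParams | None = None,
    seed: int | None = None,
    emit_reads: bool = True,
) -> SimulatedData:
    """Convenience wrapper: genome + reads in one call.

    ``seed`` (when given) overrides ``cfg.seed`` and also seeds the gene
    models, so a single integer reproduces the whole dataset.
    """
    cfg = cfg or EffectConfig()
    if seed is not None:
        cfg.seed = int(seed)
    genome = simulate_gene_models(n_genes, length_params, seed=cfg.seed)
    return simulate_reads(genome, cfg, emit_reads=emit_reads)


def simulate_gene_sets(
    gene_ids: list[str],
    n_sets: int = 20,
    size_low: int = 15,
    size_high: int = 60,
    seed: int = 0,
    planted: dict[str, set[str]] | None = None,
) -> dict[str, set[str]]:
    """Random gene sets (plus optional planted ones) for module scoring."""
    rng = np.random.default_rng(seed)
    ids = np.array(gene_ids)
    sets: dict[str, set[str]] = {}
    width = int(np.ceil(np.log10(max(n_sets, 10))))
    for i in range(n_sets):
        size = int(rng.integers(size_low, size_high + 1))
        size = min(size, len(ids))
        sets[f"module_{str(i).zfill(width)}"] = set(rng.choice(ids, size=size, replace=False))
    for name, members in (planted or {}).items():
        sets[name] = set(members)
    return sets
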