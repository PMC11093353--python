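"""Synthetic study generator with planted ground truth.

Every pipeline input can be simulated with known truth so each downstream
stage is testable without external data:

* a balanced 3-block x 8-treatment log2 expression matrix with planted
  class effects (hypoxia-responsive, HIF-1-dependent, mutant-misregulated);
* a toy genome: gene models (strand, exons/introns/UTRs, TSS) on one or
  more chromosomes, sequence at C. elegans-like GC content (~0.36);
* ChIP/input bin-count tracks for two biological replicates, negative-
  binomial background with planted enriched intervals near chosen genes
  (reproducible by construction) plus optional single-replicate decoys,
  and RCGTG motifs spliced into the planted peak sequences;
* binomial hatching/adulthood outcomes with genotype-dependent hypoxia
  penalties (defaults mirror a hif-1 null: 78% hatched, 18% adult in
  hypoxia vs essentially unaffected wild type).

One RNG stream per artifact, derived from the master seed by fixed labels,
so adding a generator never perturbs the others.  Identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .chip import BinTrack
from .errors import ConfigurationError
from .expression import DEFAULT_TREATMENTS, MUTANTS, ExpressionStudy
from .targets import GeneModel

__all__ = ["SimConfig", "TruthTable", "ChipSim",
           "simulate_expression", "simulate_genome", "simulate_chip",
           "simulate_phenotype"]

GENE_CLASSES = (
    "hypoxia_up",
    "hypoxia_down",
    "hif1_positive",
    "hif1_negative",
    "mutant_up",
    "mutant_down",
    "null",
)


def default_survival_probs() -> dict:
    """(hatch, adult) success probabilities per genotype x treatment."""
    return {
        ("N2", "normoxia"): (0.99, 0.95),
        ("N2", "hypoxia"): (0.99, 0.93),
        ("hif-1", "normoxia"): (0.99, 0.95),
        ("hif-1", "hypoxia"): (0.78, 0.18),
    }


@dataclass(frozen=True)
class SimConfig:
    """All tunable parameters of the synthetic study.

    Expression: planted contrast magnitude ``effect_log2`` (log2 units),
    residual SD ``noise_sd``, per-(gene, block) effect SD ``block_sd``.
    ChIP: negative-binomial background with mean ``background_mean`` and
    size parameter ``background_dispersion`` per 200-bp bin; planted peaks
    multiply the mean by ``peak_enrichment`` over ``peak_width_bins`` bins.
    Phenotype: binomial outcomes of ``n_animals`` per arm and replicate.
    """

    n_genes: int = 2000
    n_blocks: int = 3
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    frac_hypoxia_up: float = 0.05
    frac_hypoxia_down: float = 0.05
    frac_hif1_pos: float = 0.05
    frac_hif1_neg: float = 0.05
    frac_mutant_up: float = 0.02
    frac_mutant_down: float = 0.02
    effect_log2: float = 2.0
    noise_sd: float = 0.25
    block_sd: float = 0.3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    genome_length: int = 6_000_000
    n_chromosomes: int = 2
    bin_size: int = 200
    intergenic_bp: int = 2000
    background_mean: float = 20.0
    background_dispersion: float = 200.0
    peak_enrichment: float = 5.0
    peak_width_bins: int = 3
    n_peaks: int = 30
    n_decoy_peaks: int = 2
    gc_content: float = 0.36
    motifs_per_peak: int = 2
    survival_probs: Mapping = field(default_factory=default_survival_probs)
    n_animals: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        fr_hyp = self.frac_hypoxia_up + self.frac_hypoxia_down
        fr_cls = (self.frac_hif1_pos + self.frac_hif1_neg
                  + self.frac_mutant_up + self.frac_mutant_down)
        for name in ("frac_hypoxia_up", "frac_hypoxia_down", "frac_hif1_pos",
                     "frac_hif1_neg", "frac_mutant_up", "frac_mutant_down"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if fr_hyp + fr_cls > 1 + 1e-9:
            raise ConfigurationError("class fractions sum to more than 1")
        if self.n_genes < 1 or self.n_blocks < 2:
            raise ConfigurationError("need n_genes >= 1 and n_blocks >= 2")
        if self.bin_size <= 0:
            raise ConfigurationError("bin_size must be positive")
        if self.peak_width_bins < 1:
            raise ConfigurationError("peak_width_bins must be >= 1")
        if self.genome_length % self.bin_size != 0:
            raise ConfigurationError("genome_length must be divisible by bin_size")
        if self.intergenic_bp <= 0:
            raise ConfigurationError("intergenic_bp must be positive")
        if not 0 < self.gc_content < 1:
            raise ConfigurationError("gc_content must be in (0, 1)")
        for key, (ph, pa) in dict(self.survival_probs).items():
            if not (0 <= ph <= 1 and 0 <= pa <= 1):
                raise ConfigurationError(f"survival probabilities for {key} not in [0, 1]")

    def rng(self, label: str) -> np.random.Generator:
        """A named, reproducible RNG stream derived from the master seed."""
        tag = zlib.crc32(label.encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence([self.seed, tag]))


@dataclass
class TruthTable:
    """Planted ground truth: gene classes and effects, peaks, motifs.

    ``genes``: gene_id-indexed with columns ``cls`` and planted log2 effects
    per contrast.  ``peaks``: one row per planted interval with coordinates,
    enrichment, the gene it was constructed for and whether it is present in
    both replicates (decoys are not).  ``motifs``: planted HRE placements.
    """

    genes: pd.DataFrame
    peaks: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["peak_id", "chrom", "start", "end", "enrichment",
                     "gene", "reproducible", "replicate"]
        )
    )
    motifs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["peak_id", "chrom", "offset", "motif"]
        )
    )

    def genes_of_class(self, cls: str) -> list[str]:
        return sorted(self.genes.index[self.genes["cls"] == cls])

    def planted_direct_targets(self) -> pd.DataFrame:
        """Reproducible planted peaks joined with their genes' classes."""
        rep = self.peaks[self.peaks["reproducible"]].copy()
        rep["cls"] = self.genes.loc[rep["gene"], "cls"].to_numpy()
        return rep


def _class_sizes(cfg: SimConfig) -> dict[str, int]:
    sizes = {
        "hypoxia_up": int(round(cfg.n_genes * cfg.frac_hypoxia_up)),
        "hypoxia_down": int(round(cfg.n_genes * cfg.frac_hypoxia_down)),
        "hif1_positive": int(round(cfg.n_genes * cfg.frac_hif1_pos)),
        "hif1_negative": int(round(cfg.n_genes * cfg.frac_hif1_neg)),
        "mutant_up": int(round(cfg.n_genes * cfg.frac_mutant_up)),
        "mutant_down": int(round(cfg.n_genes * cfg.frac_mutant_down)),
    }
    if sum(sizes.values()) > cfg.n_genes:
        raise ConfigurationError("class fractions leave no room for null genes")
    sizes["null"] = cfg.n_genes - sum(sizes.values())
    return sizes


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def simulate_expression(cfg: SimConfig) -> tuple[ExpressionStudy, TruthTable]:
    """Simulate the factorial expression study.

    Planted treatment effects on the log2 scale, by class:

    * hypoxia_up/down: +/- effect_log2 in both hypoxia arms (HIF-independent);
    * hif1_positive: +effect_log2 in the N2 hypoxia arm only, so the
      interaction contrast (N2 effect minus hif-1 effect) equals effect_log2;
    * hif1_negative: +effect_log2 in the hif-1 hypoxia arm only
      (interaction -effect_log2);
    * mutant_up/down: +/- effect_log2 in the first HIF-1-stabilizing mutant
      arm; null genes carry no effect for any contrast.
    """
    rng = cfg.rng("expression")
    sizes = _class_sizes(cfg)
    ids = _gene_ids(cfg.n_genes)
    classes = rng.permutation(
        np.repeat([c for c in GENE_CLASSES], [sizes[c] for c in GENE_CLASSES])
    )

    t_idx = {t: i for i, t in enumerate(cfg.treatments)}
    mutant = next(m for m in MUTANTS if m in cfg.treatments)
    effects = np.zeros((cfg.n_genes, len(cfg.treatments)))
    e = cfg.effect_log2
    for i, cls in enumerate(classes):
        if cls == "hypoxia_up":
            effects[i, t_idx["N2-hypoxia"]] = e
            effects[i, t_idx["hif-1-hypoxia"]] = e
        elif cls == "hypoxia_down":
            effects[i, t_idx["N2-hypoxia"]] = -e
            effects[i, t_idx["hif-1-hypoxia"]] = -e
        elif cls == "hif1_positive":
            effects[i, t_idx["N2-hypoxia"]] = e
        elif cls == "hif1_negative":
            effects[i, t_idx["hif-1-hypoxia"]] = e
        elif cls == "mutant_up":
            effects[i, t_idx[mutant]] = e
        elif cls == "mutant_down":
            effects[i, t_idx[mutant]] = -e

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    block_eff = rng.normal(0.0, cfg.block_sd, size=(cfg.n_genes, cfg.n_blocks))

    cols, data = [], []
    for b in range(1, cfg.n_blocks + 1):
        for t in cfg.treatments:
            cols.append(f"b{b}_{t}")
            mean = baseline + effects[:, t_idx[t]] + block_eff[:, b - 1]
            data.append(mean + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes))
    matrix = pd.DataFrame(np.column_stack(data), index=ids, columns=cols)

    samples = pd.DataFrame(
        [
            {
                "sample": f"b{b}_{t}",
                "genotype": t.replace("-hypoxia", ""),
                "treatment": t,
                "block": b,
            }
            for b in range(1, cfg.n_blocks + 1)
            for t in cfg.treatments
        ]
    ).set_index("sample")

    probe_map = pd.DataFrame({"probeset": [f"ps_{g}" for g in ids], "gene": ids})
    matrix.index = [f"ps_{g}" for g in ids]

    truth_genes = pd.DataFrame(
        {
            "cls": classes,
            "effect_n2_hypoxia": effects[:, t_idx["N2-hypoxia"]],
            "effect_hif1_hypoxia": effects[:, t_idx["hif-1-hypoxia"]],
            "effect_interaction": effects[:, t_idx["N2-hypoxia"]]
            - effects[:, t_idx["hif-1-hypoxia"]],
            f"effect_mutant:{mutant}": effects[:, t_idx[mutant]],
        },
        index=pd.Index(ids, name="gene"),
    )
    study = ExpressionStudy(matrix, samples, probe_map)
    return study, TruthTable(genes=truth_genes)


def simulate_genome(cfg: SimConfig) -> tuple[list[GeneModel], dict[str, str]]:
    """Place non-overlapping gene models and draw sequence at the target GC.

    Genes are laid out round-robin across chromosomes with ``intergenic_bp``
    spacing; each has a 5' UTR, 2-4 exons with introns, a CDS and a 3' UTR,
    and alternating strand.  Raises ConfigurationError when the genes do not
    fit at the stated genome length.
    """
    rng = cfg.rng("genome")
    ids = _gene_ids(cfg.n_genes)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    per_chrom = -(-cfg.n_genes // cfg.n_chromosomes)
    max_span = 3000
    need = per_chrom * (max_span + cfg.intergenic_bp) + cfg.intergenic_bp
    if need > cfg.genome_length:
        raise ConfigurationError(
            f"{per_chrom} genes of up to {max_span} bp plus {cfg.intergenic_bp} bp "
            f"spacing need {need} bp > genome_length {cfg.genome_length}"
        )

    genes: list[GeneModel] = []
    cursor = {c: cfg.intergenic_bp for c in chroms}
    for i, gid in enumerate(ids):
        chrom = chroms[i % cfg.n_chromosomes]
        span = int(rng.integers(1500, max_span + 1))
        start = cursor[chrom]
        end = start + span
        cursor[chrom] = end + cfg.intergenic_bp
        strand = "+" if (i // cfg.n_chromosomes) % 2 == 0 else "-"

        utr5_len, utr3_len = 100, 150
        n_exons = int(rng.integers(2, 5))
        # exon/intron layout inside the transcribed span
        inner = span - utr5_len - utr3_len
        bounds = np.sort(rng.choice(np.arange(1, inner), size=2 * n_exons - 2,
                                    replace=False)) if n_exons > 1 else np.array([], int)
        cuts = [0, *bounds.tolist(), inner]
        pieces = [(cuts[k], cuts[k + 1]) for k in range(len(cuts) - 1)]
        exon_pieces = pieces[::2]
        left = start + utr5_len if strand == "+" else start + utr3_len
        exons = [(left + s, left + e) for s, e in exon_pieces if e > s]
        # UTRs are terminal exon-level features
        if strand == "+":
            five = [(start, start + utr5_len)]
            three = [(end - utr3_len, end)]
        else:
            five = [(end - utr5_len, end)]
            three = [(start, start + utr3_len)]
        exons = sorted(set(five + exons + three))
        cds = [iv for iv in exons if iv not in five and iv not in three]
        genes.append(
            GeneModel(
                gene_id=gid, chrom=chrom, start=start, end=end, strand=strand,
                exons=exons, five_utr=five, three_utr=three, cds=cds,
            )
        )

    p = [(1 - cfg.gc_content) / 2, cfg.gc_content / 2,
         cfg.gc_content / 2, (1 - cfg.gc_content) / 2]
    seqs = {
        c: "".join(rng.choice(np.array(list("ACGT")), size=cfg.genome_length, p=p))
        for c in chroms
    }
    return genes, seqs


@dataclass
class ChipSim:
    """Simulated two-replicate ChIP experiment.

    ``tracks[rep][kind]`` with rep in {"rep1", "rep2"} and kind in
    {"chip", "input"} maps chromosome -> BinTrack.  ``sequences`` is the
    genome with planted HRE motifs spliced into peak intervals (when a
    genome was supplied).
    """

    tracks: dict
    truth: TruthTable
    sequences: dict | None = None


def _nb_counts(rng, mean: float, size_param: float, n: int) -> np.ndarray:
    """Negative binomial with mean ``mean`` and size (dispersion) ``size_param``."""
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def simulate_chip(
    annotation: list[GeneModel],
    truth: TruthTable,
    cfg: SimConfig,
    sequences: dict[str, str] | None = None,
) -> ChipSim:
    """Simulate ChIP/input bin tracks for two replicates with planted peaks.

    Peaks are planted bin-aligned immediately upstream of the TSS of chosen
    genes (preferentially HIF-1-dependent and mutant-misregulated ones, the
    remainder null genes), present in both replicates; ``n_decoy_peaks``
    extra intervals are enriched in replicate 1 only.  Input tracks are
    negative-binomial background; ChIP tracks equal background except inside
    planted intervals, where the mean is multiplied by ``peak_enrichment``.
    RCGTG motifs are spliced into each planted peak when sequence is given.
    """
    rng = cfg.rng("chip")
    by_id = {g.gene_id: g for g in annotation}
    n_bins = cfg.genome_length // cfg.bin_size
    chroms = sorted({g.chrom for g in annotation})
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    cls_of = truth.genes["cls"].to_dict()

    peak_rows, motif_rows = [], []
    occupied: dict[str, set[int]] = {c: set() for c in chroms}

    def eligible(gene: GeneModel, start: int, end: int) -> bool:
        """No second non-null gene within assignment range of the interval:
        keeps the constructed gene the unique by-construction target."""
        from .targets import gene_distance

        for h in by_chrom[gene.chrom]:
            if h.gene_id == gene.gene_id:
                continue
            if (gene_distance((start, end), h.span) <= 6000
                    and cls_of.get(h.gene_id, "null") != "null"):
                return False
        return True

    def plant(gene: GeneModel, peak_id: str, reproducible: bool, replicate: str):
        width = cfg.peak_width_bins * cfg.bin_size
        if gene.strand == "+":
            start = max(0, gene.start - width - cfg.bin_size)
        else:
            start = min(cfg.genome_length - width, gene.end + cfg.bin_size)
        start = (start // cfg.bin_size) * cfg.bin_size
        end = start + width
        if end > cfg.genome_length or start < 0:
            raise ConfigurationError(f"peak for {gene.gene_id} falls off {gene.chrom}")
        bins = set(range(start // cfg.bin_size, end // cfg.bin_size))
        if bins & occupied[gene.chrom] or not eligible(gene, start, end):
            return False
        occupied[gene.chrom] |= bins
        peak_rows.append(
            {"peak_id": peak_id, "chrom": gene.chrom, "start": start, "end": end,
             "enrichment": cfg.peak_enrichment, "gene": gene.gene_id,
             "reproducible": reproducible, "replicate": replicate}
        )
        if sequences is not None:
            seq = sequences[gene.chrom]
            n_m = cfg.motifs_per_peak
            offs = sorted(rng.choice(np.arange(0, end - start - 5, 6),
                                     size=min(n_m, (end - start - 5) // 6),
                                     replace=False))
            for off in offs:
                motif = "ACGTG" if rng.random() < 0.5 else "GCGTG"
                pos = start + int(off)
                sequences[gene.chrom] = seq[:pos] + motif + seq[pos + 5:]
                seq = sequences[gene.chrom]
                motif_rows.append({"peak_id": peak_id, "chrom": gene.chrom,
                                   "offset": pos - start, "motif": motif})
        return True

    # round-robin over truth classes so every regulation row gets planted
    # direct targets; nulls exercise the nearest-gene path
    pools = [
        iter([g for g in truth.genes_of_class(cls) if g in by_id])
        for cls in ("hif1_positive", "hif1_negative", "mutant_up",
                    "mutant_down", "null")
    ]
    k = 0
    exhausted: set[int] = set()
    while k < cfg.n_peaks and len(exhausted) < len(pools):
        for pi, pool in enumerate(pools):
            if k >= cfg.n_peaks or pi in exhausted:
                continue
            for gid in pool:
                if plant(by_id[gid], f"peak{k + 1:03d}", True, "both"):
                    k += 1
                    break
            else:
                exhausted.add(pi)

    # replicate-1-only decoys on remaining null genes
    d = 0
    for gid in pools[-1]:
        if d >= cfg.n_decoy_peaks:
            break
        if plant(by_id[gid], f"decoy{d + 1:02d}", False, "rep1"):
            d += 1

    peaks = pd.DataFrame(peak_rows, columns=["peak_id", "chrom", "start", "end",
                                             "enrichment", "gene", "reproducible",
                                             "replicate"])
    motifs = pd.DataFrame(motif_rows, columns=["peak_id", "chrom", "offset", "motif"])

    tracks: dict[str, dict[str, dict[str, BinTrack]]] = {}
    for rep in ("rep1", "rep2"):
        rep_tracks: dict[str, dict[str, BinTrack]] = {"chip": {}, "input": {}}
        chip_counts, input_counts = {}, {}
        for chrom in chroms:
            mean_vec = np.full(n_bins, cfg.background_mean)
            sel = peaks[(peaks["chrom"] == chrom)
                        & (peaks["reproducible"] | (peaks["replicate"] == rep))]
            for _, row in sel.iterrows():
                b0, b1 = row["start"] // cfg.bin_size, row["end"] // cfg.bin_size
                mean_vec[b0:b1] = cfg.background_mean * row["enrichment"]
            chip = np.empty(n_bins, dtype=np.int64)
            for m in np.unique(mean_vec):
                idx = mean_vec == m
                chip[idx] = _nb_counts(rng, m, cfg.background_dispersion,
                                       int(idx.sum()))
            input_counts[chrom] = _nb_counts(rng, cfg.background_mean,
                                             cfg.background_dispersion, n_bins)
            chip_counts[chrom] = chip
        chip_total = int(sum(a.sum() for a in chip_counts.values()))
        input_total = int(sum(a.sum() for a in input_counts.values()))
        for chrom in chroms:
            rep_tracks["chip"][chrom] = BinTrack(chrom, cfg.bin_size,
                                                 chip_counts[chrom], chip_total)
            rep_tracks["input"][chrom] = BinTrack(chrom, cfg.bin_size,
                                                  input_counts[chrom], input_total)
        tracks[rep] = rep_tracks

    new_truth = TruthTable(genes=truth.genes, peaks=peaks, motifs=motifs)
    return ChipSim(tracks=tracks, truth=new_truth, sequences=sequences)


def simulate_phenotype(cfg: SimConfig, n_replicates: int = 3) -> pd.DataFrame:
    """Binomial hatch/adult outcomes per genotype, treatment and replicate.

    ``cfg.survival_probs`` maps (genotype, treatment) -> (P(hatch),
    P(adult)); every arm gets ``cfg.n_animals`` animals per replicate.
    Adulthood is scored against the same plated total (an un-hatched embryo
    is also a non-adult), so P(adult) <= P(hatch) is the realistic regime.
    """
    rng = cfg.rng("phenotype")
    rows = []
    for (genotype, treatment), (p_hatch, p_adult) in dict(cfg.survival_probs).items():
        for rep in range(1, n_replicates + 1):
            n = cfg.n_animals
            hatched = int(rng.binomial(n, p_hatch))
            # adults are a subset of hatched animals
            p_cond = min(1.0, p_adult / p_hatch) if p_hatch > 0 else 0.0
            adult = int(rng.binomial(hatched, p_cond))
            rows.append({"genotype": genotype, "treatment": treatment,
                         "replicate": rep, "n_total": n,
                         "n_hatched": hatched, "n_adult": adult})
    return pd.DataFrame(rows)
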