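"""End-to-end orchestration: simulate -> DE -> ChIP -> assign -> overlap -> report.

A single :class:`RunConfig` drives every stage; per-stage RNG streams are
derived from the master seed by fixed labels, so an identical config and
seed reproduce a byte-identical summary.  The summary is a plain dict
(JSON-serializable) with the gene-list counts, region count, assignment and
cross-reference tables, overlap results, recovery-vs-truth metrics and a
provenance record (config hash, seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .chip import call_peaks, filter_peaks, reproducible_regions
from .errors import ConfigurationError
from .expression import DEAnalysis, Thresholds, dedup_probesets
from .overlap import fisher_overlap
from .phenotype import survival_test
from .synthdata import SimConfig, simulate_chip, simulate_expression, simulate_genome, simulate_phenotype
from .targets import assign_region, cross_reference, scan_hre

log = logging.getLogger("hifseek")

ALL_STAGES = ("simulate", "de", "chip", "assign", "overlap", "phenotype")


@dataclass
class RunConfig:
    out_dir: str | Path = "hifseek_run"
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    stages: tuple[str, ...] = ALL_STAGES
    fdr: float = 0.05
    hre_mode: str = "core"
    hre_strands: str = "given"
    seed: int | None = None  # overrides sim.seed when set

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")
        if self.seed is not None:
            self.sim = dataclasses.replace(self.sim, seed=int(self.seed))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**{k: v for k, v in raw.pop("sim", {}).items()})
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        stages = tuple(raw.pop("stages", ALL_STAGES))
        return cls(sim=sim, thresholds=thresholds, stages=stages, **raw)

    def config_hash(self) -> str:
        payload = {
            "sim": {k: (list(v) if isinstance(v, tuple) else
                        {f"{a}|{b}": list(p) for (a, b), p in dict(v).items()}
                        if isinstance(v, dict) else v)
                    for k, v in dataclasses.asdict(self.sim).items()},
            "thresholds": dataclasses.asdict(self.thresholds),
            "stages": list(self.stages),
            "fdr": self.fdr,
            "hre_mode": self.hre_mode,
            "hre_strands": self.hre_strands,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _relabel_to_genes(study, probe_map_11: pd.DataFrame):
    """Restrict the matrix to the one-to-one probesets and index rows by gene."""
    keep = probe_map_11.set_index("probeset")["gene"]
    matrix = study.matrix.loc[keep.index]
    matrix.index = keep.to_numpy()
    from .expression import ExpressionStudy

    return ExpressionStudy(matrix, study.samples, probe_map_11)


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.sim
    enabled = set(config.stages)
    summary: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": cfg.seed,
            "version": _version(),
        }
    }
    if not enabled:
        _write_summary(summary, out)
        return summary

    if "simulate" not in enabled:
        raise ConfigurationError(
            "stage 'simulate' is required by every downstream stage in a "
            "synthetic run"
        )
    log.info("simulating expression study")
    study, truth = simulate_expression(cfg)
    genes, seqs = simulate_genome(cfg)
    hio.write_expression(study, out / "matrix.tsv", out / "samples.tsv")
    study.probe_map.to_csv(out / "probe_map.tsv", sep="\t", index=False)
    hio.write_gff3(genes, out / "annotation.gff3")
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t")
    summary["simulate"] = {
        "n_genes": cfg.n_genes,
        "n_samples": int(study.matrix.shape[1]),
        "class_counts": truth.genes["cls"].value_counts().to_dict(),
    }

    de_results = None
    if "de" in enabled:
        log.info("fitting factorial contrasts")
        map11 = dedup_probesets(study.probe_map, study.matrix)
        gene_study = _relabel_to_genes(study, map11)
        de_results = DEAnalysis(gene_study, thresholds=config.thresholds).fit()
        lists = de_results.gene_lists()
        for name, members in lists.items():
            safe = name.replace(":", "_").replace(";", "_")
            (out / f"genes_{safe}.txt").write_text("\n".join(members) + "\n")
        de_results.table("interaction").to_csv(out / "de_interaction.tsv", sep="\t")
        summary["de"] = {"list_sizes": {k: len(v) for k, v in lists.items()}}

    regions = []
    chip_sim = None
    if "chip" in enabled:
        log.info("simulating and calling ChIP data")
        chip_sim = simulate_chip(genes, truth, cfg, sequences=seqs)
        truth = chip_sim.truth
        truth.peaks.to_csv(out / "truth_peaks.tsv", sep="\t", index=False)
        hio.write_fasta(chip_sim.sequences, out / "genome.fasta")
        filtered = {}
        for rep in ("rep1", "rep2"):
            t = chip_sim.tracks[rep]
            hio.write_bedgraph(t["chip"], out / f"chip_{rep}.bedgraph")
            hio.write_bedgraph(t["input"], out / f"input_{rep}.bedgraph")
            calls = call_peaks(t["chip"], t["input"], fdr=config.fdr, replicate=rep)
            filtered[rep] = filter_peaks(calls)
            hio.write_peaks(filtered[rep], out / f"peaks_{rep}.bed",
                            out / f"peaks_{rep}.tsv")
        regions = reproducible_regions(filtered["rep1"], filtered["rep2"],
                                       bin_size=cfg.bin_size)
        summary["chip"] = {
            "peaks_rep1": len(filtered["rep1"]),
            "peaks_rep2": len(filtered["rep2"]),
            "n_regions": len(regions),
            "n_planted_reproducible": int(truth.peaks["reproducible"].sum()),
        }

    annotations = []
    if "assign" in enabled and "chip" in enabled:
        log.info("assigning regions to genes")
        de_gene_set: set[str] = set()
        if de_results is not None:
            for members in de_results.gene_lists().values():
                de_gene_set |= set(members)
        by_chrom: dict[str, list] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for i, r in enumerate(regions):
            ann = assign_region(r, by_chrom, de_gene_set,
                                region_id=f"region{i + 1}")
            seq = chip_sim.sequences[r.chrom][r.start:r.end]
            ann.hre_hits = scan_hre(seq, mode=config.hre_mode,
                                    strands=config.hre_strands)
            r.genes = ann.assigned_genes
            annotations.append(ann)
        table = pd.DataFrame(
            [
                {"region_id": a.region_id, "coords": f"{a.chrom}:{a.start + 1}-{a.end}",
                 "size": a.end - a.start, "gene": asg.gene_id,
                 "distance": asg.distance, "basis": asg.basis,
                 "context": asg.context, "n_hre": len(a.hre_hits)}
                for a in annotations
                for asg in (a.assignments or [])
            ]
        )
        table.to_csv(out / "assignments.tsv", sep="\t", index=False)
        hio.write_regions(regions, out / "regions.bed", out / "regions.tsv")
        with_hre = sum(1 for a in annotations if a.hre_hits)
        summary["assign"] = {
            "n_assigned_regions": sum(1 for a in annotations if a.assignments),
            "n_target_genes": len({asg.gene_id for a in annotations
                                   for asg in a.assignments}),
            "hre_fraction": with_hre / len(annotations) if annotations else 0.0,
            "context_counts": table["context"].value_counts().to_dict()
            if len(table) else {},
        }
        if de_results is not None:
            xref = cross_reference(annotations, de_results.labels)
            pd.DataFrame(
                [{"row": k, "count": len(v), "genes": ", ".join(v)}
                 for k, v in xref.items()]
            ).to_csv(out / "cross_reference.tsv", sep="\t", index=False)
            summary["cross_reference"] = {k: sorted(v) for k, v in xref.items()}

    if "overlap" in enabled and de_results is not None:
        lists = de_results.gene_lists()
        a = set(lists.get("hypoxia_up", []))
        b = set(lists.get("hif1_positive", []))
        res = fisher_overlap(len(a), len(b), len(a & b), cfg.n_genes,
                             alpha=config.thresholds.overlap_alpha)
        summary["overlap"] = {
            "lists": ["hypoxia_up", "hif1_positive"],
            "n_a": res.n_a, "n_b": res.n_b, "n_ab": res.n_ab,
            "p": res.p, "significant": res.significant,
        }

    if "phenotype" in enabled:
        log.info("simulating and testing phenotypes")
        counts = simulate_phenotype(cfg)
        counts.to_csv(out / "phenotype.tsv", sep="\t", index=False)
        tests = {}
        for genotype, sub in counts.groupby("genotype"):
            for endpoint in ("hatched", "adult"):
                res = survival_test(sub, endpoint=endpoint, seed=cfg.seed)
                tests[f"{genotype}:{endpoint}"] = {
                    "p": res.p, "method": res.method,
                    "proportions": {k: float(v) for k, v in res.proportions.items()},
                }
        summary["phenotype"] = tests

    if de_results is not None and "de" in enabled:
        summary["recovery"] = _recovery_metrics(de_results, truth, regions)

    _write_summary(summary, out)
    return summary


def _recovery_metrics(de_results, truth, regions) -> dict:
    """Score detected gene lists and regions against the planted truth."""
    labels = de_results.labels
    out: dict = {}
    for cls, label in (("hif1_positive", "hif1_positive"),
                       ("hif1_negative", "hif1_negative"),
                       ("hypoxia_up", "hypoxia_up"),
                       ("hypoxia_down", "hypoxia_down")):
        planted = set(truth.genes_of_class(cls))
        if cls.startswith("hypoxia"):
            # HIF-1-dependent genes are also hypoxia-responsive in N2
            extra = "hif1_positive" if cls == "hypoxia_up" else None
            if extra:
                planted |= set(truth.genes_of_class(extra))
        called = set(labels.index[labels[label]]) if label in labels else set()
        tp = len(planted & called)
        out[cls] = {
            "planted": len(planted), "called": len(called),
            "sensitivity": tp / len(planted) if planted else float("nan"),
            "fdr": (len(called) - tp) / len(called) if called else 0.0,
        }
    if len(truth.peaks):
        rep = truth.peaks[truth.peaks["reproducible"]]
        matched = 0
        for _, p in rep.iterrows():
            js = [
                _jaccard((p["start"], p["end"]), (r.start, r.end))
                for r in regions if r.chrom == p["chrom"]
            ]
            if js and max(js) >= 0.66:
                matched += 1
        out["peaks"] = {
            "planted_reproducible": int(len(rep)),
            "regions_called": len(regions),
            "recovered_jaccard_0.66": matched,
        }
    return out


def _jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def _version() -> str:
    from . import __version__

    return __version__


def _write_summary(summary: dict, out: Path) -> None:
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
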