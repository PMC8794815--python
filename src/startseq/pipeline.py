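"""End-to-end orchestration: alignments in, analysis tables out.

``run_all`` executes the full analysis from one :class:`RunConfig`:
read filtering and density assignment for each condition, gene
quantification, log2 TE change, coupling categorization, top-inhibited
selection, start-context motif enrichment, metagene profiles, head
enrichment and its change, the HE/TE Spearman correlation, and the
pairwise group tests. Every stage is a pure function of its inputs and
the config; all tables are TSV and a machine-readable summary plus a
run log (resolved parameters, versions, seed) are written alongside.

``run_demo`` simulates a small data set first and then runs the same
analysis, so the whole pipeline is exercisable without any downloads.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import load_annotation, read_fasta, write_annotation_tsv
from .coupling import categorize_genes
from .density import assign_rna_density, assign_ribo_density, quantify_genes
from .expression import compare_groups, delta_te, select_top_inhibited
from .motif import extract_context, plogo_scores
from .occupancy import (
    delta_head_enrichment,
    head_enrichment_table,
    metagene_profile,
    spearman_he_te,
)
from .reads import read_alignments

log = logging.getLogger(__name__)


@dataclass
class ConditionInput:
    label: str
    ribo_path: str
    rna_path: str
    global_factor: float = 1.0  # residual-translation fraction (35S labeling)


@dataclass
class RunConfig:
    fasta: str
    gff: str
    operons: str
    control: ConditionInput
    treated: ConditionInput
    outdir: str = "startseq_out"
    ribo_length_filter: tuple[int, int] = (20, 45)
    rna_length_filter: tuple[int, int] = (25, 45)
    pseudocount_rpkm: float = 0.1
    pseudocount_he: float = 0.1
    min_rna_rpkm: float = 1.0
    min_ribo_count: float = 32.0
    top_fraction: float = 0.05
    alpha: float = 0.05
    metagene_window: tuple[int, int] = (-30, 61)
    head_window: tuple[int, int] = (0, 15)
    coverage_floor: float = 0.1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("control", "treated"):
            raw[key] = ConditionInput(**raw[key])
        for key in ("ribo_length_filter", "rna_length_filter", "metagene_window", "head_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for p in (self.fasta, self.gff, self.operons,
                  self.control.ribo_path, self.control.rna_path,
                  self.treated.ribo_path, self.treated.rna_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Run every analysis stage; returns the result bundle as a dict of
    DataFrames/values and writes all declared outputs under
    ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("annotation")
        genes = load_annotation(config.gff, config.operons, config.fasta)
        genes = categorize_genes(genes)
        seqs = read_fasta(config.fasta)
        replicon_lengths = {name: len(s) for name, s in seqs.items()}
        write_annotation_tsv(outdir / "annotation.tsv", genes)
    except Exception as exc:  # noqa: BLE001
        raise StageError("annotation", exc) from exc

    tracks = {}
    quants = {}
    for cond in (config.control, config.treated):
        try:
            stage(f"density:{cond.label}")
            ribo_reads = read_alignments(cond.ribo_path, config.ribo_length_filter)
            rna_reads = read_alignments(cond.rna_path, config.rna_length_filter)
            ribo = assign_ribo_density(ribo_reads, replicon_lengths)
            rna = assign_rna_density(rna_reads, replicon_lengths)
            tracks[cond.label] = {"ribo": ribo, "rna": rna}
            quants[cond.label] = quantify_genes(
                ribo, rna, genes,
                min_rna_rpkm=config.min_rna_rpkm,
                min_ribo_count=config.min_ribo_count,
            )
            quants[cond.label].to_csv(outdir / f"quant_{cond.label}.tsv", sep="\t")
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"density:{cond.label}", exc) from exc

    try:
        stage("delta_te")
        delta = delta_te(
            quants[config.treated.label],
            quants[config.control.label],
            pseudocount=config.pseudocount_rpkm,
            genes=genes,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("delta_te", exc) from exc

    try:
        stage("head_enrichment")
        he = {
            label: head_enrichment_table(
                t["ribo"], genes,
                head_window=config.head_window,
                pseudocount=config.pseudocount_he,
            )
            for label, t in tracks.items()
        }
        dhe = delta_head_enrichment(he[config.treated.label], he[config.control.label])
        delta = delta.join(dhe, how="left")
        delta.to_csv(outdir / "delta.tsv", sep="\t")
        try:
            rho = spearman_he_te(delta)
            results["spearman_rho"] = rho.rho
            results["spearman_n"] = rho.n
        except ValueError as exc:
            log.warning("Spearman correlation unavailable: %s", exc)
            results["spearman_rho"] = None
            results["spearman_n"] = 0
    except Exception as exc:  # noqa: BLE001
        raise StageError("head_enrichment", exc) from exc

    try:
        stage("motif")
        top = select_top_inhibited(delta, config.top_fraction)
        contexts = extract_context(genes, seqs)
        universe = contexts.loc[contexts.index.intersection(delta.index)]
        fg = universe.loc[universe.index.intersection(top)]
        motif = plogo_scores(fg, universe, alpha=config.alpha)
        motif.scores.to_csv(outdir / "motif_scores.tsv", sep="\t")
        results["motif_threshold"] = motif.threshold
        results["top_inhibited"] = top
    except Exception as exc:  # noqa: BLE001
        raise StageError("motif", exc) from exc

    try:
        stage("metagene")
        profiles = {}
        for label, t in tracks.items():
            prof = metagene_profile(
                t["ribo"], genes,
                window=config.metagene_window,
                coverage_floor=config.coverage_floor,
            )
            prof.to_csv(outdir / f"metagene_{label}.tsv", sep="\t", index=False)
            profiles[label] = prof
    except Exception as exc:  # noqa: BLE001
        raise StageError("metagene", exc) from exc

    try:
        stage("group_tests")
        groups_minus1 = compare_groups(
            delta, by="minus1_base", test="mann_whitney",
            exclude_top_fraction=config.top_fraction,
        )
        groups_minus1.to_csv(outdir / "groups_minus1.tsv", sep="\t", index=False)
        groups_cat = compare_groups(delta, by="category", test="t_test")
        groups_cat.to_csv(outdir / "groups_category.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("group_tests", exc) from exc

    results.update(
        {
            "genes": genes,
            "quant": quants,
            "tracks": tracks,
            "delta": delta,
            "motif": motif,
            "metagene": profiles,
            "groups_minus1": groups_minus1,
            "groups_category": groups_cat,
        }
    )
    _write_summary(outdir, config, results)
    return results


def _write_summary(outdir: Path, config: RunConfig, results: dict) -> None:
    delta = results["delta"]
    summary = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if not isinstance(v, dict)
        },
        "n_genes_analyzed": int(len(delta)),
        "median_log2_te_change": float(np.nanmedian(delta["log2_te_change"])),
        "top_inhibited_n": len(results["top_inhibited"]),
        "spearman_rho_he_te": results["spearman_rho"],
        "motif_threshold": results["motif_threshold"],
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"startseq {__version__} python {sys.version.split()[0]}\n")
        fh.write(f"seed {config.seed}\n")
        fh.write(f"resolved config: {dataclasses.asdict(config)!r}\n")


def run_demo(outdir: str | Path, seed: int = 0, sim_config=None) -> dict:
    """Simulate a small data set, write all inputs, then run the full
    analysis against the written files (the demo exercises the same
    SAM/FASTA/GFF path a real-data run would take)."""
    from .simulate import SimConfig, build_genome, simulate_riboseq, simulate_rnaseq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = sim_config or SimConfig(n_operons=30, ribo_depth=60_000, rna_depth=60_000, seed=seed)
    cfg = dataclasses.replace(cfg, seed=seed)
    genome = build_genome(cfg)
    paths = genome.write(outdir / "sim")
    sams = {}
    for label, cond in (("control", "control"), ("treated", "drug")):
        ribo = simulate_riboseq(genome, cond, cfg)
        rna = simulate_rnaseq(genome, cfg, condition=cond)
        sams[label] = {
            "ribo": outdir / "sim" / f"ribo_{label}.sam",
            "rna": outdir / "sim" / f"rna_{label}.sam",
        }
        ribo.write_sam(sams[label]["ribo"], genome.sequence)
        rna.write_sam(sams[label]["rna"], genome.sequence)

    run_cfg = RunConfig(
        fasta=str(paths["fasta"]),
        gff=str(paths["gff"]),
        operons=str(paths["operons"]),
        control=ConditionInput("control", str(sams["control"]["ribo"]), str(sams["control"]["rna"])),
        treated=ConditionInput("treated", str(sams["treated"]["ribo"]), str(sams["treated"]["rna"])),
        outdir=str(outdir / "analysis"),
        seed=seed,
    )
    return run_all(run_cfg)
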