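"""End-to-end pipeline: simulate -> classify -> genotype -> map -> report.

Each stage serialises its outputs into a fixed layout under the run
directory and is skipped on re-run when those outputs already exist, so a
run can resume after deleting any stage's files.  A manifest records the
package version, the seed, the echoed config and SHA-256 digests of the key
artifacts; identical configs reproduce identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, io
from .config import PipelineConfig
from .genotyper import build_matrix, scan_all_turning_points, split_markers_at_turning_points
from .linkmap import build_map, pairwise_linkage_table, segregation_screen
from .readclass import classify_isolate
from .report import concordance, summarize_groups, summarize_map, summary_table, truth_accuracy
from .simdata import simulate_meiosis, simulate_parents, simulate_reads

log = logging.getLogger("sporemap")

STAGES = ("simulate", "classify", "genotype", "map", "report")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_done(outdir: Path, files: list[str]) -> bool:
    return all((outdir / f).exists() for f in files)


def run_pipeline(config: PipelineConfig, outdir: str | Path, force: bool = False) -> dict:
    """Run (or resume) the full pipeline; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.sim
    isolates = cfg.isolate_names()
    scaffolds = cfg.scaffold_names()

    sim_files = (
        ["reference.fasta", "parentB.fasta", "catalog.vcf", "scaffold_map.tsv", "truth_genotypes.tsv"]
        + [f"reads/{iso}.fastq" for iso in isolates]
        + [f"aln/{iso}.sam" for iso in isolates]
    )
    stage_outputs = {
        "simulate": sim_files,
        "classify": [f"obs/{iso}.tsv" for iso in isolates] + ["class_summary.json"],
        "genotype": ["matrix.csv", "votes.csv", "turning_points.tsv"],
        "map": ["map.tsv", "segregation.tsv", "pairwise.tsv", "mstmap_input.txt", "mapchart.txt"],
        "report": ["summary.tsv", "summary.json"],
    }

    # -- simulate -------------------------------------------------------------
    if force or not _stage_done(outdir, stage_outputs["simulate"]):
        log.info("stage simulate: generating parents, progeny and reads")
        (outdir / "reads").mkdir(exist_ok=True)
        (outdir / "aln").mkdir(exist_ok=True)
        genomes = simulate_parents(cfg)
        truth = simulate_meiosis(cfg, genomes.scaffold_map)
        reads = simulate_reads(cfg, truth, genomes)
        io.write_fasta(genomes.reference, outdir / "reference.fasta")
        io.write_fasta(genomes.alt, outdir / "parentB.fasta")
        ref_lens = {n: len(s) for n, s in genomes.reference.items()}
        io.write_vcf_catalog(genomes.catalog, outdir / "catalog.vcf", ref_lens)
        io.write_scaffold_map_tsv(genomes.scaffold_map, outdir / "scaffold_map.tsv")
        io.write_truth_tsv(truth, outdir / "truth_genotypes.tsv")
        for iso in isolates:
            io.write_reads_fastq(reads[iso], outdir / "reads" / f"{iso}.fastq")
            io.write_truth_sam(reads[iso], ref_lens, outdir / "aln" / f"{iso}.sam")
    else:
        log.info("stage simulate: outputs present, skipping")

    # -- classify -------------------------------------------------------------
    catalog = io.read_vcf_catalog(outdir / "catalog.vcf")
    if force or not _stage_done(outdir, stage_outputs["classify"]):
        log.info("stage classify: classifying reads against the SNP catalog")
        (outdir / "obs").mkdir(exist_ok=True)
        summaries = {}
        for iso in isolates:
            obs, summary = classify_isolate(
                outdir / "aln" / f"{iso}.sam", catalog, config.classify
            )
            io.write_observations_tsv(obs, outdir / "obs" / f"{iso}.tsv")
            summaries[iso] = summary.proportions
        io.write_json(summaries, outdir / "class_summary.json")
    else:
        log.info("stage classify: outputs present, skipping")

    # -- genotype -------------------------------------------------------------
    smap = io.read_scaffold_map_tsv(outdir / "scaffold_map.tsv")
    scaffold_lengths = smap["length_bp"].to_dict()
    if force or not _stage_done(outdir, stage_outputs["genotype"]):
        log.info("stage genotype: majority-vote calling")
        obs_by_iso = {
            iso: io.read_observations_tsv(outdir / "obs" / f"{iso}.tsv") for iso in isolates
        }
        gopt = config.genotype
        matrix = build_matrix(
            obs_by_iso, list(smap.index), scaffold_lengths, gopt.informative_only
        )
        tps = scan_all_turning_points(
            obs_by_iso,
            list(smap.index),
            gopt.min_segment_reads,
            gopt.min_score,
            gopt.informative_only,
        )
        if gopt.split_at_turning_points and tps:
            matrix = split_markers_at_turning_points(obs_by_iso, matrix, tps, gopt.informative_only)
        io.write_matrix_csv(matrix, outdir / "matrix.csv")
        io.write_votes_csv(matrix, outdir / "votes.csv")
        io.write_turning_points_tsv(tps, outdir / "turning_points.tsv")
    else:
        log.info("stage genotype: outputs present, skipping")

    # -- map ------------------------------------------------------------------
    matrix = io.read_matrix_csv(outdir / "matrix.csv", scaffold_lengths)
    if force or not _stage_done(outdir, stage_outputs["map"]):
        log.info("stage map: two-point linkage mapping")
        lmap = build_map(matrix, config.map)
        seg = segregation_screen(matrix, config.map.alpha)
        retained = list(seg.index[seg.retained])
        pairs = pairwise_linkage_table(matrix, retained, config.map.n_min)
        io.write_map_tsv(lmap, outdir / "map.tsv")
        seg.to_csv(outdir / "segregation.tsv", sep="\t")
        pairs.to_frame().to_csv(outdir / "pairwise.tsv", sep="\t", index=False)
        io.write_mstmap_input(matrix, outdir / "mstmap_input.txt")
        io.write_mapchart_text(lmap, outdir / "mapchart.txt")
    else:
        log.info("stage map: outputs present, skipping")
        lmap = None

    # -- report ---------------------------------------------------------------
    if force or not _stage_done(outdir, stage_outputs["report"]):
        log.info("stage report: map summary statistics")
        if lmap is None:
            lmap = build_map(matrix, config.map)
        genome_size = config.report.genome_size_bp or float(sum(scaffold_lengths.values()))
        # headline groups when any exist; otherwise every group with a positive
        # span (tiny populations often yield only short or zero-span groups)
        candidates = lmap.headline_groups() or [
            g for g in lmap.groups if g.span_cm > 0 and g.n_markers >= 2
        ]
        if candidates:
            rows = [
                (g.name, g.span_cm, g.n_markers,
                 sum(scaffold_lengths[m] for m in g.markers) / 1000.0)
                for g in candidates
            ]
            per_group, summary = summarize_groups(rows, genome_size)
            table = summary_table(per_group, summary)
            payload = dataclasses.asdict(summary)
        else:
            log.warning("no summarisable linkage groups; writing empty summary")
            table = pd.DataFrame()
            payload = {"n_groups": 0, "total_markers": 0}
        table.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        truth_path = outdir / "truth_genotypes.tsv"
        if truth_path.exists():
            truth_parent = (
                pd.read_csv(truth_path, sep="\t")
                .pivot(index="scaffold", columns="isolate", values="parent")
            )
            acc = truth_accuracy(matrix, truth_parent)
            payload["genotyping_accuracy_pct"] = acc.accuracy_pct
            payload["genotyping_cells_compared"] = acc.n_compared
        if config.report.experimental_table:
            exp = pd.read_csv(config.report.experimental_table)
            res = concordance(matrix, exp)
            payload["concordance_accuracy_pct"] = res.accuracy_pct
            payload["concordance_n"] = res.n_compared
        io.write_json(payload, outdir / "summary.json")
    else:
        log.info("stage report: outputs present, skipping")

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": config.to_dict(),
        "digests": {
            f: _digest(outdir / f)
            for stage in STAGES
            for f in stage_outputs[stage]
            if (outdir / f).exists()
        },
    }
    io.write_json(manifest, outdir / "manifest.json")
    with open(outdir / "config.yaml", "w") as fh:
        import yaml

        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return manifest
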