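"""Config-driven orchestration of the full selection-signature analysis.

One run reads a genotype set plus breed assignments, applies the branch
QC profiles, and writes per-stage TSV artifacts:

* ``qc_report_<branch>.tsv`` per QC branch,
* per breed: ``roh_segments_<pop>.tsv``, ``froh_<pop>.tsv``,
  ``incidence_manhattan_<pop>.tsv``, ``islands_<pop>.tsv``,
* per comparison: ``fst_manhattan_<comp>.tsv``, ``fst_significant_<comp>.tsv``,
* ``diversity.tsv``, ``fst_genes.tsv``, ``island_genes.tsv``,
* ``manifest.json`` with config hash and software version.

All outputs are deterministic for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_fst_outliers, annotate_island_members
from .datamodel import GenotypeMatrix
from .diversity import breed_mean_ho, diversity_table, ho_froh_correlation
from .fst import fst_mean, fst_outliers, fst_track, pairwise_comparisons
from .islands import call_islands, incidence
from .plink import (
    assign_populations,
    read_gene_annotation,
    read_plink_binary,
    read_plink_text,
    read_populations,
)
from .qc import apply_qc, qc_profile
from .roh import RohParams, call_roh, froh, resolve_window

logger = logging.getLogger(__name__)

DEFAULT_BRANCHES = ("roh", "islands", "fst", "diversity", "annotate", "structure")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_genotypes(cfg: dict) -> GenotypeMatrix:
    inputs = cfg["inputs"]
    if "bed" in inputs:
        g = read_plink_binary(inputs["bed"], inputs["bim"], inputs["fam"])
    elif "ped" in inputs:
        g = read_plink_text(inputs["ped"], inputs["map"])
    else:
        raise ValueError("config inputs must name bed/bim/fam or ped/map files")
    if "populations" in inputs:
        g = assign_populations(g, read_populations(inputs["populations"]))
    return g


def _check_inputs(cfg: dict) -> None:
    inputs = cfg.get("inputs", {})
    paths = [v for k, v in inputs.items() if k in ("bed", "bim", "fam", "ped", "map", "populations")]
    ann = cfg.get("annotation")
    if ann:
        paths.append(ann["path"])
    missing = [p for p in paths if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    if not paths:
        raise ValueError("config declares no inputs")


def run_pipeline(config, outdir=None) -> Path:
    """Run the full analysis.  ``config`` is a dict or a YAML file path."""
    if not isinstance(config, dict):
        config_text = Path(config).read_text()
        cfg = yaml.safe_load(config_text)
    else:
        cfg = config
        config_text = yaml.safe_dump(cfg, sort_keys=True)
    _check_inputs(cfg)
    out = Path(outdir or cfg.get("output_dir", "rohscan_out"))
    out.mkdir(parents=True, exist_ok=True)
    branches = set(cfg.get("branches", DEFAULT_BRANCHES))

    g = load_genotypes(cfg)
    logger.info("loaded %s", g)

    roh_cfg = cfg.get("roh", {})
    params = RohParams(
        alpha=roh_cfg.get("alpha", 0.05),
        window_overlap_min=roh_cfg.get("window_overlap_min", 0.05),
        max_missing_per_window=roh_cfg.get("max_missing_per_window", 1),
        min_density_bp_per_snp=roh_cfg.get("min_density_bp_per_snp", 150_000),
        max_gap_bp=roh_cfg.get("max_gap_bp", 1_000_000),
        window_snps=roh_cfg.get("window_snps"),
    )
    isl_cfg = cfg.get("islands", {})
    fst_cfg = cfg.get("fst", {})
    flank_bp = int(cfg.get("flank_bp", 100_000))

    froh_tables = []
    members_by_pop = {}
    div_tables = []

    if "roh" in branches or "islands" in branches or "diversity" in branches:
        # breed-by-breed QC and ROH calling
        for pop, sub in g.by_population():
            sub_qc, report = apply_qc(sub, qc_profile("roh"))
            _write_tsv(report.to_frame(), out / f"qc_report_roh_{pop}.tsv")
            if sub_qc.n_markers == 0 or sub_qc.n_samples == 0:
                logger.warning("breed %s empty after QC; skipped", pop)
                continue
            L = resolve_window(sub_qc, params)
            segments = call_roh(sub_qc, params, window_snps=L)
            _write_tsv(segments, out / f"roh_segments_{pop}.tsv")
            ftab = froh(segments, sub_qc.coverage_bp(), sub_qc.sample_ids)
            ftab.insert(1, "population", pop)
            _write_tsv(ftab, out / f"froh_{pop}.tsv")
            froh_tables.append(ftab)

            if "islands" in branches:
                track = incidence(segments, sub_qc)
                _write_tsv(track, out / f"incidence_manhattan_{pop}.tsv")
                islands, members = call_islands(
                    track,
                    p_min=isl_cfg.get("p_min", 0.999),
                    incidence_floor_pct=isl_cfg.get("incidence_floor_pct", 30.0),
                    merge_gap_bp=isl_cfg.get("merge_gap_bp", params.max_gap_bp),
                    fallback_p_min=isl_cfg.get("fallback_p_min", 0.998),
                )
                _write_tsv(islands, out / f"islands_{pop}.tsv")
                members_by_pop[pop] = members

            if "diversity" in branches:
                div = diversity_table(sub_qc)
                div_tables.append(div)

    if froh_tables:
        all_froh = pd.concat(froh_tables, ignore_index=True)
        _write_tsv(all_froh, out / "froh_all_breeds.tsv")

    if "diversity" in branches and div_tables and froh_tables:
        div = pd.concat(div_tables, ignore_index=True)
        merged = div.merge(
            pd.concat(froh_tables)[["sample_id", "froh_all"]], on="sample_id"
        )
        _write_tsv(merged, out / "diversity.tsv")
        _write_tsv(breed_mean_ho(div), out / "diversity_breed_means.tsv")
        try:
            r, p = ho_froh_correlation(div, pd.concat(froh_tables))
        except ValueError as exc:  # degenerate cohort (no ROH / flat Ho)
            logger.warning("Ho~F_ROH correlation skipped: %s", exc)
        else:
            (out / "diversity_correlation.json").write_text(
                json.dumps({"pearson_r": r, "p_value": p}, indent=2) + "\n"
            )

    outliers_by_comp = {}
    if "fst" in branches:
        g_fst, report = apply_qc(g, qc_profile("fst"))
        _write_tsv(report.to_frame(), out / "qc_report_fst.tsv")
        mean_rows = []
        for comp in pairwise_comparisons(g_fst):
            name = "~".join(comp)
            track = fst_track(g_fst, populations=comp)
            mean = fst_mean(track)
            mean_rows.append({"comparison": name, "mean_fst": mean})
            manhattan = track.copy()
            manhattan["fst_plot"] = manhattan["fst"].clip(lower=0.0)
            _write_tsv(
                manhattan[
                    ["marker_id", "chromosome", "position_bp", "fst", "fst_plot", "p_empirical"]
                ],
                out / f"fst_manhattan_{name}.tsv",
            )
            sig = fst_outliers(track, top_fraction=fst_cfg.get("top_fraction", 0.001))
            _write_tsv(sig, out / f"fst_significant_{name}.tsv")
            outliers_by_comp[name] = sig
            logger.info("FST %s: mean %.4f, %d significant SNPs", name, mean, len(sig))
        _write_tsv(pd.DataFrame(mean_rows), out / "fst_means.tsv")

    if "structure" in branches:
        g_struct, report = apply_qc(g, qc_profile("structure"))
        _write_tsv(report.to_frame(), out / "qc_report_structure.tsv")
        g_struct.markers[["marker_id", "chromosome", "position_bp"]].to_csv(
            out / "structure_pruned_markers.tsv", sep="\t", index=False
        )

    if "annotate" in branches and cfg.get("annotation"):
        ann = cfg["annotation"]
        genes = read_gene_annotation(ann["path"], ann.get("format", "bed"))
        if outliers_by_comp:
            _write_tsv(
                annotate_fst_outliers(outliers_by_comp, genes, flank_bp),
                out / "fst_genes.tsv",
            )
        if members_by_pop:
            _write_tsv(
                annotate_island_members(members_by_pop, genes, flank_bp),
                out / "island_genes.tsv",
            )

    manifest = {
        "software": "rohscan",
        "version": __version__,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": cfg.get("seed"),
        "n_samples": int(g.n_samples),
        "n_markers": int(g.n_markers),
        "branches": sorted(branches),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
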