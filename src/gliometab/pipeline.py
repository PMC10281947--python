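"""End-to-end pipeline orchestration from a declarative YAML config.

One config drives every stage: normalization, presence filtering,
perfusate-exclusion masking, per-case ranked lists, top/bottom metabolite
sets, cross-case enrichment, paired exact differential tables, clustering,
and the CSF bloodiness / plasma-contamination analysis.  Every output
table carries a provenance header (input checksums or generator seed,
thresholds, software version), and a rerun with an identical config
produces byte-identical tables.  Unknown config keys abort (strict mode),
and the seed must be explicit — there is no silent default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import hierarchical_cluster, spearman_matrix
from .csf_plasma import paired_bloodiness_list, plasma_enrichment, pooled_bloodiness_list
from .datamodel import Location, PeakAreaMatrix, SampleAnnotation, ValidationError
from .differential import CONTRASTS, paired_contrast_table, volcano_table
from .enrichment import (
    REPORT_FLOOR,
    build_sets_from_list,
    cross_case_enrichment_matrix,
    results_table,
)
from .io import read_annotation, read_peak_matrix, write_rnk, write_set_file
from .preprocess import (
    apply_perfusate_exclusions,
    median_normalize,
    normalizable_subset,
    presence_filter,
    presence_threshold,
)
from .ranking import Contrast, RankedList, average_rank_table, make_ranked_list
from .synthetic import GeneratorConfig, generate_cohort

logger = logging.getLogger("gliometab")

__all__ = ["run_pipeline", "load_config", "report_tables"]

_KNOWN_KEYS = {
    "seed", "simulate", "inputs", "presence_min_fraction", "csf_min_fraction",
    "top_k", "weighting_exponent", "n_permutations", "fdr_threshold",
    "alpha", "fc_threshold", "csf",
}

_DEFAULTS = {
    "presence_min_fraction": 0.90,
    "csf_min_fraction": 0.85,
    "top_k": 35,
    "weighting_exponent": 1.0,
    "n_permutations": 1000,
    "fdr_threshold": 0.05,
    "alpha": 0.05,
    "fc_threshold": 2.0,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in cfg:
        raise ValidationError("config must set an explicit seed")
    if ("simulate" in cfg) == ("inputs" in cfg):
        raise ValidationError("config must set exactly one of 'simulate' or 'inputs'")
    out = dict(_DEFAULTS)
    out.update(cfg)
    return out


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_table(frame: pd.DataFrame, path: Path, meta: dict, index: bool = True) -> None:
    lines = [f"# {k}: {v}" for k, v in meta.items()]
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        frame.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def _load_inputs(cfg: dict) -> tuple[PeakAreaMatrix, SampleAnnotation, dict]:
    meta: dict = {}
    if "simulate" in cfg:
        sim = dict(cfg["simulate"] or {})
        sim.setdefault("seed", cfg["seed"])
        known = {f.name for f in dataclasses.fields(GeneratorConfig)}
        unknown = set(sim) - known
        if unknown:
            raise ValidationError(f"unknown simulate keys: {sorted(unknown)}")
        gen = GeneratorConfig(**sim)
        matrix, annotation, _truth = generate_cohort(gen)
        meta["inputs"] = f"simulated (generator seed {gen.seed})"
    else:
        spec = cfg["inputs"]
        matrix = read_peak_matrix(
            spec["matrix"], orientation=spec.get("orientation", "metabolites_in_rows")
        )
        annotation = read_annotation(spec["annotation"])
        batch = annotation.table["batch"].astype(str).to_dict() \
            if "batch" in annotation.table.columns else {}
        matrix = PeakAreaMatrix(values=matrix.values, layer=matrix.layer,
                                batch_of=batch)
        meta["inputs"] = (f"matrix sha256 {_sha256(spec['matrix'])}; "
                          f"annotation sha256 {_sha256(spec['annotation'])}")
    annotation = annotation.for_matrix(matrix)
    return matrix, annotation, meta


def _case_lists(
    matrix: PeakAreaMatrix, annotation: SampleAnnotation, label: str
) -> list[RankedList]:
    """Per-case ranked lists for one location contrast, cases with both
    catheters only."""
    loc_a, loc_b = CONTRASTS[label]
    lists = []
    for case in annotation.cases():
        if annotation.table.loc[annotation.table["case_id"] == case, "location"].iloc[0] == Location.CSF.value:
            continue
        sa = annotation.sample_for(case, loc_a)
        sb = annotation.sample_for(case, loc_b)
        if sa is None or sb is None:
            continue
        contrast = Contrast.paired(sa, sb, label)
        lists.append(
            make_ranked_list(matrix, contrast, annotation,
                             name=f"{case}:{label}")
        )
    return lists


def run_pipeline(config_path: str | Path, outdir: str | Path) -> Path:
    """Run every stage on the configured inputs; write the output tree.

    Returns the output directory.  Outputs: normalized matrix, ranked
    lists (RNK), metabolite sets (GMT), cross-case NES matrices,
    differential and volcano tables, correlation/linkage tables, CSF
    bloodiness lists and plasma-enrichment summary, and a provenance log.
    """
    cfg = load_config(config_path)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    raw, annotation, meta = _load_inputs(cfg)
    meta.update({
        "gliometab_version": __version__,
        "seed": seed,
        "presence_min_fraction": cfg["presence_min_fraction"],
        "csf_min_fraction": cfg["csf_min_fraction"],
        "top_k": cfg["top_k"],
        "weighting_exponent": cfg["weighting_exponent"],
        "n_permutations": cfg["n_permutations"],
        "fdr_threshold": cfg["fdr_threshold"],
        "alpha": cfg["alpha"],
        "fc_threshold": cfg["fc_threshold"],
    })

    micro_samples = [s for s in raw.sample_ids
                     if annotation.table.loc[s, "location"] != Location.CSF.value]
    csf_samples = [s for s in raw.sample_ids
                   if annotation.table.loc[s, "location"] == Location.CSF.value]
    micro_raw, micro_dropped = normalizable_subset(
        raw.copy_with(raw.values[micro_samples]))
    micro = median_normalize(micro_raw)
    meta["n_unnormalizable_microdialysate"] = len(micro_dropped)
    threshold = presence_threshold(micro.n_samples, cfg["presence_min_fraction"])
    filtered, n_kept = presence_filter(micro, cfg["presence_min_fraction"])
    logger.info("presence filter: threshold %d of %d samples; %d metabolites kept",
                threshold, micro.n_samples, n_kept)
    meta["presence_threshold"] = f"{threshold}/{micro.n_samples}"
    meta["n_metabolites_kept"] = n_kept
    masked, exclusion_log = apply_perfusate_exclusions(filtered, annotation)
    _write_table(masked.values, out / "normalized_filtered_matrix.tsv", meta)
    if len(exclusion_log):
        _write_table(exclusion_log, out / "perfusate_exclusions.tsv", meta, index=False)

    # --- ranked lists and sets --------------------------------------------
    lists_by_contrast: dict[str, list[RankedList]] = {}
    for label, fname in (("E/B", "E_vs_B"), ("E/NE", "E_vs_NE"), ("NE/B", "NE_vs_B")):
        lists = _case_lists(masked, annotation, label)
        lists_by_contrast[label] = lists
        for rl in lists:
            write_rnk(rl.entries, out / f"ranked_{fname}_{rl.name.split(':')[0]}.rnk")
    enrichment_frames = []
    for label, fname in (("E/B", "E_vs_B"), ("E/NE", "E_vs_NE")):
        lists = lists_by_contrast[label]
        if len(lists) < 2:
            continue
        sets, self_of = [], {}
        for rl in lists:
            top, bottom = build_sets_from_list(rl, k=cfg["top_k"])
            sets += [top, bottom]
            self_of[top.name] = rl.name
            self_of[bottom.name] = rl.name
        write_set_file(sets, out / f"sets_{fname}.gmt")
        nes, stars, results = cross_case_enrichment_matrix(
            lists, sets, weighting_exponent=cfg["weighting_exponent"],
            n_permutations=cfg["n_permutations"], seed=seed, self_of=self_of,
            fdr_threshold=cfg["fdr_threshold"],
        )
        _write_table(nes, out / f"nes_matrix_{fname}.tsv", meta)
        _write_table(stars, out / f"nes_stars_{fname}.tsv", meta)
        enrichment_frames.append(results_table(results).assign(contrast=label))
        rank_table = average_rank_table(lists)
        _write_table(rank_table, out / f"average_ranks_{fname}.tsv", meta)
    if enrichment_frames:
        _write_table(pd.concat(enrichment_frames, ignore_index=True),
                     out / "enrichment_results.tsv", meta, index=False)

    # --- differential abundance -------------------------------------------
    diff_results = {}
    for label, fname in (("E/B", "E_vs_B"), ("E/NE", "E_vs_NE"), ("NE/B", "NE_vs_B")):
        try:
            results, untestable = paired_contrast_table(
                masked, annotation, contrast=label,
                alpha=cfg["alpha"], fc_threshold=cfg["fc_threshold"],
            )
        except ValidationError as err:
            logger.info("skipping %s differential: %s", label, err)
            continue
        diff_results[label] = results
        volcano = volcano_table(results)
        counts = volcano.attrs["class_counts"]
        vmeta = dict(meta, n_up=counts["up"], n_down=counts["down"],
                     n_untestable=len(untestable))
        _write_table(volcano, out / f"volcano_{fname}.tsv", vmeta, index=False)

    # --- clustering ---------------------------------------------------------
    rho, undefined = spearman_matrix(masked)
    _write_table(rho, out / "spearman_correlation.tsv",
                 dict(meta, n_undefined_pairs=len(undefined)))
    cluster = hierarchical_cluster(masked, scaling="autoscale")
    linkage = pd.DataFrame(cluster.linkage,
                           columns=["left", "right", "height", "size"])
    _write_table(linkage, out / "ward_linkage.tsv", meta, index=False)
    (out / "ward_dendrogram.nwk").write_text(cluster.to_newick() + "\n")

    # --- CSF bloodiness and plasma contamination ----------------------------
    plasma_summary: dict = {}
    if csf_samples:
        csf_raw, _csf_dropped = normalizable_subset(
            raw.copy_with(raw.values[csf_samples]))
        csf = median_normalize(csf_raw)
        csf_cfg = dict(cfg.get("csf") or {})
        universe = masked.metabolite_ids
        bl = csf_cfg.get("bloody_sample")
        cl = csf_cfg.get("clean_sample")
        bloodiness = None
        if bl and cl:
            bloodiness = paired_bloodiness_list(csf, bl, cl, universe)
            write_rnk(bloodiness.entries, out / "bloodiness_paired.rnk")
            meta["bloodiness_paired_n"] = len(bloodiness)
        heme = annotation.table.loc[csf_samples, "heme"]
        if heme.notna().sum() >= 8:
            exclude = list(csf_cfg.get("exclude", []))
            if bl and cl:
                exclude += [bl, cl]  # the paired subject stays out of the pools
            pooled = pooled_bloodiness_list(
                csf, heme, universe, exclude=exclude,
                csf_min_fraction=cfg["csf_min_fraction"],
            )
            write_rnk(pooled.entries, out / "bloodiness_pooled.rnk")
            if bloodiness is None:
                bloodiness = pooled
        if bloodiness is not None and lists_by_contrast.get("E/NE"):
            table, results, plasma_summary = plasma_enrichment(
                lists_by_contrast["E/NE"], bloodiness, k=cfg["top_k"],
                weighting_exponent=cfg["weighting_exponent"],
                n_permutations=cfg["n_permutations"], seed=seed,
                fdr_threshold=cfg["fdr_threshold"],
            )
            _write_table(table, out / "plasma_enrichment_E_vs_NE.tsv",
                         dict(meta, **plasma_summary), index=False)

    # --- report -------------------------------------------------------------
    if diff_results:
        report = report_tables(diff_results, alpha=cfg["alpha"])
        _write_table(report, out / "differential_summary.tsv", meta)
    with open(out / "provenance.log", "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k}: {v}\n")
        for k, v in plasma_summary.items():
            fh.write(f"plasma_{k}: {v}\n")
    return out


def format_p(p: float) -> str:
    """Render a p-value to 4 decimal places (machine tables keep full
    precision)."""
    return f"{p:.4f}"


def format_q(q_raw: float, q: float) -> str:
    return "<1e-05" if q_raw == 0 else f"{q:.4g}"


def report_tables(
    diff_results: dict, alpha: float = 0.05
) -> pd.DataFrame:
    """Three-contrast differential summary: mean FC and p per contrast,
    p rendered to 4 decimals with ``**`` marking p < alpha (bolding rule),
    rows ordered by descending E/B (or first available) mean FC."""
    frames = {}
    for label, results in diff_results.items():
        frames[label] = pd.DataFrame(
            {
                "metabolite": [r.metabolite_id for r in results],
                f"mean_fc {label}": [round(r.mean_fc, 2) for r in results],
                f"p {label}": [
                    format_p(r.p_two_sided)
                    + ("**" if r.p_two_sided < alpha else "")
                    for r in results
                ],
                f"_fc_{label}": [r.mean_fc for r in results],
            }
        ).set_index("metabolite")
    merged = pd.concat(frames.values(), axis=1, join="outer")
    sort_col = next(c for c in merged.columns if c.startswith("_fc_"))
    merged = merged.sort_values(sort_col, ascending=False, kind="mergesort")
    merged = merged[[c for c in merged.columns if not c.startswith("_fc_")]]
    merged.index.name = "metabolite"
    return merged
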