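"""End-to-end run: filter -> diversity/structure -> Fst -> estimators ->
ROH -> HBD, with every stage artifact written to the output directory.

The merged configuration (package defaults < config file < explicit
overrides) is echoed verbatim into the output directory so any threshold
appearing in any table can be traced; a JSON manifest lists every artifact.
Outputs carry no timestamps, so a re-run with the same inputs and seed is
byte-identical.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fcoef, hbd, popdiv, roh
from .genotype_io import (FilterConfig, apply_filters, read_vcf, write_bed,
                          write_tsv)

logger = logging.getLogger(__name__)

DEFAULTS: dict = {
    "filter": {
        "min_depth": 6,
        "min_call_rate_variant": 0.9,
        "min_call_rate_sample": 0.9,
        "min_maf": 0.01,
        "hwe_alpha": 1e-6,
        "autosomes": None,
    },
    "prune": {"r2_max": 0.9, "window_snps": 50, "step_snps": 5},
    "fst": {"window": 200_000, "step": 100_000, "k_sd": 3.5},
    "inbreeding": {"min_snps_degraded": 1000, "exclude_focal": False},
    "roh": {
        "window_snps": 15,
        "max_missing_in_window": 1,
        "max_het_in_window": 1,
        "snp_in_run_threshold": 0.05,
        "min_snps": 20,
        "min_length_bp": 500_000,
        "min_density_bp_per_snp": 200_000,
        "max_gap_bp": 1_000_000,
        "incidence_frac": 0.70,
        "incidence_flank": 100_000,
    },
    "hbd": {
        "n_classes": 7,
        "rate_base": 2.0,
        "err": 0.001,
        "cm_per_mb": 1.0,
        "min_post": 0.5,
    },
}


def merge_config(config_file=None, overrides: dict | None = None) -> dict:
    """Package defaults < config file < overrides."""
    cfg = copy.deepcopy(DEFAULTS)

    def deep_update(base, other):
        for k, v in other.items():
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                deep_update(base[k], v)
            else:
                base[k] = v

    if config_file is not None:
        with open(config_file) as fh:
            deep_update(cfg, yaml.safe_load(fh) or {})
    if overrides:
        deep_update(cfg, overrides)
    return cfg


def run_pipeline(vcf_path, pop_map, outdir, config_file=None,
                 overrides: dict | None = None) -> Path:
    """Run the full analysis and write all artifacts under ``outdir``."""
    cfg = merge_config(config_file, overrides)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "config.yaml").open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    artifacts = {}

    def emit(name, obj, writer=write_tsv):
        path = outdir / name
        writer(obj, path)
        artifacts[name.split(".")[0]] = name

    # --- filtering ---------------------------------------------------
    fc = cfg["filter"]
    G = read_vcf(vcf_path, pop_map, min_depth=fc["min_depth"])
    G, report = apply_filters(G, FilterConfig(
        min_depth=fc["min_depth"],
        min_call_rate_variant=fc["min_call_rate_variant"],
        min_call_rate_sample=fc["min_call_rate_sample"],
        min_maf=fc["min_maf"],
        hwe_alpha=fc["hwe_alpha"],
        autosomes=None if fc["autosomes"] is None
        else frozenset(fc["autosomes"]),
    ))
    emit("filter_report.tsv", report.as_frame())

    # --- diversity / structure ---------------------------------------
    emit("site_stats.tsv", popdiv.site_stats(G))
    P = popdiv.prune(G, **cfg["prune"])
    g = popdiv.grm(P)
    emit("relatedness.tsv", g.offdiag_summary())
    k = min(3, P.n_samples)
    scores, var_exp = popdiv.pca(g, k=k)
    scores = scores.copy()
    for i, v in enumerate(var_exp):
        scores.attrs[f"var_explained_PC{i + 1}"] = float(v)
    emit("pca_scores.tsv", scores)

    two_pops = len(G.populations) == 2
    summary_extra = {}
    if two_pops:
        fw = popdiv.windowed_fst(G, window=cfg["fst"]["window"],
                                 step=cfg["fst"]["step"])
        emit("fst_windows.tsv", fw)
        regions = popdiv.significant_regions(fw, k_sd=cfg["fst"]["k_sd"])
        emit("fst_regions.tsv", regions)
        emit("fst_regions.bed", regions, writer=write_bed)
        defined = fw["weighted_fst"].dropna()
        summary_extra.update(
            fst_mean=float(defined.mean()), fst_sd=float(defined.std(ddof=1)),
            fst_threshold=float(regions.attrs["threshold"]),
            n_fst_regions=int(len(regions)),
            genome_wide_fst=popdiv.genome_wide_fst(G),
        )

    # --- inbreeding estimators (on the pruned set) --------------------
    ib = fcoef.inbreeding_table(
        P, min_snps_degraded=cfg["inbreeding"]["min_snps_degraded"],
        exclude_focal=cfg["inbreeding"]["exclude_focal"])

    # --- ROH ----------------------------------------------------------
    rc = cfg["roh"]
    roh_cfg = roh.RohConfig(
        window_snps=rc["window_snps"],
        max_missing_in_window=rc["max_missing_in_window"],
        max_het_in_window=rc["max_het_in_window"],
        snp_in_run_threshold=rc["snp_in_run_threshold"],
        min_snps=rc["min_snps"],
        min_length_bp=rc["min_length_bp"],
        min_density_bp_per_snp=rc["min_density_bp_per_snp"],
        max_gap_bp=rc["max_gap_bp"],
    )
    segments = roh.detect_roh(P, roh_cfg)
    emit("roh_segments.tsv", segments)
    froh = roh.f_roh(segments, P)
    incidence = roh.roh_incidence(segments, P, frac=rc["incidence_frac"],
                                  flank=rc["incidence_flank"])
    emit("roh_incidence_regions.tsv", incidence)
    emit("roh_incidence_regions.bed", incidence, writer=write_bed)

    # --- HBD ----------------------------------------------------------
    hc = cfg["hbd"]
    core = P.take_samples(~P.degraded)
    model = hbd.HbdModel(n_classes=hc["n_classes"], rate_base=hc["rate_base"],
                         err=hc["err"], cm_per_mb=hc["cm_per_mb"])
    result = hbd.fit_em(core, model, min_post=hc["min_post"])
    emit("hbd_autozygosity.tsv", result.autozygosity)
    emit("hbd_segments.tsv", result.segments)
    emit("hbd_segments.bed",
         result.segments.rename(columns={})[["chrom", "start", "end"]]
         if len(result.segments) else result.segments,
         writer=write_bed)

    # --- consolidated tables ------------------------------------------
    table = ib.merge(froh.drop(columns="population"), on="sample", how="left")
    table = table.merge(
        result.autozygosity[["sample", "f_hbd"]], on="sample", how="left")
    emit("inbreeding_table.tsv", table)
    emit("inbreeding_summary.tsv", fcoef.population_summary(table))
    corr_r, corr_p = popdiv.estimator_correlations(
        table[["f_hom", "f_lh", "f_vr1", "f_vr2", "f_yan"]])
    emit("estimator_correlations.tsv", corr_r.reset_index(names="estimator"))

    summary = {
        "n_samples": G.n_samples,
        "n_variants_filtered": G.n_variants,
        "n_variants_pruned": P.n_variants,
        "n_roh": int(len(segments)),
        "roh_mean_length": float(segments["length"].mean())
        if len(segments) else float("nan"),
        "roh_median_length": float(segments["length"].median())
        if len(segments) else float("nan"),
        "n_hbd_segments": int(len(result.segments)),
        **summary_extra,
    }
    with (outdir / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    artifacts["summary"] = "summary.json"
    with (outdir / "manifest.json").open("w") as fh:
        json.dump({"artifacts": artifacts, "config": "config.yaml"},
                  fh, indent=2, sort_keys=True)
    return outdir
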