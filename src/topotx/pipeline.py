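"""End-to-end orchestration of the synthetic study.

``run_pipeline`` executes every stage on one simulated experiment —
simulate, spike-in normalization, global mRNA levels, SLR tables and
deregulated fractions, covariate trend analysis, derived gene features,
set-overlap enrichment and the profile correlation screen, TSS nucleosome
meta-profiles with the NFR test, and qPCR time courses — writing tabular
outputs (TSV), a machine-readable summary (JSON) and a run manifest that
records the configuration, the seed, every dialect decision and the SHA-256
checksum of each written file.  A run is a pure function of the manifest's
configuration: re-running from it reproduces every checksum.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from . import synthetic
from .enrichment import (
    annotation_enrichment,
    compendium_correlation_screen,
    hypergeometric_overlap,
)
from .features import (
    group_feature_ttest,
    plasticity as plasticity_measure,
    transcriptional_activity,
)
from .normalization import (
    compute_slr,
    deregulated_fraction,
    fit_spikein_scale,
    global_mrna_level,
    replicate_slr,
)
from .nucleosome import (
    NucleosomeTrack,
    align_to_tss,
    meta_profile,
    nfr_occupancy_test,
    select_extreme_genes,
)
from .qpcr import chip_timecourse, expression_timecourse, timecourse_normalize
from .synthetic import SimulationConfig
from .trends import moving_average_trend, pearson_with_permutation, rank_sum_compare

__all__ = ["run_pipeline", "rerun_from_manifest", "DIALECT"]

logger = logging.getLogger(__name__)

# Every analysis convention that the outputs depend on, recorded verbatim in
# the manifest so a run can be interpreted and reproduced without the code.
DIALECT = {
    "normalization_anchor": "median-of-ratios vs geometric-mean spike-in pseudo-array",
    "detection_floor": "mean wild-type normalized intensity >= floor",
    "slr": "mean of replicate log2(max(I, floor)), mutant minus wild-type, unpaired",
    "moving_average": "trailing windows of exactly `window` genes, step 1, no padding",
    "trend_tie_break": "covariate ties broken by gene_id",
    "permutation_p": "two-sided; exact enumeration when n! <= n_perm, else add-one estimate",
    "ranksum": "midrank ties; exact enumeration for combined n <= 12, else normal approx with continuity correction",
    "responsiveness_sd": "sample sd (n-1) over per-gene mean squared ratios",
    "hypergeometric_tail": "upper tail P(X >= k), enrichment only",
    "percentile_ties": "included on the extreme side",
    "nfr_window": "[-200, 0) bp relative to TSS",
    "profile_window": "[-500, +500) bp relative to TSS",
    "ci": "t-distribution 95% interval",
    "qpcr_model": "quantity = efficiency**(-Ct), efficiency 2.0",
}


def _log_stage(name: str, t0: float) -> None:
    logger.info("stage %-14s %6.2fs", name, time.perf_counter() - t0)


def run_pipeline(
    config: SimulationConfig,
    outdir,
    floor: float = 1.0,
    window: int = 200,
    n_perm: int = 999,
    n_extreme: int = 100,
    write_track: bool = True,
) -> dict:
    """Run the full synthetic study; returns the summary dictionary.

    ``window`` and ``n_extreme`` are clipped to what the configured gene count
    supports, so small test configurations run unchanged.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict = {}

    def save_frame(frame: pd.DataFrame, name: str, index=True) -> None:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=index)
        files[name] = path

    window = max(2, min(window, config.n_genes // 8))
    n_extreme = max(1, min(n_extreme, config.n_genes // 3))

    # -- simulate ----------------------------------------------------------
    t0 = time.perf_counter()
    genome = synthetic.simulate_genome(config)
    sim = synthetic.simulate_arrays(config, genome.annotation)
    compendium = synthetic.simulate_compendium(config, genome.annotation)
    profiles = synthetic.simulate_profile_library(config, sim.truth)
    categories = synthetic.simulate_categories(config, genome.annotation)
    qpcr_sim = synthetic.simulate_qpcr(config)
    track = NucleosomeTrack.from_simulation(genome.track)

    sim.matrix.to_tsv(outdir / "expression.tsv")
    files["expression.tsv"] = outdir / "expression.tsv"
    tio.write_annotation(genome.annotation, outdir / "annotation.tsv")
    files["annotation.tsv"] = outdir / "annotation.tsv"
    tio.write_bed6(genome.annotation, outdir / "genes.bed")
    files["genes.bed"] = outdir / "genes.bed"
    if write_track:
        track.to_bedgraph(outdir / "nucleosome.bedgraph")
        files["nucleosome.bedgraph"] = outdir / "nucleosome.bedgraph"
    save_frame(qpcr_sim.expression, "qpcr_expression.tsv", index=False)
    save_frame(qpcr_sim.chip, "qpcr_chip.tsv", index=False)
    tio.write_config(config.to_dict(), outdir / "config.yaml")
    files["config.yaml"] = outdir / "config.yaml"
    _log_stage("simulate", t0)

    summary: dict = {"seed": config.seed, "n_genes": config.n_genes, "window": window}

    # -- normalize ---------------------------------------------------------
    t0 = time.perf_counter()
    result = fit_spikein_scale(sim.matrix)
    mutants = list(config.mutant_specs())
    full = config.full_mutant()
    norm_report = {"scale_factors": result.scale_factors.to_dict(), "anchor": result.reference}
    summary["global_mrna_level"] = {}
    summary["deregulated"] = {}
    slr_tables = {}
    for mutant in mutants:
        level = global_mrna_level(result, mutant, synthetic.WILDTYPE, floor=floor)
        summary["global_mrna_level"][mutant] = {
            "percent": level["percent"],
            "sd": level["sd"],
            "n_genes": level["n_genes"],
        }
        table = compute_slr(result, mutant, synthetic.WILDTYPE, floor=floor)
        slr_tables[mutant] = table
        save_frame(table, f"slr_{mutant}.tsv")
        reps = replicate_slr(result, mutant, synthetic.WILDTYPE, floor=floor)
        detect = table["detectable"]
        summary["deregulated"][mutant] = {
            "twofold": deregulated_fraction(
                table.loc[detect, "slr"], 1.0, -1.0, per_replicate=reps.loc[detect]
            ),
            "asymmetric": deregulated_fraction(
                table.loc[detect, "slr"], 0.5, -1.0, per_replicate=reps.loc[detect]
            ),
        }
    tio.write_json(norm_report, outdir / "normalization.json")
    files["normalization.json"] = outdir / "normalization.json"
    _log_stage("normalize", t0)

    # -- trends ------------------------------------------------------------
    t0 = time.perf_counter()
    ann = genome.annotation
    table = slr_tables[full]
    slr = table["slr"]
    activity, _rejected = transcriptional_activity(ann["abundance_wt"], ann["half_life"])
    covariates = {
        "abundance": ann["abundance_wt"],
        "activity": activity,
        "length": ann["transcript_length"].astype(float),
    }
    trend_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(100,)))
    summary["trends"] = {}
    for name, cov in covariates.items():
        shared = slr.index.intersection(cov.dropna().index)
        curve = moving_average_trend(
            cov.loc[shared].to_numpy(),
            slr.loc[shared].to_numpy(),
            window=window,
            ids=shared.to_numpy(),
        )
        save_frame(curve.to_frame(), f"trend_slr_vs_{name}.tsv", index=False)
        corr = pearson_with_permutation(
            cov.loc[shared].to_numpy(), slr.loc[shared].to_numpy(),
            n_perm=n_perm, rng=trend_rng,
        )
        summary["trends"][name] = {"r": corr["r"], "p": corr["p"], "n": len(shared)}

    short = slr.loc[ann.index[ann["transcript_length"] < 500]].dropna()
    long = slr.loc[ann.index[ann["transcript_length"] > 4500]].dropna()
    if len(short) and len(long):
        ranksum = rank_sum_compare(short.to_numpy(), long.to_numpy())
        summary["trends"]["length_groups"] = {
            "U": ranksum["U"],
            "p": ranksum["p"],
            "method": ranksum["method"],
            "n_short": len(short),
            "n_long": len(long),
        }
    _log_stage("trends", t0)

    # -- features ----------------------------------------------------------
    t0 = time.perf_counter()
    plast = plasticity_measure(compendium)
    features = pd.DataFrame({"activity": activity, "plasticity": plast, "slr": slr})
    features["telomere_distance"] = ann["telomere_distance"].astype(float)
    save_frame(features, "features.tsv")

    plast_curve = moving_average_trend(
        slr.to_numpy(), plast.reindex(slr.index).to_numpy(),
        window=window, ids=slr.index.to_numpy(),
    )
    save_frame(plast_curve.to_frame(), "trend_plasticity_vs_slr.tsv", index=False)
    # U-shape summary: plasticity at both SLR extremes vs the middle
    # (outermost ~1% of windows against the central band).
    k = plast_curve.n_windows
    edge = max(1, k // 100)
    mid_lo, mid_hi = (k - edge) // 2, (k - edge) // 2 + edge
    summary["plasticity_curve"] = {
        "low_slr_extreme": float(np.mean(plast_curve.y_points[:edge])),
        "middle": float(np.mean(plast_curve.y_points[mid_lo:mid_hi])),
        "high_slr_extreme": float(np.mean(plast_curve.y_points[-edge:])),
    }

    detect = table["detectable"]
    up_set = slr.index[(slr >= 1.0) & detect]
    down_set = slr.index[(slr <= -1.0) & detect]
    dereg_set = up_set.union(down_set)
    summary["responsiveness_ttests"] = {}
    for name, members in (("up", up_set), ("down", down_set), ("deregulated", dereg_set)):
        if 2 <= len(members) <= len(plast) - 2:
            res = group_feature_ttest(plast, members, alternative="greater")
            summary["responsiveness_ttests"][name] = {
                "t": res["t"], "df": res["df"], "p": res["p"],
                "mean_group": res["mean_a"], "mean_rest": res["mean_b"],
            }
    if 2 <= len(dereg_set) <= len(features) - 2:
        tel = group_feature_ttest(
            features["telomere_distance"], dereg_set, alternative="two-sided"
        )
        summary["telomere_ttest"] = {"t": tel["t"], "df": tel["df"], "p": tel["p"]}
    _log_stage("features", t0)

    # -- enrichment --------------------------------------------------------
    t0 = time.perf_counter()
    universe = slr.index[detect]
    summary["set_overlaps"] = {}
    for name, col in (("tata", "tata"), ("saga", "saga")):
        member = ann.index[ann[col]].intersection(universe)
        k_overlap = len(dereg_set.intersection(member))
        summary["set_overlaps"][name] = {
            "k": k_overlap,
            "set_size": len(member),
            "dereg_size": len(dereg_set),
            "p": hypergeometric_overlap(
                k_overlap, len(member), len(dereg_set), len(universe)
            ),
        }
    if len(dereg_set):
        enriched = annotation_enrichment(dereg_set, categories, universe=universe)
    else:
        enriched = pd.DataFrame(
            columns=["category_id", "k", "f", "set_size", "universe_size", "p", "p_bonferroni"]
        )
    save_frame(enriched, "category_enrichment.tsv", index=False)
    summary["category_enrichment"] = enriched.to_dict(orient="records")

    screen_seed = int(
        np.random.SeedSequence(config.seed, spawn_key=(101,)).generate_state(1)[0] % (2**31)
    )
    screen = compendium_correlation_screen(
        slr, profiles, min_overlap=min(100, config.n_genes // 2),
        n_perm=n_perm, seed=screen_seed,
    )
    save_frame(screen, "profile_screen.tsv", index=False)
    summary["profile_screen_top"] = (
        screen.iloc[0].to_dict() if len(screen) else None
    )
    _log_stage("enrichment", t0)

    # -- nucleosome --------------------------------------------------------
    t0 = time.perf_counter()
    tss = align_to_tss(track, ann, upstream=500, downstream=500)
    groups = select_extreme_genes(table.loc[detect], n=n_extreme)
    summary["nucleosome"] = {"group_size": n_extreme}
    for name, members in list(groups.items()) + [("all", list(tss.data.index))]:
        profile = meta_profile(tss, members)
        save_frame(profile, f"metaprofile_{name}.tsv", index=False)
    for name in ("most_down", "most_up"):
        res = nfr_occupancy_test(tss, groups[name], groups["most_unaffected"])
        summary["nucleosome"][f"nfr_{name}_vs_unaffected"] = {
            "mean_difference": res["mean_difference"],
            "t": res["t"],
            "df": res["df"],
            "p": res["p"],
        }
    _log_stage("nucleosome", t0)

    # -- qPCR --------------------------------------------------------------
    t0 = time.perf_counter()
    summary["qpcr"] = {"chip": {}, "expression": {}}
    for locus in config.chip_kinetics:
        summary["qpcr"]["chip"][locus] = {}
        for strain in config.chip_kinetics[locus]:
            series = chip_timecourse(qpcr_sim.chip, locus, strain=strain)
            norm = timecourse_normalize(series, mode="t0_to_1")
            summary["qpcr"]["chip"][locus][strain] = {
                "normalized": {str(t): float(v) for t, v in norm["normalized"].items()},
                "fold_increase": norm["fold_increase"],
            }
    for locus in config.expression_kinetics:
        per_strain = config.expression_kinetics[locus]
        if synthetic.WILDTYPE not in per_strain:
            continue
        wt_series = expression_timecourse(qpcr_sim.expression, locus, strain=synthetic.WILDTYPE)
        summary["qpcr"]["expression"][locus] = {}
        for strain in per_strain:
            series = expression_timecourse(qpcr_sim.expression, locus, strain=strain)
            norm = timecourse_normalize(series, mode="wt_max_100", reference=wt_series)
            summary["qpcr"]["expression"][locus][strain] = {
                "normalized_pct": {str(t): float(v) for t, v in norm["normalized"].items()},
                "fold_increase": norm["fold_increase"],
            }
    _log_stage("qpcr", t0)

    # -- report ------------------------------------------------------------
    tio.write_json(summary, outdir / "summary.json")
    files["summary.json"] = outdir / "summary.json"
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "dialect": DIALECT,
        "parameters": {
            "floor": floor,
            "window": window,
            "n_perm": n_perm,
            "n_extreme": n_extreme,
        },
        "checksums": {name: tio.sha256_of(path) for name, path in sorted(files.items())},
    }
    tio.write_json(manifest, outdir / "manifest.json")
    summary["manifest"] = manifest
    return summary


def rerun_from_manifest(manifest: dict, outdir) -> dict:
    """Re-execute a run from its manifest; outputs are checksum-identical."""
    config = _config_from_dict(manifest["config"])
    params = manifest["parameters"]
    return run_pipeline(
        config,
        outdir,
        floor=params["floor"],
        window=params["window"],
        n_perm=params["n_perm"],
        n_extreme=params["n_extreme"],
        write_track="nucleosome.bedgraph" in manifest["checksums"],
    )


def _config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key in ("chip_kinetics", "expression_kinetics"):
        d[key] = {
            locus: {
                strain: synthetic.Kinetics(
                    timepoints=tuple(k["timepoints"]), fold=tuple(k["fold"])
                )
                for strain, k in per.items()
            }
            for locus, per in d[key].items()
        }
    if d.get("mutants") is not None:
        d["mutants"] = {
            m: synthetic.MutantSpec(**spec) for m, spec in d["mutants"].items()
        }
    return SimulationConfig(**d)
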