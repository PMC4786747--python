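"""End-to-end orchestration: simulate or load inputs, run every stage, and
write per-stage CSVs plus one machine-readable JSON report.

The configuration is a flat JSON-able dict with a fixed schema; unknown keys
are rejected so typos fail loudly.  All randomness flows from a single seed
recorded in the report, and reruns with the same config are deterministic.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate as sim
from .strat import BinSequence, read_bins, read_ranges, write_bins, write_ranges
from .charmatrix import read_nexus_matrix, write_nexus_matrix
from .trees import read_trees, write_trees
from .timescale import timescale_set
from .diversity import taxic_diversity, phylo_diversity
from .disparity import (
    pairwise_dissimilarity,
    binned_dissimilarity,
    pcoa,
    axes_for_variance,
    presence_table,
    sum_of_variances,
)
from .ancstates import reconstruct_ancestors
from .rates import (
    cladogenesis_per_bin,
    extinction_per_bin,
    per_lineage_extinction,
    turnover,
)
from .ecomorph import (
    scale_traits,
    multiscale_bootstrap_support,
    cut_guilds,
    guilds_per_bin,
)
from .extinction import (
    prob_zero,
    freq_upper_bound,
    recovery_rate,
    poisson_extension,
    strauss_sadler_extension,
)
from .envcorr import run_windows

log = logging.getLogger("cladewane")

CONFIG_DEFAULTS: dict = {
    "simulate": True,          # generate a synthetic bundle instead of reading inputs
    "matrix": None,            # NEXUS path (when simulate=False)
    "trees": None,             # newick/NEXUS path
    "ranges": None,            # CSV path
    "bins": None,              # CSV path (optional when simulating)
    "seed": 0,
    "timescale_methods": ["basic", "equal"],
    "root_buffer": 0.0,
    "n_boot": 1000,
    "target_variance": 0.95,
    "n_guilds": 3,
    "ecomorph_B": 200,
    "confidence": 0.95,
    "out": "results/pipeline",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_config(config: dict) -> dict:
    unknown = set(config) - set(CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**CONFIG_DEFAULTS, **config}
    if not merged["simulate"]:
        for key in ("matrix", "trees", "ranges", "bins"):
            if merged[key] is None:
                raise ValueError(f"config missing required input path: {key!r}")
    return merged


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: dict) -> dict:
    """Run every stage; write CSV outputs and a JSON report; return the report."""
    cfg = validate_config(config)
    outdir = Path(cfg["out"])
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in cfg.items()}, "stages": {}}
    stage = "inputs"
    try:
        if cfg["simulate"]:
            simcfg = sim.SimConfig(seed=cfg["seed"], n_guilds=cfg["n_guilds"])
            bundle = sim.simulate_clade(simcfg)
            bins = sim.default_bins(simcfg)
            ranges = bundle.ranges
            matrix = bundle.matrix
            trees = [sim.observed_cladogram(bundle)]
            traits, env, occ = bundle.traits, bundle.env, bundle.occurrences
            report["stages"]["inputs"] = {"synthetic": True,
                                          "truth": _jsonable(bundle.truth)}
            write_ranges(ranges, outdir / "ranges.csv")
            write_bins(bins, outdir / "bins.csv")
            write_nexus_matrix(matrix, outdir / "matrix.nex")
            traits.to_csv(outdir / "traits.csv")
            env.to_csv(outdir / "env.csv", index=False)
            occ.to_csv(outdir / "occurrences.csv", index=False)
        else:
            ranges = read_ranges(cfg["ranges"])
            bins = read_bins(cfg["bins"])
            matrix = read_nexus_matrix(cfg["matrix"])
            trees = read_trees(cfg["trees"])
            traits = env = occ = None
            report["stages"]["inputs"] = {"synthetic": False}

        stage = "timescale"
        ts_trees = timescale_set(trees, ranges, cfg["timescale_methods"],
                                 cfg["root_buffer"])
        write_trees([t.clone() for t in ts_trees], outdir / "timescaled.nwk")
        report["stages"]["timescale"] = {"n_trees": len(ts_trees),
                                         "labels": [t.label for t in ts_trees]}

        stage = "diversity"
        tde = taxic_diversity(ranges, bins)
        pde = phylo_diversity(ts_trees, ranges, bins)
        tde.to_frame().to_csv(outdir / "diversity_taxic.csv", index=False)
        pde.to_frame().to_csv(outdir / "diversity_phylo.csv", index=False)
        report["stages"]["diversity"] = {
            "taxic": _jsonable(tde.to_frame()),
            "phylogenetic": _jsonable(pde.to_frame()),
        }

        stage = "disparity"
        dis = pairwise_dissimilarity(matrix)
        diss_curve = binned_dissimilarity(dis, ranges, bins,
                                          n_boot=cfg["n_boot"], seed=cfg["seed"])
        best_tree = ts_trees[0]
        anc = reconstruct_ancestors(matrix, best_tree)
        anc_dis = pairwise_dissimilarity(anc)
        undefined = np.isnan(anc_dis.values).sum()
        if undefined:
            keep = [l for i, l in enumerate(anc_dis.labels)
                    if not np.isnan(anc_dis.values[i]).any()]
            anc_dis = anc_dis.submatrix(keep)
        ordn = pcoa(anc_dis)
        k = axes_for_variance(ordn, cfg["target_variance"])
        pres = presence_table(ordn.labels, bins, ranges, best_tree)
        sov = sum_of_variances(ordn, pres, bins, k,
                               n_boot=cfg["n_boot"], seed=cfg["seed"])
        diss_curve.to_frame().to_csv(outdir / "disparity_dissimilarity.csv", index=False)
        sov.to_frame().to_csv(outdir / "disparity_sov.csv", index=False)
        pd.DataFrame(ordn.scores, index=ordn.labels).to_csv(outdir / "pco_scores.csv")
        report["stages"]["disparity"] = {
            "dissimilarity": _jsonable(diss_curve.to_frame()),
            "sum_of_variances": _jsonable(sov.to_frame()),
            "axes_retained": k,
            "missing_fraction_tips": matrix.missing_fraction,
            "missing_fraction_with_ancestors": anc.missing_fraction,
        }

        stage = "rates"
        clado = cladogenesis_per_bin(ts_trees, bins)
        ext = extinction_per_bin(ranges, bins)
        rel = per_lineage_extinction(ext, pde)
        turn = turnover(clado, ext)
        for series, fname in [(clado, "rates_cladogenesis.csv"),
                              (ext, "rates_extinction.csv"),
                              (rel, "rates_per_lineage_extinction.csv"),
                              (turn, "rates_turnover.csv")]:
            series.to_frame().to_csv(outdir / fname, index=False)
        report["stages"]["rates"] = {
            s.kind: _jsonable(s.to_frame()) for s in (clado, ext, rel, turn)
        }

        stage = "ecomorph"
        if traits is not None:
            scaled = scale_traits(traits)
            dendro = multiscale_bootstrap_support(scaled, B=max(100, cfg["ecomorph_B"]),
                                                  seed=cfg["seed"])
            guilds = cut_guilds(dendro, k=cfg["n_guilds"])
            per_bin = guilds_per_bin(guilds, ranges, bins)
            guilds.to_csv(outdir / "guilds.csv")
            per_bin.to_csv(outdir / "guilds_per_bin.csv")
            report["stages"]["ecomorph"] = {
                "guilds": _jsonable(guilds),
                "guilds_per_bin": _jsonable(per_bin),
                "au": {" |".join(sorted(s.members)): s.au
                       for s in dendro.support.values()},
            }

        stage = "extinction_test"
        if occ is not None:
            focal = occ["n_focal_formations"].to_numpy()
            group = occ["n_group_formations"].to_numpy()
            with np.errstate(invalid="ignore"):
                freq = np.where(group > 0, focal / np.maximum(group, 1), np.nan)
            total_range = bins.oldest - bins.youngest
            rate = recovery_rate(float(focal.sum()), total_range)
            ext_report = {
                "occurrence_frequency": _jsonable(freq),
                "recovery_rate_per_my": rate,
                "poisson_extension_my": (poisson_extension(rate, cfg["confidence"])
                                          if rate > 0 else None),
            }
            lads = sorted(r.lad for r in ranges)
            fads = max(r.fad for r in ranges)
            horizons = len(ranges)
            if horizons >= 2 and fads > lads[0]:
                ext_report["strauss_sadler_extension_my"] = strauss_sadler_extension(
                    fads - lads[0], horizons, cfg["confidence"]
                )
            last_bin = occ.iloc[-1]
            overall_freq = float(np.nansum(focal) / max(np.nansum(group), 1))
            ext_report["prob_zero_last_bin"] = prob_zero(
                overall_freq, int(last_bin["n_group_formations"])
            )
            ext_report["freq_upper_bound_last_bin_p05"] = (
                freq_upper_bound(int(last_bin["n_group_formations"]), 0.05)
                if last_bin["n_group_formations"] >= 1 else None
            )
            with open(outdir / "extinction_test.json", "w") as fh:
                json.dump(_jsonable(ext_report), fh, indent=2)
            report["stages"]["extinction_test"] = _jsonable(ext_report)

        stage = "correlate"
        if env is not None:
            env_idx = env.set_index("bin")
            response = pd.Series(pde.values, index=bins.names, name="pde")
            predictors = env_idx[[c for c in env_idx.columns if c.endswith("_mean")
                                  or c.endswith("_var")]]
            times = pd.Series(bins.midpoints, index=bins.names)
            windows = {
                "full": bins.names,
                "truncated": bins.names[:-1],
            }
            res = run_windows(response, predictors, times, windows)
            corr_report = {}
            for wname, r in res.items():
                if r.get("skipped"):
                    corr_report[wname] = r
                    continue
                r["models"].to_csv(outdir / f"models_{wname}.csv", index=False)
                corr_report[wname] = {
                    "pairwise": r["pairwise"],
                    "models": _jsonable(r["models"]),
                }
            report["stages"]["correlate"] = _jsonable(corr_report)
    except Exception as exc:
        (outdir / "failed").mkdir(exist_ok=True)
        with open(outdir / "failed" / "report_partial.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, default=str)
        raise PipelineError(stage, exc) from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    return report
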