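"""End-to-end analysis: detect features, optimize discrimination
thresholds, test enrichment against the random background, evaluate the
holdout, search for co-localized modules, and write all artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

from . import catalog
from .discrimination import (
    DEFAULT_MAX_NP,
    DEFAULT_MIN_TSP,
    DiscriminationResult,
    default_grid,
    discriminate,
    select_most_sensitive,
    sweep_thresholds,
)
from .features import FeatureDefinition, find_hits
from .module_search import GAParams, ga_search, modules_to_rows
from .seqio import read_fasta, write_fasta, write_hits_tsv
from .simulate import StudyConfig, generate_study

logger = logging.getLogger("promdissect")


@dataclass
class RunConfig:
    """Everything one analysis run needs; serializable to/from JSON."""

    study: StudyConfig | None = None  # generate synthetic sets ...
    tsp_fasta: str | None = None      # ... or read them from FASTA
    np_fasta: str | None = None
    lowtsp_fasta: str | None = None
    rp_fasta: str | None = None
    min_tsp: float = DEFAULT_MIN_TSP
    max_np: float = DEFAULT_MAX_NP
    ga: GAParams = field(default_factory=GAParams)
    n_rp: int = 1000  # desk-scale background; set 7682 for full size
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        study = data.pop("study", None)
        ga = data.pop("ga", None)
        cfg = cls(**data)
        if study is not None:
            cfg.study = StudyConfig(**study)
        if ga is not None:
            cfg.ga = GAParams(**ga)
        return cfg


def _load_sets(config: RunConfig):
    if config.tsp_fasta and config.np_fasta:
        tsp = read_fasta(config.tsp_fasta, "TSP")
        np_set = read_fasta(config.np_fasta, "NP")
        lowtsp = read_fasta(config.lowtsp_fasta, "lowTSP") if config.lowtsp_fasta else None
        rp = read_fasta(config.rp_fasta, "RP") if config.rp_fasta else None
        return tsp, np_set, lowtsp, rp, None
    study_cfg = config.study or StudyConfig(seed=config.seed, n_rp=config.n_rp)
    data = generate_study(study_cfg)
    return data.tsp, data.np, data.lowtsp, data.rp, data.truth


def run_pipeline(
    config: RunConfig,
    features: list[FeatureDefinition] | None = None,
) -> dict:
    """Run the full analysis and return the summary report.

    For every catalogue feature: sweep the exact threshold grid on
    TSP vs NP, select the ratio-maximizing feasible threshold, measure the
    holdout and background frequencies at that frozen threshold and the
    binomial enrichment p-value; then run the genetic module search on the
    per-feature hits at their selected thresholds.
    """
    features = features or catalog.default_catalogue()
    tsp, np_set, lowtsp, rp, _truth = _load_sets(config)
    logger.info("sets: TSP=%d NP=%d lowTSP=%s RP=%s", len(tsp), len(np_set),
                lowtsp and len(lowtsp), rp and len(rp))

    feature_rows = []
    results: dict[str, DiscriminationResult | None] = {}
    hits_by_feature: dict[str, list] = {}
    rp_hits_by_feature: dict[str, list] = {}
    for feature in features:
        grid = default_grid(feature, tsp, np_set)
        logger.info("feature %s: %d grid points", feature.feature_id, len(grid))
        res = discriminate(feature, tsp, np_set, lowtsp, rp,
                           config.min_tsp, config.max_np, grid or None)
        results[feature.feature_id] = res
        if res is None:
            logger.info("feature %s: infeasible under bounds (%.2f, %.2f)",
                        feature.feature_id, config.min_tsp, config.max_np)
            feature_rows.append({"feature_id": feature.feature_id, "feasible": False})
            hits_by_feature[feature.feature_id] = []
            continue
        logger.info(
            "feature %s: threshold=%.4f freq_tsp=%.3f freq_np=%.3f ratio=%.2f",
            feature.feature_id, res.threshold, res.freq_tsp, res.freq_np, res.ratio,
        )
        # module-stage hits use the sensitivity-first threshold: member
        # detectors at maximal recall (NP bound still enforced); the module
        # combination, not the single element, provides the specificity
        sensitive = select_most_sensitive(
            sweep_thresholds(feature, tsp, np_set, grid, config.min_tsp,
                             config.max_np),
            config.max_np,
        )
        module_threshold = sensitive.threshold if sensitive else res.threshold
        logger.info("feature %s: module-stage threshold=%.4f",
                    feature.feature_id, module_threshold)
        hits = []
        for pset in (tsp, np_set):
            for rec in pset:
                hits.extend(find_hits(rec, feature, module_threshold))
        hits_by_feature[feature.feature_id] = hits
        if rp is not None:
            rp_hits = []
            for rec in rp:
                rp_hits.extend(find_hits(rec, feature, module_threshold))
            rp_hits_by_feature[feature.feature_id] = rp_hits
        feature_rows.append(
            {
                "feature_id": feature.feature_id,
                "feasible": True,
                "threshold": res.threshold,
                "freq_tsp": res.freq_tsp,
                "freq_np": res.freq_np,
                "freq_lowtsp": res.freq_lowtsp,
                "freq_rp": res.freq_rp,
                "ratio": res.ratio,
                "p_value": res.p_value,
                "p_value_bonferroni": (
                    None if res.p_value is None
                    else min(1.0, res.p_value * len(features))
                ),
                "counts": res.counts,
            }
        )

    feasible_rows = [r for r in feature_rows if r["feasible"]]
    # ties on the TSP/NP ratio are broken by background specificity:
    # the feature rarer in the random set is the more promoter-specific one
    ranking = sorted(
        feasible_rows,
        key=lambda r: (
            -r["ratio"],
            -r["freq_tsp"],
            r["freq_rp"] if r.get("freq_rp") is not None else float("inf"),
            r["feature_id"],
        ),
    )
    for rank, row in enumerate(ranking, start=1):
        row["rank"] = rank

    modules = []
    searchable = {f: h for f, h in hits_by_feature.items() if h}
    if len(searchable) >= 2:
        modules = ga_search(
            searchable, tsp, np_set, config.ga, seed=config.seed,
            rp=rp, rp_hits_by_feature=rp_hits_by_feature or None,
        )

    summary = {
        "seed": config.seed,
        "bounds": {"min_tsp": config.min_tsp, "max_np": config.max_np},
        "set_sizes": {
            "tsp": len(tsp), "np": len(np_set),
            "lowtsp": len(lowtsp) if lowtsp else None,
            "rp": len(rp) if rp else None,
        },
        "features": sorted(feature_rows, key=lambda r: r["feature_id"]),
        "ranking": [r["feature_id"] for r in ranking],
        "modules": modules_to_rows(modules),
    }

    if config.outdir:
        os.makedirs(config.outdir, exist_ok=True)
        for fid, hits in hits_by_feature.items():
            if hits:
                write_hits_tsv(hits, os.path.join(config.outdir, f"hits_{fid}.tsv"))
        _write_results_tsv(feature_rows,
                           os.path.join(config.outdir, "discrimination.tsv"))
        _write_modules_tsv(modules, os.path.join(config.outdir, "modules.tsv"))
        with open(os.path.join(config.outdir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


_RESULT_COLS = ("feature_id", "threshold", "freq_tsp", "freq_np", "freq_lowtsp",
                "freq_rp", "ratio", "p_value", "feasible")


def _write_results_tsv(rows: list[dict], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_RESULT_COLS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in _RESULT_COLS) + "\n")


def _write_modules_tsv(modules, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("members\tmax_span\tsupport_tsp\tsupport_np\tfitness\tp_value\n")
        for row in modules_to_rows(modules):
            fh.write(
                f"{row['members']}\t{row['max_span']}\t{row['support_tsp']:.4f}\t"
                f"{row['support_np']:.4f}\t{row['fitness']:.4f}\t{row['p_value']}\n"
            )


def simulate_to_dir(study_cfg: StudyConfig, outdir: str) -> dict:
    """Generate a synthetic study and write its FASTA files and truth JSON."""
    os.makedirs(outdir, exist_ok=True)
    data = generate_study(study_cfg)
    paths = {}
    for name, pset in (("tsp", data.tsp), ("np", data.np),
                       ("lowtsp", data.lowtsp), ("rp", data.rp)):
        path = os.path.join(outdir, f"{name}.fasta")
        write_fasta(pset, path)
        paths[name] = path
    truth_path = os.path.join(outdir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(
            {
                sid: [dataclasses.asdict(imp) for imp in imps]
                for sid, imps in data.truth.implants.items()
            },
            fh, indent=2, sort_keys=True,
        )
    paths["truth"] = truth_path
    return paths
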