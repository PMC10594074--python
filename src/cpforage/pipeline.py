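"""End-to-end orchestration: simulate/load -> segment -> metrics ->
consistency -> covariate stats -> report.

Configuration is a TOML file; every analysis constant (colony radius,
fix-count and sinuosity filters, region and depth boundaries, distance
bin width) is a config key whose default is the standard value used
throughout the package.  A run manifest records the config snapshot,
seeds, input digests and per-stage record counts so that every output
row is traceable and the counts reconcile exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geodesy import GeoPoint
from .trip_builder import (
    ColonySite,
    Trip,
    GpsFix,
    clean_trips,
    fixes_from_frame,
    group_by_deployment,
    read_fixes_csv,
    segment_trips,
    trip_fixes_frame,
    trips_summary_frame,
    REASON_TOO_FEW_FIXES,
    REASON_SINUOSITY,
)
from .trip_metrics import metrics_frame
from .consistency import (
    bin_distances,
    build_between_season_pairs,
    build_reference_pairs,
    build_within_season_pairs,
    g_test,
)
from .covariate_stats import (
    circular_anova_lrt,
    delta_s_t_test,
    linear_regression,
    one_way_anova,
    sequential_sinuosity_deltas,
    welch_t_test,
)
from .synthetic_data import SyntheticPopulationConfig, make_bathymetry, simulate_population

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "demo_config"]

log = logging.getLogger("cpforage")

LINEAR_METRICS = ["max_displacement_km", "total_distance_km", "duration_h", "sinuosity_S"]


@dataclass
class PipelineConfig:
    seed: int = 0
    # simulate stage; ignored when input_fixes_csv is set
    simulate: dict = field(default_factory=dict)
    input_fixes_csv: str | None = None
    metadata_csv: str | None = None  # individual_id, sex, age_years
    colony_lat: float = -40.3780953
    colony_lon: float = 144.6557384
    colony_radius_m: float = 400.0
    min_fixes: int = 11
    max_sinuosity: float = 0.5
    region_boundaries: tuple[float, float, float] = (130.0, 260.0, 355.0)
    shelf_break_min_m: float = 200.0
    pelagic_min_m: float = 1000.0
    bin_width_km: float = 50.0
    max_km: float = 1100.0
    reference_mode: str = "one_per_individual"
    bathymetry_enabled: bool = True
    bathymetry: dict = field(default_factory=dict)
    #: per-season ISO start dates; earlier trips are kept for the
    #: consistency analysis but excluded from metric summaries and
    #: covariate tests (e.g. a late-winter deployment)
    metric_season_start: dict = field(default_factory=dict)

    @property
    def colony(self) -> ColonySite:
        return ColonySite(GeoPoint(self.colony_lat, self.colony_lon), self.colony_radius_m)

    def synthetic_config(self, seed: int | None = None) -> SyntheticPopulationConfig:
        kwargs = dict(self.simulate)
        kwargs.pop("enabled", None)
        for key in ("seasons", "trips_per_deployment_probs", "bearing_mix_weights",
                    "bearing_mix_means_deg", "bearing_mix_kappas", "distance_range_km"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "sampling_interval_overrides" in kwargs:
            kwargs["sampling_interval_overrides"] = {
                int(k): float(v) for k, v in kwargs["sampling_interval_overrides"].items()
            }
        kwargs.setdefault("colony", self.colony.centre)
        kwargs.setdefault("colony_radius_m", self.colony_radius_m)
        return SyntheticPopulationConfig(seed=seed if seed is not None else self.seed, **kwargs)


def load_config(path) -> PipelineConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = PipelineConfig()
    run = raw.get("run", {})
    cfg.seed = int(run.get("seed", cfg.seed))
    cfg.input_fixes_csv = run.get("input_fixes_csv")
    cfg.metadata_csv = run.get("metadata_csv")
    cfg.simulate = raw.get("simulate", {})
    col = raw.get("colony", {})
    cfg.colony_lat = float(col.get("lat", cfg.colony_lat))
    cfg.colony_lon = float(col.get("lon", cfg.colony_lon))
    cfg.colony_radius_m = float(col.get("radius_m", cfg.colony_radius_m))
    cl = raw.get("clean", {})
    cfg.min_fixes = int(cl.get("min_fixes", cfg.min_fixes))
    cfg.max_sinuosity = float(cl.get("max_sinuosity", cfg.max_sinuosity))
    reg = raw.get("regions", {})
    cfg.region_boundaries = tuple(reg.get("boundaries", cfg.region_boundaries))
    dep = raw.get("depth_classes", {})
    cfg.shelf_break_min_m = float(dep.get("shelf_break_min_m", cfg.shelf_break_min_m))
    cfg.pelagic_min_m = float(dep.get("pelagic_min_m", cfg.pelagic_min_m))
    con = raw.get("consistency", {})
    cfg.bin_width_km = float(con.get("bin_width_km", cfg.bin_width_km))
    cfg.max_km = float(con.get("max_km", cfg.max_km))
    cfg.reference_mode = con.get("reference_mode", cfg.reference_mode)
    bat = raw.get("bathymetry", {})
    cfg.bathymetry_enabled = bool(bat.pop("enabled", cfg.bathymetry_enabled))
    cfg.bathymetry = bat
    cfg.metric_season_start = {
        int(k): v for k, v in raw.get("metrics", {}).get("season_start", {}).items()
    }
    return cfg


def demo_config() -> PipelineConfig:
    """The bundled small demo configuration."""
    with resources.as_file(resources.files("cpforage") / "demo_config.toml") as p:
        return load_config(p)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _trip_objects(fixes: list[GpsFix], colony: ColonySite) -> list[Trip]:
    trips: list[Trip] = []
    for _, dep_fixes in sorted(group_by_deployment(fixes).items()):
        trips.extend(segment_trips(dep_fixes, colony))
    return trips


def _season_mask(metrics: pd.DataFrame, season_start: dict) -> pd.Series:
    mask = pd.Series(True, index=metrics.index)
    for season, start in season_start.items():
        cutoff = pd.Timestamp(start, tz="UTC")
        mask &= ~((metrics["season"] == season) & (metrics["start_time"] < cutoff))
    return mask


def _gtest_payload(res, pair_kind: str, seed: int) -> dict:
    return {
        "comparison": f"{pair_kind}_vs_reference",
        "G": res.G,
        "df": res.df,
        "p": res.p,
        "pooling": res.pooled_bins,
        "seed": seed,
    }


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    seed: int | None = None,
    stop_after: str | None = None,
) -> Path:
    """Run the stages in order and write all outputs into ``out_dir``.

    ``stop_after`` may be ``"segment"``, ``"metrics"`` or
    ``"consistency"`` to end the run early (the manifest is always
    written).  Returns the output directory.  Deterministic for a fixed
    config and seed: rerunning produces byte-identical CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    colony = config.colony
    manifest: dict = {
        "software": {"name": "cpforage", "version": __version__},
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {},
        "counts": {},
    }

    # -- stage 1: obtain fixes ---------------------------------------------
    metadata = None
    if config.input_fixes_csv:
        fixes = read_fixes_csv(config.input_fixes_csv)
        manifest["inputs"]["fixes_csv"] = _sha256(config.input_fixes_csv)
        if config.metadata_csv:
            metadata = pd.read_csv(config.metadata_csv)
            manifest["inputs"]["metadata_csv"] = _sha256(config.metadata_csv)
        fixes_frame = None
    else:
        syn_cfg = config.synthetic_config()
        fixes_frame, truth = simulate_population(syn_cfg)
        fixes_frame.to_csv(out / "fixes.csv", index=False)
        truth.trips.to_csv(out / "truth_trips.csv", index=False)
        truth.roster.to_csv(out / "truth_roster.csv", index=False)
        truth.individuals.to_csv(out / "metadata.csv", index=False)
        metadata = truth.individuals
        manifest["inputs"]["fixes_csv"] = _sha256(out / "fixes.csv")
        fixes = fixes_from_frame(fixes_frame, source="simulated")
    manifest["counts"]["fixes_read"] = len(fixes)
    log.info("stage fixes: %d fixes", len(fixes))

    # -- stage 2: segment and clean ----------------------------------------
    raw_trips = _trip_objects(fixes, colony)
    n_trip_fixes = sum(t.n_fixes for t in raw_trips)
    kept, removals = clean_trips(
        raw_trips, min_fixes=config.min_fixes, max_sinuosity=config.max_sinuosity
    )
    counts = manifest["counts"]
    counts["colony_fixes"] = len(fixes) - n_trip_fixes
    counts["at_sea_fixes"] = n_trip_fixes
    counts["trips_raw"] = len(raw_trips)
    counts["removed_too_few_fixes"] = sum(r.reason == REASON_TOO_FEW_FIXES for r in removals)
    counts["removed_sinuosity"] = sum(r.reason == REASON_SINUOSITY for r in removals)
    counts["trips_kept"] = len(kept)
    assert counts["trips_kept"] == (
        counts["trips_raw"] - counts["removed_too_few_fixes"] - counts["removed_sinuosity"]
    )
    trips_summary_frame(kept).to_csv(out / "trips.csv", index=False)
    trip_fixes_frame(kept).to_csv(out / "trip_fixes.csv", index=False)
    pd.DataFrame(
        [(r.trip_id, r.reason, r.detail) for r in removals],
        columns=["trip_id", "reason", "detail"],
    ).to_csv(out / "removed_trips.csv", index=False)
    log.info(
        "stage segment: %d raw trips, %d removed (%d few fixes, %d sinuosity), %d kept",
        len(raw_trips), len(removals),
        counts["removed_too_few_fixes"], counts["removed_sinuosity"], len(kept),
    )
    if stop_after == "segment":
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        return out

    # -- stage 3: metrics ---------------------------------------------------
    grid = None
    if config.bathymetry_enabled:
        grid = make_bathymetry(colony=colony.centre, **config.bathymetry)
        grid.to_ascii(out / "bathymetry.asc")
    metrics = metrics_frame(kept, colony, grid=grid)
    metrics["in_metric_window"] = _season_mask(metrics, config.metric_season_start)
    metrics.to_csv(out / "metrics.csv", index=False)
    counts["trips_in_metric_window"] = int(metrics["in_metric_window"].sum())
    log.info("stage metrics: %d rows", len(metrics))
    if stop_after == "metrics":
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        return out

    # -- stage 4: consistency -----------------------------------------------
    results: dict = {"g_tests": [], "covariates": {}}
    if len(metrics) >= 2 and metrics["individual_id"].nunique() >= 2:
        ref = build_reference_pairs(metrics, mode=config.reference_mode, seed=config.seed)
        within = build_within_season_pairs(metrics)
        between = build_between_season_pairs(metrics, seed=config.seed)
        for pset, name in ((ref, "reference"), (within, "within_season"), (between, "between_season")):
            pset.pairs.to_csv(out / f"pairs_{name}.csv", index=False)
            counts[f"pairs_{name}"] = pset.n_pairs
        ref_binned = bin_distances(ref, config.bin_width_km, config.max_km)
        binned_rows = {"bin_left_km": ref_binned.bin_edges[:-1], "reference": ref_binned.counts}
        for pset, name in ((within, "within_season"), (between, "between_season")):
            if pset.n_pairs == 0:
                continue
            binned = bin_distances(pset, config.bin_width_km, config.max_km)
            binned_rows[name] = binned.counts
            res = g_test(ref_binned, binned)
            payload = _gtest_payload(res, name, config.seed)
            results["g_tests"].append(payload)
            (out / f"gtest_{name}.json").write_text(json.dumps(payload, indent=2) + "\n")
        pd.DataFrame(binned_rows).to_csv(out / "binned_distances.csv", index=False)
        log.info("stage consistency: %s", {k: v for k, v in counts.items() if k.startswith("pairs")})
    if stop_after == "consistency":
        (out / "stats.json").write_text(json.dumps(results, indent=2, default=float) + "\n")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        return out

    # -- stage 5: covariate statistics --------------------------------------
    mwin = metrics[metrics["in_metric_window"]]
    cov = results["covariates"]
    if len(mwin) >= 3:
        cov.update(_covariate_tests(mwin, metadata))
    deltas_within = sequential_sinuosity_deltas(metrics, "within_season")
    deltas_between = sequential_sinuosity_deltas(metrics, "between_season")
    deltas_within.to_csv(out / "sinuosity_deltas_within.csv", index=False)
    deltas_between.to_csv(out / "sinuosity_deltas_between.csv", index=False)
    for name, deltas in (("within_season", deltas_within), ("between_season", deltas_between)):
        if len(deltas) >= 2:
            t = delta_s_t_test(deltas)
            cov[f"delta_S_{name}"] = {
                "test": "one_sample_t", "mean_delta_S": float(deltas["delta_S"].mean()),
                "statistic": t.t, "df": t.df, "p": t.p, "n": len(deltas),
            }
    (out / "stats.json").write_text(json.dumps(results, indent=2, default=float) + "\n")

    # -- stage 6: report and manifest ---------------------------------------
    _write_summary(out, metrics, results, counts)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    log.info("run complete: %s", out)
    return out


def _covariate_tests(mwin: pd.DataFrame, metadata: pd.DataFrame | None) -> dict:
    """Year ANOVAs, circular year/sex tests, sex t-tests, age regressions."""
    cov: dict = {}
    seasons = sorted(mwin["season"].unique())
    if len(seasons) >= 2:
        for metric in LINEAR_METRICS:
            groups = [mwin.loc[mwin["season"] == s, metric].to_numpy() for s in seasons]
            if all(len(g) >= 1 for g in groups):
                res = one_way_anova(groups)
                cov[f"year_anova_{metric}"] = {
                    "test": "one_way_anova", "statistic": res.F,
                    "df": [res.df1, res.df2], "p": res.p, "groups": len(seasons),
                    "n": int(len(mwin)),
                }
        by_season = mwin.groupby("season")["bearing_deg"].count()
        if (by_season >= 2).all():
            res = circular_anova_lrt(mwin["bearing_deg"].to_numpy(), mwin["season"].to_numpy())
            cov["year_circular_anova_bearing"] = {
                "test": "von_mises_lrt", "statistic": res.chi_sq, "df": res.df,
                "p": res.p, "kappa_hat": res.kappa_hat, "n": int(len(mwin)),
            }
    if metadata is not None:
        merged = mwin.merge(metadata, on="individual_id", how="left")
        sexed = merged[merged["sex"].isin(["female", "male"])]
        f, m = sexed[sexed["sex"] == "female"], sexed[sexed["sex"] == "male"]
        if len(f) >= 2 and len(m) >= 2:
            for metric in LINEAR_METRICS:
                res = welch_t_test(f[metric].to_numpy(), m[metric].to_numpy())
                cov[f"sex_t_test_{metric}"] = {
                    "test": "welch_t", "statistic": res.t, "df": res.df, "p": res.p,
                    "n": int(len(sexed)),
                }
            res = circular_anova_lrt(sexed["bearing_deg"].to_numpy(), sexed["sex"].to_numpy())
            cov["sex_circular_anova_bearing"] = {
                "test": "von_mises_lrt", "statistic": res.chi_sq, "df": res.df,
                "p": res.p, "n": int(len(sexed)),
            }
        aged = merged.dropna(subset=["age_years"])
        if len(aged) >= 3 and aged["age_years"].nunique() >= 2:
            for metric in LINEAR_METRICS:
                res = linear_regression(aged["age_years"].to_numpy(), aged[metric].to_numpy())
                cov[f"age_regression_{metric}"] = {
                    "test": "linear_regression", "statistic": res.F, "df": list(res.df),
                    "p": res.p, "slope": res.slope, "r_squared": res.r_squared,
                    "n": int(len(aged)),
                }
    return cov


def _write_summary(out: Path, metrics: pd.DataFrame, results: dict, counts: dict) -> None:
    lines = ["# Run summary", "", "## Record counts", ""]
    for k, v in counts.items():
        lines.append(f"- {k}: {v}")
    mwin = metrics[metrics["in_metric_window"]]
    if len(mwin):
        lines += ["", "## Trip metrics by season (min / mean / max)", ""]
        for metric in LINEAR_METRICS:
            lines.append(f"### {metric}")
            agg = mwin.groupby("season")[metric].agg(["min", "mean", "max"])
            lines.append(agg.to_string())
            lines.append("")
        lines += ["## Bearing regions", "", mwin["region"].value_counts().to_string(), ""]
        if mwin["habitat_class"].notna().any():
            lines += ["## Habitat classes", "", mwin["habitat_class"].value_counts().to_string(), ""]
    if results["g_tests"]:
        lines += ["## Site-fidelity G-tests", ""]
        for g in results["g_tests"]:
            lines.append(
                f"- {g['comparison']}: G = {g['G']:.2f}, df = {g['df']}, p = {g['p']:.3g}"
            )
    (out / "summary.md").write_text("\n".join(lines) + "\n")
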