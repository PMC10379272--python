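"""End-to-end orchestration: reproducible behaviour, stereology and
correlation runs with manifest logging and bit-stable CSV outputs.

A run is driven by a :class:`RunConfig` (constructed directly or loaded from
JSON).  Each stage either reads its inputs from CSV (press logs, counting
sheets) or generates them with the synthetic module; every output directory
carries a manifest recording the configuration, master seed and row counts,
so any run can be re-derived exactly.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as osio
from .behavior import (
    bin_ext_presses,
    bin_fi_presses,
    burst_index,
    check_stability,
    hyperactivity_metrics,
    irt_distribution,
)
from .schedule import PressLog, ScheduleConfig
from .stats import (
    GroupSample,
    behavior_anatomy_correlation,
    two_sample_test,
)
from .stereology import (
    CountingSheet,
    GridGeometry,
    StereoEstimate,
    estimate_sheet,
    precision_audit,
)
from .synthetic import (
    CONTROL_PHENOTYPE,
    TREATED_PHENOTYPE,
    generate_phantom,
    section_and_sample,
    simulate_operant_cohort,
)

__all__ = [
    "RunConfig",
    "REGION_GEOMETRY",
    "run_behavior",
    "run_stereology",
    "run_correlation",
    "run_all",
]

#: Per-region sampling geometry (grid spacing / frame side in mm on the
#: montage, magnification x220), by cohort age.  Younger tissue uses tighter
#: grids on the smaller nuclei.
REGION_GEOMETRY: dict[str, dict[str, GridGeometry]] = {
    "PN14": {
        "VTA": GridGeometry(25.0, 50.0, 220.0, 0.005, 20, 2),
        "SNCd": GridGeometry(10.0, 30.0, 220.0, 0.005, 20, 1),
        "SNCv": GridGeometry(15.0, 50.0, 220.0, 0.005, 20, 2),
        "RRF": GridGeometry(15.0, 50.0, 220.0, 0.005, 20, 2),
    },
    "PN545": {
        "VTA": GridGeometry(30.0, 50.0, 220.0, 0.005, 40, 2),
        "CLi": GridGeometry(30.0, 50.0, 220.0, 0.005, 40, 1),
        "SNCd": GridGeometry(30.0, 20.0, 220.0, 0.005, 20, 1),
        "SNCv": GridGeometry(30.0, 50.0, 220.0, 0.005, 20, 1),
        "RRF": GridGeometry(30.0, 50.0, 220.0, 0.005, 40, 1),
    },
}


@dataclass
class RunConfig:
    """Configuration of a full run; every field JSON-serialisable."""

    seed: int = 0
    out_dir: str = "results"
    # behaviour stage
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"control": 9, "treated": 10})
    n_days: int = 32
    n_sequences_per_day: int = 2
    analysis_days: tuple[int, int] = (23, 32)
    press_logs_csv: str | None = None  # analyse these instead of simulating
    excluded_animals: list[str] = field(default_factory=list)
    # stereology stage
    regions: list[str] = field(default_factory=lambda: ["VTA"])
    cohort_age: str = "PN14"
    group_mean_n: dict[str, float] = field(
        default_factory=lambda: {"control": 11479.0, "treated": 8894.0})
    group_mean_vref: dict[str, float] = field(
        default_factory=lambda: {"control": 0.682, "treated": 0.585})
    animal_cv: float = 0.10
    counting_mode: str = "unidirectional"
    counting_sheets_csv: str | None = None
    geometry_json: str | None = None
    # statistics
    tails: str = "two"
    bonferroni_m: int | None = None  # default: number of regions tested

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        lo, hi = self.analysis_days
        if lo > hi:
            raise ValueError("empty analysis-day range")
        if self.press_logs_csv is None and self.n_days < lo:
            raise ValueError("n_days does not reach the analysis window")
        for path in (self.press_logs_csv, self.counting_sheets_csv,
                     self.geometry_json):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    @property
    def schedule(self) -> ScheduleConfig:
        return ScheduleConfig(analysis_days=tuple(self.analysis_days))

    def manifest_hash(self) -> str:
        # out_dir is where the run lands, not what the run is
        cfg = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(cfg, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(cfg: RunConfig, out: Path, stage: str,
                    row_counts: dict[str, int]) -> None:
    manifest = {
        "stage": stage,
        "seed": cfg.seed,
        "config_hash": cfg.manifest_hash(),
        "config": {k: v for k, v in asdict(cfg).items() if k != "out_dir"},
        "row_counts": row_counts,
    }
    (out / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )


# ---------------------------------------------------------------------------

def _get_logs(cfg: RunConfig) -> list[PressLog]:
    if cfg.press_logs_csv is not None:
        logs = osio.read_press_logs_csv(cfg.press_logs_csv)
    else:
        logs = simulate_operant_cohort(
            cfg.n_per_group,
            {"control": CONTROL_PHENOTYPE, "treated": TREATED_PHENOTYPE},
            cfg.schedule, n_days=cfg.n_days, seed=cfg.seed,
            n_sequences_per_day=cfg.n_sequences_per_day,
        )
    return [l for l in logs if l.animal_id not in cfg.excluded_animals]


def run_behavior(cfg: RunConfig) -> pd.DataFrame:
    """Behaviour stage: per-animal curves, IRT matrices, burst metrics.

    Returns the per-animal metrics table and writes all outputs (tidy CSVs,
    one 7x12 IRT matrix CSV per animal, group comparison, manifest) under
    ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sched = cfg.schedule
    logs = _get_logs(cfg)
    if cfg.press_logs_csv is None:
        osio.write_press_logs_csv(logs, out / "press_logs.csv")

    metric_rows, fi_rows, ext_rows = [], [], []
    fi_by_group: dict[str, list] = {}
    for log in sorted(logs, key=lambda l: l.animal_id):
        fi = bin_fi_presses(log, sched)
        ext = bin_ext_presses(log, sched)
        hist = irt_distribution(log, sched)
        b = burst_index(hist, sched)
        hyper = hyperactivity_metrics(fi)
        fi_by_group.setdefault(log.group, []).append(fi)
        metric_rows.append({
            "animal_id": log.animal_id, "group": log.group,
            "burst_index": b.burst_index, "overall_rate_p": hist.overall_rate_p,
            "last60s_total": hyper["last60s_total"], "bin11": hyper["bin11"],
            "n_fis_included": fi.n_fis_included,
        })
        fi_rows.append({"animal_id": log.animal_id, "group": log.group,
                        **{f"bin{i + 1}": v for i, v in enumerate(fi.per_bin_mean)}})
        ext_rows.append({"animal_id": log.animal_id, "group": log.group,
                         **{f"bin{i + 1}": v for i, v in enumerate(ext.per_bin_mean)}})
        irt_df = pd.DataFrame(
            hist.counts,
            index=[f"irt_bin{i + 1}" for i in range(7)],
            columns=[f"segment{j + 1}" for j in range(12)],
        ).map(osio.format_float)
        irt_df.to_csv(out / f"irt_matrix_{log.animal_id}.csv")

    osio.write_tidy_csv(metric_rows, out / "behavior_metrics.csv")
    osio.write_tidy_csv(fi_rows, out / "behavior_fi_bins.csv")
    osio.write_tidy_csv(ext_rows, out / "behavior_ext_bins.csv")

    metrics = pd.DataFrame(metric_rows)
    group_rows = []
    groups = sorted(metrics["group"].unique())
    for g in groups:
        sub = metrics[metrics["group"] == g]
        group_rows.append({
            "group": g, "n": len(sub),
            "burst_index_mean": sub["burst_index"].mean(),
            "burst_index_sem": sub["burst_index"].sem(),
            "last60s_mean": sub["last60s_total"].mean(),
            "bin11_mean": sub["bin11"].mean(),
            "stable": check_stability(fi_by_group[g]),
        })
    if len(groups) == 2:
        a, b_ = (metrics[metrics["group"] == g]["burst_index"].tolist()
                 for g in groups)
        res = two_sample_test(GroupSample(groups[0], a),
                              GroupSample(groups[1], b_), tails=cfg.tails)
        for row in group_rows:
            row["burst_test"] = res.test_name
            row["burst_statistic"] = res.statistic
            row["burst_p"] = res.p_value
    osio.write_tidy_csv(group_rows, out / "behavior_groups.csv")
    _write_manifest(cfg, out, "behavior",
                    {"animals": len(metric_rows), "groups": len(group_rows)})
    return metrics


# ---------------------------------------------------------------------------

def _synthetic_sheets(cfg: RunConfig) -> list[CountingSheet]:
    """Per-animal phantoms sized from the group means, sliced and counted."""
    rng_root = np.random.SeedSequence(cfg.seed + 7_919)
    geom_table = REGION_GEOMETRY[cfg.cohort_age]
    sheets: list[CountingSheet] = []
    animals = [(g, f"{g}_{i + 1:02d}")
               for g in sorted(cfg.n_per_group)
               for i in range(cfg.n_per_group[g])]
    children = rng_root.spawn(len(animals) * len(cfg.regions))
    k = 0
    for region in cfg.regions:
        if region not in geom_table:
            raise ValueError(
                f"region {region!r} has no geometry entry for {cfg.cohort_age}")
        for g, animal in animals:
            child = children[k]
            k += 1
            rng = np.random.default_rng(child)
            sigma = np.sqrt(np.log1p(cfg.animal_cv ** 2))
            n_i = int(round(cfg.group_mean_n[g]
                            * rng.lognormal(-0.5 * sigma ** 2, sigma)))
            v_i = cfg.group_mean_vref[g] * rng.lognormal(-0.5 * sigma ** 2, sigma)
            ph = generate_phantom(
                N_true=max(n_i, 1), region_volume_mm3=v_i,
                seed=int(rng.integers(2 ** 31)),
            )
            sheets.append(section_and_sample(
                ph, geom_table[region], seed=int(rng.integers(2 ** 31)),
                animal_id=animal, group=g, region=region,
                counting_mode=cfg.counting_mode,
            ))
    return sheets


def run_stereology(cfg: RunConfig) -> list[StereoEstimate]:
    """Stereology stage: per-animal estimates, group summary, CE audit."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.counting_sheets_csv is not None:
        if cfg.geometry_json is None:
            raise ValueError("counting_sheets_csv requires geometry_json")
        sheets = osio.read_counting_sheets(cfg.counting_sheets_csv,
                                           cfg.geometry_json)
    else:
        sheets = _synthetic_sheets(cfg)
        osio.write_counting_sheets(sheets, out / "counting_sheets.csv",
                                   out / "counting_geometry.json")

    estimates = [estimate_sheet(sh) for sh in sheets]
    estimates.sort(key=lambda e: (e.region, e.group, e.animal_id))
    osio.write_estimates_csv(estimates, out / "stereo_estimates.csv")

    # Table-1-style group summary
    df = pd.DataFrame([{
        "group": e.group, "region": e.region, "stain": e.stain,
        "Vref_mm3": e.Vref_mm3, "Nv_per_mm3": e.Nv_per_mm3,
        "N_absolute": e.N_absolute,
    } for e in estimates])
    rows = []
    for (g, region), sub in df.groupby(["group", "region"], sort=True):
        for q in ("Vref_mm3", "Nv_per_mm3", "N_absolute"):
            rows.append({
                "group": g, "region": region, "quantity": q,
                "n": len(sub), "mean": sub[q].mean(),
                "sd": sub[q].std(ddof=1), "sem": sub[q].sem(),
            })
    osio.write_tidy_csv(rows, out / "stereo_group_summary.csv")

    audit = precision_audit(estimates)
    osio.write_tidy_csv([{
        "group": c.group, "region": c.region, "quantity": c.quantity,
        "mean_ce": c.mean_ce, "cv": c.cv,
        "ratio_ce2_cv2": c.ratio if np.isfinite(c.ratio) else np.nan,
        "verdict": c.verdict, "note": c.note,
    } for c in audit.cells], out / "precision_audit.csv")
    with open(out / "precision_audit.log", "w") as fh:
        for c in audit.cells:
            fh.write(
                f"{c.group}/{c.region}/{c.quantity}: mean CE^2 "
                f"{c.mean_ce ** 2:.6f} vs CV^2 {c.cv ** 2:.6f} -> {c.verdict}"
                + (f" ({c.note})" if c.note else "") + "\n")
    _write_manifest(cfg, out, "stereology",
                    {"sheets": len(sheets), "audit_cells": len(audit.cells)})
    return estimates


# ---------------------------------------------------------------------------

def run_correlation(cfg: RunConfig,
                    behavior: pd.DataFrame | None = None,
                    estimates: list[StereoEstimate] | None = None) -> pd.DataFrame:
    """Join behaviour metrics to absolute neuron numbers and correlate."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if behavior is None:
        path = out / "behavior_metrics.csv"
        if not path.exists():
            raise FileNotFoundError(f"behaviour report missing: {path}")
        behavior = pd.read_csv(path)
    if estimates is None:
        path = out / "stereo_estimates.csv"
        if not path.exists():
            raise FileNotFoundError(f"stereology report missing: {path}")
        edf = pd.read_csv(path)
    else:
        edf = pd.DataFrame([{
            "animal_id": e.animal_id, "region": e.region,
            "N_absolute": e.N_absolute,
        } for e in estimates])

    regions = sorted(edf["region"].unique())
    m = cfg.bonferroni_m if cfg.bonferroni_m is not None else len(regions)
    rows, scatter = [], []
    for region in regions:
        sub = edf[edf["region"] == region][["animal_id", "N_absolute"]]
        merged = behavior.merge(sub, on="animal_id", how="inner")
        if merged.empty:
            raise ValueError(f"no overlapping animals for region {region}")
        for metric in ("bin11", "burst_index"):
            res = behavior_anatomy_correlation(
                merged[metric], merged["N_absolute"],
                m_comparisons=m, tails=cfg.tails)
            rows.append({
                "region": region, "metric": metric, "n": len(merged),
                "pearson_r": res.statistic, "p": res.p_value,
                "p_adjusted": res.adjusted_p, "m": m, "tails": cfg.tails,
            })
            for r in merged.itertuples():
                scatter.append({
                    "region": region, "metric": metric,
                    "animal_id": r.animal_id, "group": r.group,
                    "x": getattr(r, metric), "y": r.N_absolute,
                })
    osio.write_tidy_csv(rows, out / "correlations.csv")
    osio.write_tidy_csv(scatter, out / "correlation_scatter.csv")
    _write_manifest(cfg, out, "correlation", {"tests": len(rows)})
    return pd.DataFrame(rows)


def run_all(cfg: RunConfig) -> dict[str, object]:
    """Behaviour, stereology and correlation stages in sequence."""
    cfg.validate()
    behavior = run_behavior(cfg)
    estimates = run_stereology(cfg)
    correlations = run_correlation(cfg, behavior, estimates)
    return {"behavior": behavior, "estimates": estimates,
            "correlations": correlations}
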