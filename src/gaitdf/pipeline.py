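"""End-to-end orchestration: simulate/load -> correct -> normalize -> stats.

One :func:`run_pipeline` call executes every stage in order and writes all
result tables (TSV) plus a machine-readable run manifest.  Stages log the
curves they ingest and exclude, because the gap rule and the minimum
sample count are the places where data silently disappear.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bin_compare import (
    BinComparison,
    endpoint_y_average,
    per_bin_ttest,
    significant_fraction_summary,
)
from .dissimilarity import (
    DFMatrix,
    df_baseline,
    df_cross_group,
    group_stats,
    percent_difference,
)
from .errors import ConfigError, GaitError, StepExcludedError, InsufficientDataError
from .geometry import apply_homography, estimate_homography
from .io_tracks import (
    GROUPS,
    GroupDataset,
    read_calibration,
    read_step_intervals,
    read_track_table,
    validate_dataset,
    write_calibration,
    write_step_intervals,
    write_track_table,
)
from .normalize import (
    NormalizedStepCurve,
    extract_step,
    normalize_step,
    write_normalized_curves,
)
from .synthetic import default_paper_scenario, null_scenario, simulate_dataset

logger = logging.getLogger(__name__)

SCENARIOS = {"default": default_paper_scenario, "null": null_scenario}


@dataclass
class RunConfig:
    """All knobs of one pipeline run, with documented defaults."""

    scenario: str | None = "default"  # synthetic scenario name, or None to load files
    tracks_path: str | None = None
    intervals_path: str | None = None
    calibration_path: str | None = None
    outdir: str = "gaitdf_out"
    seed: int = 0
    bins: int = 100
    alpha: float = 0.05
    df_metric: str = "squared"  # "squared" | "rmsd"
    pairing: str = "cross_group"
    percent_denominator: str = "experimental"
    stats_method: str = "anova_bonferroni"  # | "kruskal_dunn"
    zeroing: str = "onset"  # | "none"
    ttest_variant: str = "student"  # | "welch"
    bin_correction: str = "none"  # | "bonferroni" | "fdr"
    control_group: str = "control"
    injury_days: tuple[int, ...] = (3, 7)
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ConfigError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.bins < 4:
            raise ConfigError(f"bins must be >= 4, got {self.bins}")
        if self.df_metric not in ("squared", "rmsd"):
            raise ConfigError(f"unknown df_metric {self.df_metric!r}")
        if self.stats_method not in ("anova_bonferroni", "kruskal_dunn"):
            raise ConfigError(f"unknown stats_method {self.stats_method!r}")
        if self.zeroing not in ("onset", "none"):
            raise ConfigError(f"unknown zeroing {self.zeroing!r}")
        if self.bin_correction not in ("none", "bonferroni", "fdr"):
            raise ConfigError(f"unknown bin_correction {self.bin_correction!r}")
        if self.scenario is not None and self.scenario not in SCENARIOS:
            raise ConfigError(
                f"unknown scenario {self.scenario!r}; available: {sorted(SCENARIOS)}"
            )
        if self.scenario is None and not (self.tracks_path and self.intervals_path):
            raise ConfigError("either a scenario or tracks/intervals paths are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "injury_days" in raw:
            raw["injury_days"] = tuple(raw["injury_days"])
        return cls(**raw)


@dataclass
class RunReport:
    """Counts and output paths of one completed run."""

    outdir: Path
    n_tracks: int
    n_curves: int
    n_steps_excluded: int
    outputs: dict[str, str] = field(default_factory=dict)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def load_dataset(cfg: RunConfig) -> tuple[GroupDataset, object | None]:
    """Stage 1: simulate the configured scenario or load annotation files."""
    if cfg.scenario is not None:
        sc = SCENARIOS[cfg.scenario](seed=cfg.seed)
        ds, gt = simulate_dataset(sc)
        return ds, gt
    tracks = read_track_table(cfg.tracks_path)
    intervals = read_step_intervals(cfg.intervals_path)
    cals = read_calibration(cfg.calibration_path) if cfg.calibration_path else {}
    return GroupDataset(tracks=tracks, intervals=intervals, calibrations=cals), None


def correct_tracks(ds: GroupDataset) -> GroupDataset:
    """Stage 2: homographic pixel-to-arena correction of tracks in px units.

    The calibration of camera id equal to the track's side is used; a
    single calibration applies to every track.
    """
    if not any(t.units == "px" for t in ds.tracks):
        return ds
    if not ds.calibrations:
        raise ConfigError("tracks are in pixels but no calibration was provided")
    homs = {cam: estimate_homography(cal) for cam, cal in ds.calibrations.items()}
    single = next(iter(homs.values())) if len(homs) == 1 else None
    corrected = []
    for t in ds.tracks:
        if t.units != "px":
            corrected.append(t)
            continue
        hom = homs.get(t.side, single)
        if hom is None:
            raise ConfigError(f"no calibration for camera/side {t.side!r}")
        new = type(t)(
            animal_id=t.animal_id,
            group=t.group,
            day=t.day,
            side=t.side,
            joint=t.joint,
            fps=t.fps,
            frames=t.frames.copy(),
            xy=apply_homography(hom, t.xy),
            units="cm",
        )
        corrected.append(new)
    return GroupDataset(
        tracks=corrected,
        intervals=ds.intervals,
        calibrations=ds.calibrations,
        provenance=dict(ds.provenance),
    )


def normalize_dataset(
    ds: GroupDataset, bins: int = 100, zeroing: str = "onset"
) -> tuple[list[NormalizedStepCurve], int]:
    """Stage 3: extract every step of every track and spline-normalize it.

    Steps dropped by the gap rule or for having too few samples are
    counted and logged, not fatal.
    """
    curves: list[NormalizedStepCurve] = []
    excluded = 0
    by_session: dict[tuple, list] = {}
    for iv in ds.intervals:
        by_session.setdefault(iv.session_key, []).append(iv)
    for track in ds.tracks:
        for iv in sorted(
            by_session.get(track.session_key, []), key=lambda iv: iv.step_id
        ):
            try:
                raw = extract_step(track, iv, zeroing=zeroing)
                curves.append(normalize_step(raw, n_bins=bins))
            except (StepExcludedError, InsufficientDataError) as exc:
                excluded += 1
                logger.info("step excluded: %s", exc)
    logger.info("normalized %d curves (%d steps excluded)", len(curves), excluded)
    return curves, excluded


def df_analysis(
    curves: list[NormalizedStepCurve], cfg: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stage 4: DF matrices per stratum, group statistics, percent differences.

    Within every (day, side, joint) stratum each experimental curve is
    paired with every control curve; the control group's own distribution
    pairs distinct control animals.  Group statistics per day pool the
    per-stratum DF values (strata are balanced by design, so pooling is
    equal-weight).
    """
    strata = sorted({(c.day, c.side, c.joint) for c in curves})
    groups_present = [g for g in GROUPS if any(c.group == g for c in curves)]
    groups_present += sorted({c.group for c in curves} - set(GROUPS))

    df_rows = []
    values_by_day_group: dict[tuple, list[np.ndarray]] = {}
    for day, side, joint in strata:
        in_stratum = [c for c in curves if (c.day, c.side, c.joint) == (day, side, joint)]
        ctrl = [c for c in in_stratum if c.group == cfg.control_group]
        if len({c.animal_id for c in ctrl}) < 2:
            logger.warning("stratum %s lacks control animals; skipped", (day, side, joint))
            continue
        for g in groups_present:
            sub = [c for c in in_stratum if c.group == g]
            if not sub:
                continue
            if g == cfg.control_group:
                mat: DFMatrix = df_baseline(sub, metric=cfg.df_metric)
            else:
                mat = df_cross_group(sub, ctrl, metric=cfg.df_metric)
            arr = mat.df_array()
            values_by_day_group.setdefault((day, g), []).append(arr)
            for v in mat.values:
                df_rows.append(
                    {
                        "day": day,
                        "side": side,
                        "joint": joint,
                        "group": g,
                        "scheme": mat.scheme,
                        "animal_a": v.curve_a[0],
                        "step_a": v.curve_a[5],
                        "animal_b": v.curve_b[0],
                        "step_b": v.curve_b[5],
                        "df": v.df,
                    }
                )
    df_table = pd.DataFrame(df_rows)

    summary_rows = []
    pct_rows = []
    for day in sorted({d for d, _ in values_by_day_group}):
        pooled = {
            g: np.concatenate(values_by_day_group[(day, g)])
            for g in groups_present
            if (day, g) in values_by_day_group
        }
        if len(pooled) < 2:
            continue
        res = group_stats(pooled, method=cfg.stats_method)
        for g in pooled:
            summary_rows.append(
                {
                    "day": day,
                    "group": g,
                    "mean_df": res.group_means[g],
                    "sem_df": res.group_sems[g],
                    "n_pairs": res.group_ns[g],
                    "omnibus_statistic": res.omnibus_statistic,
                    "omnibus_p": res.omnibus_p,
                }
            )
        for pw in res.pairwise:
            summary_rows.append(
                {
                    "day": day,
                    "group": f"{pw.group_a} vs {pw.group_b}",
                    "mean_df": np.nan,
                    "sem_df": np.nan,
                    "n_pairs": 0,
                    "omnibus_statistic": pw.statistic,
                    "omnibus_p": pw.p_adjusted,
                }
            )
        ref_mean = res.group_means.get(cfg.control_group)
        if ref_mean is not None:
            for g in pooled:
                if g == cfg.control_group:
                    continue
                try:
                    pct = percent_difference(
                        res.group_means[g], ref_mean, denominator=cfg.percent_denominator
                    )
                except GaitError:
                    pct = np.nan
                pct_rows.append(
                    {
                        "day": day,
                        "group": g,
                        "reference": cfg.control_group,
                        "mean_df": res.group_means[g],
                        "reference_mean_df": ref_mean,
                        "percent_difference": pct,
                    }
                )
    return df_table, pd.DataFrame(summary_rows), pd.DataFrame(pct_rows)


def _default_bin_pairs(groups: list[str], control: str) -> list[tuple[str, str]]:
    pairs = [(g, control) for g in groups if g != control]
    for treated in ("ischemia_nanopso", "pre_nanopso_ischemia"):
        if "ischemia" in groups and treated in groups:
            pairs.append(("ischemia", treated))
    return pairs


def bin_analysis(
    curves: list[NormalizedStepCurve], cfg: RunConfig
) -> tuple[list[BinComparison], pd.DataFrame, pd.DataFrame]:
    """Stage 5: per-bin VD/HD t-tests on the injury days, plus endpoints."""
    groups_present = [g for g in GROUPS if any(c.group == g for c in curves)]
    groups_present += sorted({c.group for c in curves} - set(GROUPS))
    pairs = _default_bin_pairs(groups_present, cfg.control_group)
    comparisons: list[BinComparison] = []
    endpoint_rows = []
    strata = sorted(
        {
            (c.day, c.side, c.joint)
            for c in curves
            if c.day in cfg.injury_days or c.group == cfg.control_group
        }
    )
    for day, side, joint in strata:
        if day not in cfg.injury_days:
            continue
        in_stratum = [c for c in curves if (c.day, c.side, c.joint) == (day, side, joint)]
        by_group = {
            g: [c for c in in_stratum if c.group == g] for g in groups_present
        }
        for g, sub in by_group.items():
            if len(sub) >= 1:
                start, end = endpoint_y_average(sub)
                endpoint_rows.append(
                    {
                        "day": day,
                        "side": side,
                        "joint": joint,
                        "group": g,
                        "start_y_mean": start,
                        "end_y_mean": end,
                    }
                )
        for ga, gb in pairs:
            a, b = by_group.get(ga, []), by_group.get(gb, [])
            if len(a) < 2 or len(b) < 2:
                continue
            for component in ("VD", "HD"):
                comparisons.append(
                    per_bin_ttest(
                        a,
                        b,
                        alpha=cfg.alpha,
                        component=component,
                        variant=cfg.ttest_variant,
                        correction=cfg.bin_correction,
                    )
                )
    summary = significant_fraction_summary(comparisons)
    return comparisons, summary, pd.DataFrame(endpoint_rows)


def _bin_comparison_table(comparisons: list[BinComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        side, joint, day = c.stratum
        for i in range(c.t.size):
            rows.append(
                (side, joint, day, c.component, c.group_a, c.group_b, i + 1,
                 c.t[i], c.p[i], bool(c.flags[i]))
            )
    return pd.DataFrame(
        rows,
        columns=["side", "joint", "day", "component", "group_a", "group_b",
                 "bin", "t", "p", "significant"],
    )


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute all stages and write result tables plus the run manifest."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    ds, gt = load_dataset(cfg)
    report = validate_dataset(ds)
    if not report.ok:
        raise ConfigError(
            "dataset validation failed:\n" + "\n".join(report.violations[:20])
        )
    logger.info(
        "dataset: %d tracks, %d intervals, groups %s",
        len(ds.tracks),
        len(ds.intervals),
        report.group_animal_counts,
    )

    ds = correct_tracks(ds)
    curves, excluded = normalize_dataset(ds, bins=cfg.bins, zeroing=cfg.zeroing)
    df_table, df_summary, pct_table = df_analysis(curves, cfg)
    comparisons, frac_summary, endpoints = bin_analysis(curves, cfg)

    outputs = {}

    def _write(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        outputs[name] = str(path)

    _write("normalized_curves.tsv", lambda p: write_normalized_curves(curves, p))
    _write("df_values.tsv", lambda p: df_table.to_csv(p, sep="\t", index=False))
    _write("df_group_summary.tsv", lambda p: df_summary.to_csv(p, sep="\t", index=False))
    _write("df_percent_differences.tsv", lambda p: pct_table.to_csv(p, sep="\t", index=False))
    _write(
        "bin_comparisons.tsv",
        lambda p: _bin_comparison_table(comparisons).to_csv(p, sep="\t", index=False),
    )
    _write(
        "significant_fractions.tsv",
        lambda p: frac_summary.to_csv(p, sep="\t", index=False),
    )
    _write("endpoint_y.tsv", lambda p: endpoints.to_csv(p, sep="\t", index=False))
    if gt is not None:
        _write("ground_truth_effects.tsv", lambda p: gt.effects.to_csv(p, sep="\t", index=False))
        _write(
            "ground_truth_animals.tsv",
            lambda p: gt.animal_effects.to_csv(p, sep="\t", index=False),
        )

    manifest = {
        "config": asdict(cfg),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "versions": {
            "gaitdf": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": {
            "tracks": len(ds.tracks),
            "intervals": len(ds.intervals),
            "curves": len(curves),
            "steps_excluded": excluded,
        },
        "output_checksums": {name: _file_checksum(p) for name, p in outputs.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    outputs["manifest.json"] = str(outdir / "manifest.json")

    return RunReport(
        outdir=outdir,
        n_tracks=len(ds.tracks),
        n_curves=len(curves),
        n_steps_excluded=excluded,
        outputs=outputs,
    )


def write_dataset(ds: GroupDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a dataset in the canonical annotation formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tracks": write_track_table(ds.tracks, outdir / "tracks.csv"),
        "intervals": write_step_intervals(ds.intervals, outdir / "intervals.csv"),
    }
    if ds.calibrations:
        paths["calibration"] = write_calibration(ds.calibrations, outdir / "calibration.csv")
    return paths
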