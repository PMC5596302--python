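"""Study orchestration: run every analysis stage and emit a report.

``run_study`` ties the stages together in the order the analyses require:
engagement ledger -> event series (engagement value, reach, delurking) ->
Granger tests -> propensity curves and linear fits -> top-engager table.
All artefacts are written to the output directory; the report carries a
provenance block (config, seed, package version) so a rerun with the same
inputs reproduces it exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .engagement_core import (
    EngagementParams,
    compute_ledger,
    export_ledger,
    export_series,
    normalized_capacity,
    windowed_capacity,
)
from .events import (
    DAY,
    WEEK,
    activity_panel,
    bond_events,
    detect_delurking,
    engagement_value_series,
    export_series_csv,
    reach_series,
)
from .forum_model import ForumDataset, read_dataset, write_dataset
from .longitudinal import (
    GrangerResult,
    bond_propensity,
    fit_line,
    granger_test,
    retention_propensity,
)
from .synthetic_data import SimulationConfig, simulate_forum

__all__ = ["RunConfig", "StudyReport", "run_study", "top_engagers"]

log = logging.getLogger("ohf_engage")


@dataclass
class RunConfig:
    """Configuration of a full study run.

    Either ``input_dir`` (an existing dataset) or ``simulation`` (a
    :class:`SimulationConfig` or mapping of its fields) must be provided.
    """

    input_dir: str | None = None
    input_format: str = "jsonl"
    simulation: SimulationConfig | dict | None = None
    seed: int | None = None  # overrides simulation.seed when set
    alpha: float = 0.8
    K: int | None = None
    delurk_gap_days: int = 30
    day_bin_seconds: int = DAY
    granger_lag: int = 2
    difference: bool = False
    threshold_step: float = 0.25
    top_k: int = 10
    out_dir: str = "study_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved_simulation(self) -> SimulationConfig | None:
        if self.simulation is None:
            return None
        sim = (self.simulation if isinstance(self.simulation, SimulationConfig)
               else SimulationConfig(**self.simulation))
        if self.seed is not None:
            sim = dataclasses.replace(sim, seed=self.seed)
        return sim


@dataclass
class StudyReport:
    """Aggregated study results, all traceable to artefact files."""

    total_value: float
    n_posts: int
    n_users: int
    n_threads: int
    top_engagers: list[dict[str, Any]]
    granger: dict[str, dict[str, Any]]
    bond_curve: dict[str, Any] | None
    retention_curve: dict[str, Any] | None
    notes: list[str] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def top_engagers(ledger, series, k: int = 10, by: str = "capacity") -> list[dict[str, Any]]:
    """Top-k users ranked by (optionally per-post-normalised) capacity.

    Ties break by user_id; each row carries the user's windowed capacity
    dynamics for superuser tracking.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    norm = normalized_capacity(ledger)
    if by == "capacity":
        score = dict(ledger.capacity)
    elif by == "normalized":
        score = dict(norm)
    else:
        raise ValueError(f"unknown ranking {by!r}")
    users = sorted(score, key=lambda u: (-score[u], u))
    if k > len(users):
        log.warning("requested top %d but only %d users have scores", k, len(users))
    rows = []
    for u in users[:k]:
        s = series.get(u)
        rows.append({
            "user_id": u,
            "capacity": ledger.capacity.get(u, 0.0),
            "posts": ledger.post_counts.get(u, 0),
            "normalized_capacity": norm.get(u),
            "windowed": dict(sorted(s.values.items())) if s else {},
        })
    return rows


def _granger_to_dict(res: GrangerResult) -> dict[str, Any]:
    def d(g):
        return {"cause": g.cause, "effect": g.effect, "F": g.f_stat,
                "p": g.p_value, "lag": g.lag, "n": g.n}
    return {"lag": res.lag, "differenced": res.differenced,
            "forward": d(res.x_to_y), "reverse": d(res.y_to_x)}


def _curve_to_dict(curve, fit) -> dict[str, Any]:
    return {
        "thresholds": curve.thresholds.tolist(),
        "numerators": curve.numerators.tolist(),
        "denominators": curve.denominators.tolist(),
        "proportions": [None if not np.isfinite(p) else float(p)
                        for p in curve.proportions],
        "fit": dataclasses.asdict(fit) if fit else None,
    }


def _write_curve_csv(curve, path: Path) -> None:
    import csv

    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["threshold", "numerator", "denominator", "proportion"])
        for t, nu, de, pr in zip(curve.thresholds, curve.numerators,
                                 curve.denominators, curve.proportions):
            w.writerow([t, int(nu), int(de),
                        "" if not np.isfinite(pr) else f"{pr:.6g}"])


def run_study(cfg: RunConfig) -> StudyReport:
    """Execute the full analysis pipeline and write all artefacts.

    Deterministic for fixed inputs/config/seed; raises with stage context
    on failure.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    notes: list[str] = []

    # --- stage: input ------------------------------------------------------
    sim = cfg.resolved_simulation()
    if cfg.input_dir is not None:
        ds = read_dataset(cfg.input_dir, cfg.input_format)
        log.info("loaded %d posts from %s", ds.n_posts, cfg.input_dir)
    elif sim is not None:
        result = simulate_forum(sim)
        ds = result.dataset
        write_dataset(ds, out / "dataset", "jsonl")
        with (out / "truth.jsonl").open("w", encoding="utf-8") as fh:
            for key in ("bond_trials", "retention_obs"):
                for rec in result.truth[key]:
                    fh.write(json.dumps({"kind": key, **rec}) + "\n")
        log.info("simulated %d posts over %d days", ds.n_posts, sim.horizon_days)
    else:
        raise ValueError("RunConfig needs input_dir or simulation")

    params = EngagementParams(alpha=cfg.alpha, K=cfg.K)

    # --- stage: engagement ledger -----------------------------------------
    ledger = compute_ledger(ds, params)
    export_ledger(ledger, out)
    series = windowed_capacity(ds, params, window=WEEK)
    export_series(series, out / "series.csv")

    # --- stage: event series ----------------------------------------------
    eng = engagement_value_series(ds, cfg.day_bin_seconds)
    reach = reach_series(ds.registrations, cfg.day_bin_seconds,
                         anchor=eng.anchor,
                         t_end=eng.anchor + eng.bin_seconds * eng.n_bins - 1)
    delurk_events, delurk = detect_delurking(
        ds, gap_seconds=cfg.delurk_gap_days * DAY,
        bin_seconds=cfg.day_bin_seconds, anchor=eng.anchor)
    for s, name in ((eng, "engagement"), (reach, "reach"), (delurk, "delurking")):
        export_series_csv(s, out / f"events_{name}.csv")

    # --- stage: Granger ----------------------------------------------------
    granger: dict[str, dict[str, Any]] = {}
    for name, other in (("engagement_vs_reach", reach),
                        ("engagement_vs_delurking", delurk)):
        try:
            res = granger_test(eng, other, lag=cfg.granger_lag,
                               difference=cfg.difference)
            granger[name] = _granger_to_dict(res)
        except ValueError as exc:
            notes.append(f"granger[{name}] skipped: {exc}")
            log.warning("granger %s skipped: %s", name, exc)
    with (out / "granger.json").open("w", encoding="utf-8") as fh:
        json.dump(granger, fh, indent=2)

    # --- stage: propensity -------------------------------------------------
    bonds = bond_events(ds.wall_notes)
    bond_dict = None
    if ledger.targeted:
        curve = bond_propensity(ledger, bonds)
        fit = None
        try:
            fit = fit_line(curve)
        except ValueError as exc:
            notes.append(f"bond fit skipped: {exc}")
        _write_curve_csv(curve, out / "propensity_bond.csv")
        bond_dict = _curve_to_dict(curve, fit)
    else:
        notes.append("bond propensity skipped: no targeted engagement")

    panel = activity_panel(ds)
    retention_dict = None
    if panel.n_weeks >= 2:
        curve = retention_propensity(series, panel)
        fit = None
        try:
            fit = fit_line(curve)
        except ValueError as exc:
            notes.append(f"retention fit skipped: {exc}")
        _write_curve_csv(curve, out / "propensity_retention.csv")
        retention_dict = _curve_to_dict(curve, fit)
    else:
        notes.append("retention propensity skipped: fewer than 2 weeks observed")

    # --- stage: report -----------------------------------------------------
    from importlib.metadata import PackageNotFoundError, version

    try:
        pkg_version = version("ohf-engage")
    except PackageNotFoundError:
        pkg_version = "unknown"
    top = top_engagers(ledger, series, k=cfg.top_k)
    provenance = {
        "version": pkg_version,
        "config": {**dataclasses.asdict(cfg),
                   "simulation": dataclasses.asdict(sim) if sim else None},
    }
    report = StudyReport(
        total_value=ledger.total_value,
        n_posts=ds.n_posts,
        n_users=len(ds.registrations),
        n_threads=len(ds.threads),
        top_engagers=top,
        granger=granger,
        bond_curve=bond_dict,
        retention_curve=retention_dict,
        notes=notes,
        provenance=provenance,
    )
    with (out / "report.json").open("w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=float)
    _write_markdown_report(report, out / "report.md")
    return report


def _write_markdown_report(report: StudyReport, path: Path) -> None:
    lines = ["# Forum engagement study", ""]
    lines += [
        f"- posts: {report.n_posts} in {report.n_threads} threads, "
        f"{report.n_users} registered users",
        f"- total engagement value: {report.total_value:.0f}",
        "",
        "## Top engagers",
        "",
        "| user | capacity | posts | capacity/post |",
        "|---|---|---|---|",
    ]
    for row in report.top_engagers:
        nc = row["normalized_capacity"]
        lines.append(
            f"| {row['user_id']} | {row['capacity']:.3f} | {row['posts']} | "
            f"{'' if nc is None else f'{nc:.3f}'} |")
    lines += ["", "## Granger causality", ""]
    if not report.granger:
        lines.append("(not computed)")
    for name, res in report.granger.items():
        fwd, rev = res["forward"], res["reverse"]
        lines.append(
            f"- {name} (lag {res['lag']}): "
            f"{fwd['cause']}→{fwd['effect']} F={fwd['F']:.3g} p={fwd['p']:.3g}; "
            f"{rev['cause']}→{rev['effect']} F={rev['F']:.3g} p={rev['p']:.3g}")
    for title, cd in (("Bond propensity", report.bond_curve),
                      ("Retention propensity", report.retention_curve)):
        lines += ["", f"## {title}", ""]
        if cd is None:
            lines.append("(not computed)")
            continue
        if cd["fit"]:
            f = cd["fit"]
            lines.append(
                f"- linear fit: slope {f['slope']:.4g}, intercept "
                f"{f['intercept']:.4g}, adjusted R² {f['adjusted_r2']:.3f} "
                f"(n={f['n']})")
        defined = [p for p in cd["proportions"] if p is not None]
        if defined:
            lines.append(f"- proportion range: {min(defined):.4f} – {max(defined):.4f}")
    if report.notes:
        lines += ["", "## Notes", ""] + [f"- {n}" for n in report.notes]
    lines += ["", "## Provenance", "",
              f"- package version {report.provenance.get('version')}",
              "```yaml",
              yaml.safe_dump(report.provenance.get("config", {}),
                             default_flow_style=False).rstrip(),
              "```", ""]
    path.write_text("\n".join(lines), encoding="utf-8")
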