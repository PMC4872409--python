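"""Study orchestration: simulate -> analyze -> stats as one reproducible run.

A run is fully specified by a :class:`StudyConfig` (serialisable to YAML or
JSON) plus its seed: it generates a complete within-subject cohort, computes
the three electrophysiology/behaviour outcomes plus raw startle for every
session, builds subjects x conditions tables, and runs the four
repeated-measures ANOVAs with the pre-registered Bonferroni comparisons
(every pretreatment+antagonist vs vehicle+antagonist, plus
vehicle+vehicle vs vehicle+antagonist).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evoked import MorletConfig, session_ersp, evoked_gamma_score
from .ongoing import session_timecourse, session_mean_post_injection
from .ppi import session_ppi, mean_startle
from .session import INJECTION_NMDAR, PULSE_ALONE, Session, SessionDesign
from .simulate import CohortSpec, EffectSpec, effect_presets, generate_cohort, scaled_design
from .stats import (
    AnovaResult,
    bonferroni_planned,
    comparisons_frame,
    condition_table,
    rm_anova_oneway,
)

logger = logging.getLogger(__name__)

OUTCOMES = ("ppi_pct", "startle", "evoked_db", "ongoing_pct")


@dataclass
class StudyConfig:
    """Everything needed to reproduce one study run."""

    design: SessionDesign = field(default_factory=scaled_design)
    conditions: dict[str, EffectSpec] = field(default_factory=effect_presets)
    n_subjects: int = 6
    startle_scale_sd: float = 0.4
    gamma_scale_sd: float = 0.2
    seed: int = 0
    vehicle_condition: str = "vehicle_vehicle"
    antagonist_condition: str = "vehicle_nmdar"
    comparisons: list[tuple[str, str]] | None = None  # None -> pre-registered default
    morlet: MorletConfig = field(default_factory=MorletConfig)
    band: tuple[float, float] = (30.0, 80.0)

    def planned_pairs(self) -> list[tuple[str, str]]:
        if self.comparisons is not None:
            return [tuple(c) for c in self.comparisons]
        pairs = [(self.vehicle_condition, self.antagonist_condition)]
        for name in sorted(self.conditions):
            if name not in (self.vehicle_condition, self.antagonist_condition):
                pairs.append((name, self.antagonist_condition))
        return pairs

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = dataclasses.asdict(self.design)
        d["conditions"] = {k: dataclasses.asdict(v) for k, v in self.conditions.items()}
        d["morlet"] = dataclasses.asdict(self.morlet)
        d["band"] = list(self.band)
        if self.comparisons is not None:
            d["comparisons"] = [list(c) for c in self.comparisons]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "design" in d:
            d["design"] = SessionDesign(**d["design"])
        if "conditions" in d:
            d["conditions"] = {k: EffectSpec(**v) for k, v in d["conditions"].items()}
        if "morlet" in d:
            d["morlet"] = MorletConfig(**d["morlet"])
        if "band" in d:
            d["band"] = tuple(d["band"])
        if d.get("comparisons") is not None:
            d["comparisons"] = [tuple(c) for c in d["comparisons"]]
        return cls(**d)


@dataclass
class ResultsBundle:
    """All tables and maps produced by one study run."""

    config: StudyConfig
    outcomes: pd.DataFrame  # tidy per-session rows
    anovas: dict[str, AnovaResult]
    comparisons: dict[str, pd.DataFrame]
    ersp_maps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]  # cond -> (t, f, dB)
    ongoing_timecourses: dict[str, tuple[np.ndarray, np.ndarray]]  # cond -> (min, pct)
    manifest: dict

    def table(self, outcome: str) -> pd.DataFrame:
        return condition_table(self.outcomes, value=outcome)


def analyze_session(
    session: Session,
    morlet: MorletConfig = MorletConfig(),
    band: tuple[float, float] = (30.0, 80.0),
    keep_maps: bool = False,
) -> dict:
    """All four outcome measures for one session.

    Returns a dict with %PPI and mean startle over the primary period, the
    prepulse-evoked gamma score (dB), and mean ongoing gamma power as % of
    the pre-injection baseline; optionally the underlying ERSP map and
    ongoing timecourse.
    """
    tc = session_timecourse(session, band=band)
    ongoing_pct = session_mean_post_injection(session, timecourse=tc)
    emap = session_ersp(session, morlet)
    score = evoked_gamma_score(emap, band=band)
    ppi = session_ppi(session)
    t0 = session.injection_time(INJECTION_NMDAR)
    pa = [t.startle_amp for t in session.trials_in_window(t0, session.recording.duration)
          if t.kind == PULSE_ALONE]
    out = {
        "subject": session.subject_id,
        "condition": session.condition_id,
        "session_order": session.session_order,
        "ppi_pct": ppi.ppi_pct,
        "startle": mean_startle(pa),
        "evoked_db": score.value,
        "ongoing_pct": ongoing_pct,
        "n_pulse_trials": ppi.n_pulse_trials,
        "n_prepulse_trials": ppi.n_prepulse_trials,
    }
    if keep_maps:
        out["_ersp"] = (emap.times, emap.freqs, emap.value)
        out["_ongoing"] = (tc.block_times, tc.band_power_pct)
    return out


def run_study(config: StudyConfig, out_dir: str | Path | None = None,
              keep_maps: bool = True) -> ResultsBundle:
    """Execute the full study: cohort generation, per-session analysis,
    condition tables and repeated-measures statistics."""
    cohort = CohortSpec(
        conditions=config.conditions,
        n_subjects=config.n_subjects,
        startle_scale_sd=config.startle_scale_sd,
        gamma_scale_sd=config.gamma_scale_sd,
        seed=config.seed,
    )
    logger.info("generating cohort: %d subjects x %d conditions",
                cohort.n_subjects, len(cohort.conditions))
    rows = []
    ersp_acc: dict[str, list] = {}
    ong_acc: dict[str, list] = {}
    grid = None
    for session in generate_cohort(cohort, config.design):
        try:
            res = analyze_session(session, config.morlet, config.band, keep_maps=keep_maps)
        except Exception as exc:  # stage-labelled failure, partial outputs kept
            raise RuntimeError(
                f"analysis failed for subject {session.subject_id}, "
                f"condition {session.condition_id}: {exc}"
            ) from exc
        if keep_maps:
            t, f, v = res.pop("_ersp")
            grid = (t, f)
            ersp_acc.setdefault(session.condition_id, []).append(v)
            ong_acc.setdefault(session.condition_id, []).append(res.pop("_ongoing"))
        rows.append(res)
    outcomes = pd.DataFrame(rows)

    anovas: dict[str, AnovaResult] = {}
    comparisons: dict[str, pd.DataFrame] = {}
    pairs = config.planned_pairs()
    for outcome in OUTCOMES:
        table = condition_table(outcomes, value=outcome)
        anovas[outcome] = rm_anova_oneway(table)
        comparisons[outcome] = comparisons_frame(bonferroni_planned(table, pairs))
        logger.info("%s: F(%d,%d) = %.3f, p = %.3g", outcome,
                    anovas[outcome].df1, anovas[outcome].df2,
                    anovas[outcome].F, anovas[outcome].p)

    ersp_maps = {}
    ongoing_tc = {}
    if keep_maps:
        import warnings

        for cond, maps in ersp_acc.items():
            with warnings.catch_warnings():
                # wavelet-edge cells are NaN in every session by design
                warnings.simplefilter("ignore", RuntimeWarning)
                ersp_maps[cond] = (grid[0], grid[1], np.nanmean(np.stack(maps), axis=0))
        for cond, tcs in ong_acc.items():
            times = tcs[0][0]
            ongoing_tc[cond] = (times, np.nanmean(np.stack([p for _, p in tcs]), axis=0))

    cfg_dict = config.to_dict()
    manifest = {
        "config": cfg_dict,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "package_version": __version__,
        "n_sessions": len(outcomes),
    }
    bundle = ResultsBundle(
        config=config, outcomes=outcomes, anovas=anovas, comparisons=comparisons,
        ersp_maps=ersp_maps, ongoing_timecourses=ongoing_tc, manifest=manifest,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: ResultsBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.outcomes.to_csv(out / "outcomes.csv", index=False)
    for name, res in bundle.anovas.items():
        res.as_frame().to_csv(out / f"anova_{name}.csv", index=False)
        bundle.comparisons[name].to_csv(out / f"comparisons_{name}.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)


def render_heatmaps(bundle: ResultsBundle, out_dir: str | Path) -> list[Path]:
    """Per-condition ERSP heatmaps (marker at prepulse onset) and ongoing
    timecourse heatmap analogues (markers at the two injections)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for cond, (t, f, v) in bundle.ersp_maps.items():
        if v.size == 0:
            logger.warning("condition %s has no ERSP map; skipped", cond)
            continue
        fig, ax = plt.subplots(figsize=(5, 4))
        pm = ax.pcolormesh(t * 1e3, f, v, shading="auto", cmap="jet")
        ax.axvline(0.0, color="red", lw=1)
        ax.set(xlabel="time re prepulse (ms)", ylabel="frequency (Hz)", title=cond)
        fig.colorbar(pm, ax=ax, label="dB re baseline")
        p = out / f"ersp_{cond}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    if bundle.ongoing_timecourses:
        fig, ax = plt.subplots(figsize=(6, 4))
        design = bundle.config.design
        for cond, (tmin, pct) in sorted(bundle.ongoing_timecourses.items()):
            ax.plot(tmin, pct, label=cond, lw=1)
        for t_inj in (design.pretreat_time, design.nmdar_time):
            ax.axvline(t_inj / 60.0, color="red", lw=1)
        ax.set(xlabel="time (min)", ylabel="gamma power (% baseline)")
        ax.legend(fontsize=6)
        p = out / "ongoing_timecourse.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    return written
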