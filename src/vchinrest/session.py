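"""Full-session orchestration: calibration, sweeps, two staircase blocks.

A session replays the deployed procedure: card-task calibration, a
5-trial blind-spot test, then the crowding experiment split into two
independent 25-trial staircases, each followed by a 3-trial blind-spot
test (so the distance is measured pre / mid / post).  Stimulus sizes
for the crowding trials are computed once, from the PRE-phase distance
estimate; mid-session sweeps monitor movement but do not re-calibrate
the stimuli.

Two frames of reference are tracked explicitly and never conflated:

* the *intended* frame -- degrees computed from the estimated distance;
  staircase bookkeeping and reported thresholds live here;
* the *presented* frame -- the visual angle the physical stimulus
  actually subtends at the observer's true (drifted) distance; observer
  responses are generated here.

If the pre-phase estimate is k times the true distance, the physical
stimulus is k times too large and the presented angle follows
atan(k * tan(intended)); the reported threshold remains in the
intended frame, exactly as a real deployment would log it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import math

import numpy as np
import pandas as pd

from . import staircase as sc
from .blindspot import estimate_distance, simulate_sweep
from .geometry import DisplayCalibration, compute_lpd, px_to_mm
from .observer import Observer, drift_distance, respond_crowding

ECCENTRICITY_CHOICES = (4.0, 6.0)


@dataclass
class SessionConfig:
    """Display, task and staircase parameters of one session."""

    card_image_width_px: float = 342.4          # lpd 4 px/mm, ~102 dpi
    alpha_deg: float = 13.5
    eccentricity_deg: float | None = None       # None -> randomize 4/6
    n_pre_trials: int = 5
    n_mid_trials: int = 3
    n_post_trials: int = 3
    n_practice: int = 5
    keypress_noise_sd_mm: float = 2.0
    n_staircase_trials: int = 25
    step_factor: float = 1.2
    n_reversals_for_threshold: int = 6
    threshold_estimator: str = "geometric"


@dataclass
class SessionRecord:
    """Everything one session produced.

    ``crowding_effect_deg`` is the mean of the two block thresholds;
    ``percent_correct`` is the fraction correct over the 50 main-block
    trials (practice excluded).
    """

    session_id: str
    calibration: DisplayCalibration
    alpha_deg: float
    eccentricity_deg: float
    distance_estimates_mm: dict
    true_distances_mm: dict
    block_thresholds_deg: list
    crowding_effect_deg: float
    percent_correct: float
    trial_log: list = field(default_factory=list)
    observer_info: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        cal = self.calibration.to_json_dict()
        cal["alpha_deg"] = self.alpha_deg
        return {
            "session_id": self.session_id,
            "calibration": cal,
            "eccentricity_deg": self.eccentricity_deg,
            "distance_estimates_mm": self.distance_estimates_mm,
            "true_distances_mm": self.true_distances_mm,
            "block_thresholds_deg": self.block_thresholds_deg,
            "crowding_effect_deg": self.crowding_effect_deg,
            "percent_correct": self.percent_correct,
            "observer_info": self.observer_info,
            "trial_log": self.trial_log,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_json_dict(cls, d: dict) -> "SessionRecord":
        cal = compute_lpd(d["calibration"]["card_image_width_px"])
        return cls(
            session_id=d["session_id"],
            calibration=cal,
            alpha_deg=d["calibration"]["alpha_deg"],
            eccentricity_deg=d["eccentricity_deg"],
            distance_estimates_mm=d["distance_estimates_mm"],
            true_distances_mm=d["true_distances_mm"],
            block_thresholds_deg=d["block_thresholds_deg"],
            crowding_effect_deg=d["crowding_effect_deg"],
            percent_correct=d["percent_correct"],
            trial_log=d.get("trial_log", []),
            observer_info=d.get("observer_info", {}),
        )

    def trials_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.trial_log)


def presented_angle_deg(intended_deg: float, estimated_d_mm: float,
                        true_d_mm: float) -> float:
    """Visual angle actually subtended by a stimulus sized for the estimate.

    The physical extent on screen is tan(intended) * estimated_d; seen
    from the true distance it subtends atan(tan(intended) * k) with
    k = estimated_d / true_d.
    """
    mm = math.tan(math.radians(intended_deg)) * estimated_d_mm
    return math.degrees(math.atan(mm / true_d_mm))


def _blindspot_phase(observer, phase, n_trials, cal, cfg, rng, log, session_id):
    true_d = drift_distance(observer, phase, rng)
    trials = simulate_sweep(observer, true_d, cal, n_trials, rng,
                            noise_sd_mm=cfg.keypress_noise_sd_mm)
    result = estimate_distance(trials, cal, cfg.alpha_deg)
    for i, t in enumerate(trials):
        log.append({
            "session_id": session_id,
            "phase": phase,
            "trial_index": i,
            "offset_px": t.disappear_offset_px,
            "offset_mm": px_to_mm(t.disappear_offset_px, cal),
            "estimated_d_mm": result.d_mm,
        })
    return true_d, result


def _crowding_trial(observer, spacing_deg, ecc_deg, d_est, d_true, rng):
    """Present one crowding trial; returns (row-fragment, correct)."""
    side = "left" if rng.random() < 0.5 else "right"
    gap = "up" if rng.random() < 0.5 else "down"
    spacing_pres = presented_angle_deg(spacing_deg, d_est, d_true)
    ecc_pres = presented_angle_deg(ecc_deg, d_est, d_true)
    correct = respond_crowding(observer, spacing_pres, ecc_pres, rng)
    response = gap if correct else ("down" if gap == "up" else "up")
    return {
        "spacing_deg": spacing_deg,
        "spacing_presented_deg": spacing_pres,
        "eccentricity_presented_deg": ecc_pres,
        "side": side,
        "gap_direction": gap,
        "response": response,
        "correct": correct,
    }, correct


def run_session(
    observer: Observer,
    cfg: SessionConfig | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    session_id: str = "session-0",
    strict: bool = True,
) -> SessionRecord:
    """Simulate one complete session; deterministic under a fixed seed.

    Staircase estimation failures (fewer than two reversals in a block)
    propagate as :class:`~vchinrest.staircase.EstimationError`, carrying
    the partial staircase state.  With ``strict=False`` (how
    :func:`run_cohort` runs sessions) the failed block's threshold is
    recorded as NaN instead and the session is kept; analyses exclude
    such sessions listwise with a reported count.
    """
    cfg = cfg if cfg is not None else SessionConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    cal = compute_lpd(cfg.card_image_width_px)
    ecc = cfg.eccentricity_deg
    if ecc is None:
        ecc = float(ECCENTRICITY_CHOICES[int(rng.integers(len(ECCENTRICITY_CHOICES)))])

    log: list[dict] = []
    d_true_pre, res_pre = _blindspot_phase(
        observer, "pre", cfg.n_pre_trials, cal, cfg, rng, log, session_id)
    d_est = res_pre.d_mm  # stimulus geometry fixed from the pre estimate

    config = sc.init_staircase(
        ecc,
        n_trials=cfg.n_staircase_trials,
        step_factor=cfg.step_factor,
        n_reversals_for_threshold=cfg.n_reversals_for_threshold,
        threshold_estimator=cfg.threshold_estimator,
    )

    # practice: fixed at the start spacing, excluded from all statistics
    for i in range(cfg.n_practice):
        row, _ = _crowding_trial(observer, config.start_spacing_deg, ecc,
                                 d_est, d_true_pre, rng)
        row.update(session_id=session_id, phase="practice", block=0,
                   trial_index=i, is_reversal=False)
        log.append(row)

    block_thresholds: list[float] = []
    n_correct = 0
    d_true_blocks = [d_true_pre]  # block 1 runs at the pre-phase distance
    true_distances = {"pre": d_true_pre}
    estimates = {"pre": res_pre.d_mm}

    for block in (1, 2):
        state = sc.new_state(config)
        d_true_block = d_true_blocks[-1]
        for i in range(config.n_trials):
            spacing = state.spacing_deg
            row, correct = _crowding_trial(observer, spacing, ecc,
                                           d_est, d_true_block, rng)
            n_rev_before = len(state.reversal_spacings)
            state = sc.update(state, correct)
            row.update(session_id=session_id, phase=f"block{block}",
                       block=block, trial_index=i,
                       is_reversal=len(state.reversal_spacings) > n_rev_before)
            log.append(row)
            n_correct += int(correct)
        try:
            block_thresholds.append(sc.threshold(state))
        except sc.EstimationError:
            if strict:
                raise
            block_thresholds.append(float("nan"))

        phase = "mid" if block == 1 else "post"
        n_phase = cfg.n_mid_trials if block == 1 else cfg.n_post_trials
        d_true_phase, res = _blindspot_phase(
            observer, phase, n_phase, cal, cfg, rng, log, session_id)
        true_distances[phase] = d_true_phase
        estimates[phase] = res.d_mm
        d_true_blocks.append(d_true_phase)  # block 2 runs at the mid distance

    n_main = 2 * config.n_trials
    return SessionRecord(
        session_id=session_id,
        calibration=cal,
        alpha_deg=cfg.alpha_deg,
        eccentricity_deg=ecc,
        distance_estimates_mm=estimates,
        true_distances_mm=true_distances,
        block_thresholds_deg=block_thresholds,
        crowding_effect_deg=float(np.mean(block_thresholds)),
        percent_correct=n_correct / n_main,
        trial_log=log,
        observer_info={
            "age": observer.age_years,
            "dyslexia": observer.dyslexia,
            "bouma_ratio": observer.bouma_ratio,
            "blindspot_entry_deg": observer.blindspot_entry_deg,
            "true_distance_mm": observer.true_distance_mm,
            "lapse": observer.lapse_rate,
        },
    )


def run_cohort(
    population: Sequence[Observer],
    cfg: SessionConfig | None = None,
    master_seed: int = 0,
) -> list[SessionRecord]:
    """One session per observer, with per-observer sub-seeds.

    Sub-streams are spawned from the master seed (``SeedSequence.spawn``),
    so the cohort is reproducible and each observer's session does not
    depend on how many observers precede it.
    """
    if len(population) == 0:
        raise ValueError("population must be non-empty")
    children = np.random.SeedSequence(master_seed).spawn(len(population))
    return [
        run_session(obs, cfg, rng=np.random.default_rng(child),
                    session_id=f"s{i:04d}", strict=False)
        for i, (obs, child) in enumerate(zip(population, children))
    ]


def sessions_to_df(records: Sequence[SessionRecord]) -> pd.DataFrame:
    """One row per session: threshold, accuracy, covariates, distances."""
    rows = []
    for r in records:
        rows.append({
            "session_id": r.session_id,
            "eccentricity_deg": r.eccentricity_deg,
            "crowding_effect_deg": r.crowding_effect_deg,
            "percent_correct": r.percent_correct,
            "d_pre_mm": r.distance_estimates_mm.get("pre"),
            "d_mid_mm": r.distance_estimates_mm.get("mid"),
            "d_post_mm": r.distance_estimates_mm.get("post"),
            "age": r.observer_info.get("age"),
            "dyslexia": r.observer_info.get("dyslexia"),
        })
    return pd.DataFrame(rows)


def cohort_trials_df(records: Sequence[SessionRecord]) -> pd.DataFrame:
    """Concatenated trial logs of a cohort."""
    return pd.concat([r.trials_df() for r in records], ignore_index=True)


def save_sessions(records: Sequence[SessionRecord], outdir: str | Path) -> None:
    """Write one JSON per session plus cohort-level trials.csv/sessions.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for r in records:
        (outdir / f"{r.session_id}.json").write_text(r.to_json())
    cohort_trials_df(records).to_csv(outdir / "trials.csv", index=False)
    sessions_to_df(records).to_csv(outdir / "sessions.csv", index=False)


def load_sessions(indir: str | Path) -> list[SessionRecord]:
    """Load the session JSONs written by :func:`save_sessions`."""
    paths = sorted(Path(indir).glob("*.json"))
    return [SessionRecord.from_json_dict(json.loads(p.read_text())) for p in paths]
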