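"""Synthetic observer: parametric visual fields, psychometric responses,
saccade dynamics, eye-tracker noise, fixation drift and head movement.

The simulator closes the loop around the trial engine with no hardware: it
implements the :class:`~gazeperim.engine.GazeSource` protocol, emitting 50 Hz
gaze samples, and reacts to stimulus onsets by deciding — from a ground-truth
decibel sensitivity field and a cumulative-normal psychometric function —
whether the observer sees the target and saccades to it.

Behavioral model per trial:

* The ground-truth retinal position of the stimulus is its screen position
  minus the observer's *fixation of record* at onset: the settled fixation
  (base plus slow drift), excluding momentary saccadic transients.  Since a
  stimulus stays up for most of its 1500 ms window after any in-flight
  motion completes, the settled fixation is the retinal reference at which
  the target is (or is not) seen.
* Detection probability comes from :func:`p_seen` at the local sensitivity.
* A seen target triggers a saccade after a truncated-normal latency
  (>= 220 ms, which guarantees gaze 200 ms before the response is still
  pre-saccadic — the assumption the post-hoc correction relies on).  The
  primary saccade undershoots by a fraction of its amplitude (the classic
  ~10% hypometria) plus isotropic landing error; when it misses the target
  by more than half a degree, a corrective saccade follows ~100 ms later and
  settles on the target.  The observer then fixates the dot.
* An unseen target leaves gaze at the current fixation; near the end of the
  presentation the observer may give up waiting and drift back toward the
  screen center (central fixation bias).  These return saccades are
  scheduled after the trial can no longer resolve (a response would exceed
  the window), so they do not alter outcomes.
* Every emitted sample adds isotropic tracker noise, and viewing distance
  follows a slow mean-reverting walk around 50 cm.

Both drift and distance are mean-reverting (Ornstein-Uhlenbeck) walks whose
stationary standard deviations are the configured sigmas; their time
constants (~1 min) make them quasi-stationary over a single trial.

The undershoot/corrective sequence is what gives the post-hoc correction its
purpose: the engine places the next stimulus relative to gaze measured at
onset — often the undershot primary landing — while the observer actually
views the trial from the settled (post-corrective) fixation.  The 200 ms
look-back recovers that settled fixation; the intended location does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .concordance import HFAField
from .engine import EngineConfig, GazeSample, SessionResult, run_session
from .errors import ConfigError
from .geometry import AngularPoint, ScreenModel, luminance_to_hfa_db
from .grid import MeasurementGrid, build_24_2, build_measurement_grid

#: HFA-equivalent attenuation of the fixed 300 cd/m^2 target (~10.26 dB).
DEFAULT_STIMULUS_DB = luminance_to_hfa_db(300.0)

#: Age-normal flat sensitivity surrogate used for the synthetic MD (dB).
AGE_NORMAL_DB = 30.0


@dataclass(frozen=True)
class Scotoma:
    """A region of depressed sensitivity.

    ``center`` is the disk center for ``shape='disk'``; for ``'hemifield'``
    and ``'arcuate'`` it is the direction of the affected side (e.g. (0, -1)
    for the inferior hemifield).  ``radius_deg`` is the disk radius, or the
    arc radius of an arcuate band of width ``width_deg`` pivoting around
    fixation.
    """

    shape: str
    center: tuple[float, float] = (0.0, -1.0)
    radius_deg: float = 8.0
    depth_db: float = 25.0
    width_deg: float = 8.0

    def __post_init__(self):
        if self.shape not in ("disk", "hemifield", "arcuate"):
            raise ConfigError(f"unknown scotoma shape {self.shape!r}")

    def covers(self, x_deg: float, y_deg: float) -> bool:
        cx, cy = self.center
        if self.shape == "disk":
            return math.hypot(x_deg - cx, y_deg - cy) <= self.radius_deg
        on_side = x_deg * cx + y_deg * cy > 0
        if self.shape == "hemifield":
            return on_side
        ecc = math.hypot(x_deg, y_deg)
        return on_side and abs(ecc - self.radius_deg) <= self.width_deg / 2.0


@dataclass(frozen=True)
class TrueField:
    """Ground-truth decibel sensitivity across the visual field.

    sensitivity(x, y) = baseline - slope * eccentricity - sum of covering
    scotoma depths, clipped to [0, 40] dB.
    """

    baseline_center_db: float = 30.0
    eccentricity_slope_db_per_deg: float = 0.1
    scotomas: tuple[Scotoma, ...] = ()

    def sensitivity_at(self, x_deg: float, y_deg: float) -> float:
        s = (self.baseline_center_db
             - self.eccentricity_slope_db_per_deg * math.hypot(x_deg, y_deg))
        for sc in self.scotomas:
            if sc.covers(x_deg, y_deg):
                s -= sc.depth_db
        return float(np.clip(s, 0.0, 40.0))


@dataclass(frozen=True)
class ObserverParams:
    """Behavioral and measurement parameters of the simulated observer.

    psychometric_slope_db : spread (dB) of the cumulative-normal psychometric
        function relating sensitivity margin to detection probability.
    lapse_rate : probability a seen target elicits no response.
    false_saccade_rate : floor probability of orienting to an unseen target
        (search/guess behavior).
    latency_mean_ms / latency_sd_ms : saccade latency, truncated at
        >= 220 ms so the correction's look-back window stays pre-saccadic.
    landing_sigma_deg : isotropic landing error of the primary saccade.
    saccade_undershoot_frac : systematic hypometria of the primary saccade
        (fraction of its amplitude; ~10% is typical).
    corrective_delay_ms / corrective_sigma_deg / corrective_threshold_deg :
        a corrective saccade follows the primary after this delay whenever
        the primary missed the target by more than the threshold, settling
        on the target with this scatter.
    recenter_rate / recenter_sigma_deg : central fixation bias — probability
        that an undetected trial triggers a return saccade toward screen
        center (with Gaussian scatter) late in the presentation, once the
        trial can no longer resolve.  Without it gaze would ratchet toward
        the intact hemifield in eyes with hemifield loss, which real
        free-viewing observers do not do.
    tracker_noise_sigma_deg : per-sample tracker noise (< 0.6 deg precision).
    drift_sigma_deg : stationary SD of slow fixation wander.
    drift_tau_s : time constant of the wander (mean-reverting walk).
    distance_walk_sigma_cm / distance_tau_s : head-distance walk around
        ``distance_mean_cm``.
    """

    psychometric_slope_db: float = 2.0
    lapse_rate: float = 0.02
    false_saccade_rate: float = 0.02
    latency_mean_ms: float = 300.0
    latency_sd_ms: float = 50.0
    latency_floor_ms: float = 220.0
    landing_sigma_deg: float = 0.75
    saccade_undershoot_frac: float = 0.1
    corrective_delay_ms: float = 100.0
    corrective_sigma_deg: float = 0.3
    corrective_threshold_deg: float = 0.5
    recenter_rate: float = 0.6
    recenter_sigma_deg: float = 3.0
    tracker_noise_sigma_deg: float = 0.3
    drift_sigma_deg: float = 1.0
    drift_tau_s: float = 60.0
    distance_mean_cm: float = 50.0
    distance_walk_sigma_cm: float = 2.0
    distance_tau_s: float = 60.0

    def __post_init__(self):
        if not (0 <= self.lapse_rate <= 1 and 0 <= self.false_saccade_rate <= 1
                and 0 <= self.recenter_rate <= 1):
            raise ConfigError("rates must be probabilities in [0, 1]")
        if self.psychometric_slope_db <= 0:
            raise ConfigError("psychometric_slope_db must be positive")
        if self.tracker_noise_sigma_deg > 0.6:
            raise ConfigError("tracker noise above the 0.6 deg precision bound")


def p_seen(sensitivity_db: float, stimulus_db: float = DEFAULT_STIMULUS_DB,
           params: ObserverParams | None = None) -> float:
    """Probability of orienting to a suprathreshold target.

    A cumulative-normal psychometric function of the sensitivity margin,
    scaled by the lapse rate, with the false-saccade rate as a guess floor:

        p = guess + (1 - guess) * (1 - lapse) * Phi((S - S_stim) / slope)
    """
    params = params or ObserverParams()
    core = (1.0 - params.lapse_rate) * float(
        ndtr((sensitivity_db - stimulus_db) / params.psychometric_slope_db))
    g = params.false_saccade_rate
    return g + (1.0 - g) * core


class SimulatedObserver:
    """GazeSource implementation driven by a ground-truth field."""

    def __init__(self, field: TrueField, params: ObserverParams,
                 rng: np.random.Generator,
                 sample_period_ms: float = 20.0,
                 stimulus_db: float = DEFAULT_STIMULUS_DB):
        self.field = field
        self.params = params
        self.rng = rng
        self.dt_ms = sample_period_ms
        self.stimulus_db = stimulus_db
        self.t_ms = 0.0
        self.base = AngularPoint(0.0, 0.0)  # current fixation target (true)
        self.drift = np.zeros(2)
        self.distance_dev_cm = 0.0
        # Scheduled gaze shifts: time-ordered (t_exec_ms, landing) pairs.
        self._pending: list[tuple[float, AngularPoint]] = []
        self.truth_rows: list[dict] = []
        # Per-sample OU updates with stationary sd = sigma.
        self._k_drift = 1.0 - math.exp(-sample_period_ms / 1000.0 / params.drift_tau_s)
        self._k_dist = 1.0 - math.exp(-sample_period_ms / 1000.0 / params.distance_tau_s)

    # -- GazeSource protocol ------------------------------------------------
    def next_sample(self) -> GazeSample:
        p = self.params
        self.t_ms += self.dt_ms
        while self._pending and self.t_ms >= self._pending[0][0]:
            landing = self._pending.pop(0)[1]
            # Land exactly on the drawn landing point: fold current drift in.
            self.base = AngularPoint(landing.x_deg - self.drift[0],
                                     landing.y_deg - self.drift[1])
        k = self._k_drift
        self.drift = ((1.0 - k) * self.drift
                      + p.drift_sigma_deg * math.sqrt(max(1 - (1 - k) ** 2, 0.0))
                      * self.rng.standard_normal(2))
        kd = self._k_dist
        self.distance_dev_cm = ((1.0 - kd) * self.distance_dev_cm
                                + p.distance_walk_sigma_cm
                                * math.sqrt(max(1 - (1 - kd) ** 2, 0.0))
                                * self.rng.standard_normal())
        gaze = self.true_gaze()
        noise = p.tracker_noise_sigma_deg * self.rng.standard_normal(2)
        return GazeSample(t_ms=self.t_ms,
                          x_deg=gaze.x_deg + noise[0],
                          y_deg=gaze.y_deg + noise[1],
                          distance_cm=p.distance_mean_cm + self.distance_dev_cm,
                          valid=True)

    def notify_stimulus(self, stim_screen: AngularPoint, onset_ms: float) -> None:
        prm = self.params
        fixation = self.fixation_of_record()
        true_retinal = stim_screen - fixation
        s = self.field.sensitivity_at(true_retinal.x_deg, true_retinal.y_deg)
        p = p_seen(s, self.stimulus_db, prm)
        seen = bool(self.rng.random() < p)
        self.truth_rows.append({
            "trial": len(self.truth_rows), "onset_ms": onset_ms,
            "true_x_deg": true_retinal.x_deg, "true_y_deg": true_retinal.y_deg,
            "sensitivity_db": s, "p_seen": p, "seen": seen,
        })
        if seen:
            latency = self._draw_latency()
            vec = stim_screen - fixation
            landing = AngularPoint(
                stim_screen.x_deg - prm.saccade_undershoot_frac * vec.x_deg
                + prm.landing_sigma_deg * self.rng.standard_normal(),
                stim_screen.y_deg - prm.saccade_undershoot_frac * vec.y_deg
                + prm.landing_sigma_deg * self.rng.standard_normal())
            self._schedule(onset_ms + latency, landing)
            if landing.distance_to(stim_screen) > prm.corrective_threshold_deg:
                settle = stim_screen + AngularPoint(
                    *(prm.corrective_sigma_deg * self.rng.standard_normal(2)))
                self._schedule(onset_ms + latency + prm.corrective_delay_ms, settle)
        elif self.rng.random() < prm.recenter_rate:
            # Give up waiting near the end of the presentation and return
            # toward the screen center.  Scheduled late enough that a
            # response could no longer be registered within the window.
            when = onset_ms + self.rng.uniform(1300.0, 1480.0)
            target = AngularPoint(
                *(prm.recenter_sigma_deg * self.rng.standard_normal(2)))
            self._schedule(when, target)

    # -- internals -----------------------------------------------------------
    def true_gaze(self) -> AngularPoint:
        return AngularPoint(self.base.x_deg + self.drift[0],
                            self.base.y_deg + self.drift[1])

    def fixation_of_record(self) -> AngularPoint:
        """The settled fixation: where gaze rests once scheduled motion ends.

        With a saccade chain in flight the stimulus will be viewed from the
        chain's final landing for the bulk of the presentation, so that point
        (plus current drift) is the retinal reference of the trial.
        """
        if self._pending:
            final = self._pending[-1][1]
            return AngularPoint(final.x_deg, final.y_deg)
        return self.true_gaze()

    def _schedule(self, t_exec_ms: float, landing: AngularPoint) -> None:
        self._pending.append((t_exec_ms, landing))
        self._pending.sort(key=lambda item: item[0])

    def _draw_latency(self) -> float:
        p = self.params
        floor = max(p.latency_floor_ms, 220.0)
        for _ in range(1000):
            lat = p.latency_mean_ms + p.latency_sd_ms * self.rng.standard_normal()
            if lat >= floor:
                return float(lat)
        return float(floor)

    def truth(self) -> pd.DataFrame:
        return pd.DataFrame(self.truth_rows,
                            columns=["trial", "onset_ms", "true_x_deg", "true_y_deg",
                                     "sensitivity_db", "p_seen", "seen"])


@dataclass
class SimulationResult:
    """A simulated session plus its per-trial ground truth."""

    session: SessionResult
    truth: pd.DataFrame
    seed: int | None = None


def simulate_session(field: TrueField,
                     params: ObserverParams | None = None,
                     cfg: EngineConfig | None = None,
                     screen: ScreenModel | None = None,
                     seed: int = 0,
                     grid: MeasurementGrid | None = None) -> SimulationResult:
    """Run the closed-loop engine against a simulated observer.

    All stochastic draws (observer behavior and the engine's target shuffling)
    flow from one seed; identical seeds give byte-identical logs.
    """
    params = params or ObserverParams()
    cfg = cfg or EngineConfig()
    screen = screen or ScreenModel()
    grid = grid or build_measurement_grid(cfg.reps_per_location)
    ss = np.random.SeedSequence(seed)
    obs_rng, eng_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    observer = SimulatedObserver(field, params, obs_rng,
                                 sample_period_ms=cfg.sample_period_ms)
    session = run_session(grid, observer, cfg, screen, seed=eng_rng)
    return SimulationResult(session=session, truth=observer.truth(), seed=seed)


def synthetic_hfa(field: TrueField, laterality: str = "right",
                  measurement_sd_db: float = 1.0, seed: int = 0) -> HFAField:
    """Sample the ground-truth field at the 54 24-2 locations.

    Gaussian measurement noise is added and values are clipped to [0, 50] dB.
    The mean deviation is computed against a flat 30 dB age-normal surrogate
    over the 52 non-nasal points; real HFA MD uses an age-weighted normative
    model, but only ordering/offset behavior matters here.
    """
    if measurement_sd_db < 0:
        raise ConfigError("measurement_sd_db must be >= 0")
    rng = np.random.default_rng(seed)
    locs = build_24_2(laterality)
    sens = np.array([field.sensitivity_at(l.x_deg, l.y_deg) for l in locs])
    noisy = np.clip(sens + measurement_sd_db * rng.standard_normal(len(sens)), 0.0, 50.0)
    points = pd.DataFrame({
        "x_deg": [l.x_deg for l in locs],
        "y_deg": [l.y_deg for l in locs],
        "sensitivity_db": noisy,
    })
    non_nasal = points["x_deg"].abs() <= 21
    md = float((points.loc[non_nasal, "sensitivity_db"] - AGE_NORMAL_DB).mean())
    return HFAField(laterality=laterality, points=points, md_db=md)
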