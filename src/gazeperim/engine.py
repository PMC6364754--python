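"""Closed-loop trial engine for gaze-contingent suprathreshold perimetry.

The engine runs the "follow the dot" session: each trial it places a stimulus
at a fixed retinal offset from the participant's *current* fixation, watches
the 50 Hz gaze stream, and scores a hit if gaze enters a 2.9 deg radius around
the stimulus within 1500 ms of onset.  After a hit the stimulus stays visible
and becomes the anchor the participant naturally fixates next; after a miss
the previously seen target remains visible as an optional anchor.

The engine is display-free and hardware-free: it consumes any object with the
:class:`GazeSource` protocol, which a live tracker, a replayed CSV log, or the
simulated observer can all satisfy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Protocol, Sequence, runtime_checkable

import numpy as np

from .errors import GazePerimError
from .geometry import AngularPoint, ScreenModel, angular_position, cm_from_angle
from .grid import GridLocation, MeasurementGrid

logger = logging.getLogger(__name__)

HIT = "hit"
MISS = "miss"
UNTRACKABLE = "untrackable"


@dataclass(frozen=True)
class EngineConfig:
    """Timing and scoring parameters of the trial loop.

    hit_radius_deg : gaze must come within this angular radius of the
        stimulus for a hit (2.9 deg).
    response_window_ms : time allowed for the orienting response (1500 ms).
    reps_per_location : presentations per grid location (4).
    sample_rate_hz : gaze stream rate (50 Hz -> 20 ms spacing).
    lookback_ms : how far before trial resolution the post-hoc correction
        looks for the pre-saccadic fixation (200 ms).
    max_requeue_attempts : how often an unplaceable presentation is requeued
        before being dropped.
    stimulus_size_deg : Goldmann III target diameter (0.43 deg); used as a
        placement margin so the whole stimulus fits on screen.
    min_valid_samples : fewer valid samples than this inside the response
        window flags the trial untrackable.
    """

    hit_radius_deg: float = 2.9
    response_window_ms: float = 1500.0
    reps_per_location: int = 4
    sample_rate_hz: float = 50.0
    lookback_ms: float = 200.0
    max_requeue_attempts: int = 8
    stimulus_size_deg: float = 0.43
    min_valid_samples: int = 2

    def __post_init__(self):
        if min(self.hit_radius_deg, self.response_window_ms, self.reps_per_location,
               self.sample_rate_hz, self.lookback_ms, self.max_requeue_attempts) <= 0:
            raise GazePerimError("all engine parameters must be positive")
        if self.response_window_ms <= self.lookback_ms:
            raise GazePerimError("response_window_ms must exceed lookback_ms")

    @property
    def sample_period_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz


class GazeSample(NamedTuple):
    """One eye-tracker record: time, angular gaze position (screen frame),
    viewing distance, validity flag."""

    t_ms: float
    x_deg: float
    y_deg: float
    distance_cm: float
    valid: bool

    @property
    def pos(self) -> AngularPoint:
        return AngularPoint(self.x_deg, self.y_deg)


@runtime_checkable
class GazeSource(Protocol):
    """Pull-based gaze stream; may react to stimulus notifications."""

    def next_sample(self) -> GazeSample | None:
        """Next sample, or None when the stream is exhausted."""
        ...

    def notify_stimulus(self, stim_screen: AngularPoint, onset_ms: float) -> None:
        """Called when a stimulus appears (no-op for non-interactive sources)."""
        ...


class ReplaySource:
    """GazeSource over a pre-recorded sequence of samples."""

    def __init__(self, samples: Iterable[GazeSample]):
        self._it: Iterator[GazeSample] = iter(samples)

    def next_sample(self) -> GazeSample | None:
        return next(self._it, None)

    def notify_stimulus(self, stim_screen: AngularPoint, onset_ms: float) -> None:
        pass


@dataclass
class TrialRecord:
    """One stimulus presentation and its outcome."""

    index: int
    target_id: int
    intended_retinal: AngularPoint
    assumed_fixation: AngularPoint
    stim_screen: AngularPoint
    onset_ms: float
    onset_distance_cm: float
    outcome: str
    response_ms: float | None = None
    anchor_screen: AngularPoint | None = None


@dataclass
class SessionResult:
    """Full output of one session run."""

    trials: list[TrialRecord]
    gaze: list[GazeSample]
    truncated: bool = False
    dropped_locations: list[int] = field(default_factory=list)

    @property
    def quality(self) -> dict:
        counts = {HIT: 0, MISS: 0, UNTRACKABLE: 0}
        for t in self.trials:
            counts[t.outcome] += 1
        return {
            "n_trials": len(self.trials),
            "n_hit": counts[HIT],
            "n_miss": counts[MISS],
            "n_untrackable": counts[UNTRACKABLE],
            "n_dropped_unplaceable": len(self.dropped_locations),
            "truncated": self.truncated,
        }


class _TrialScorer:
    """Incremental hit/miss scorer over a gaze stream.

    The first *valid* sample with Euclidean angular distance <=
    hit_radius_deg and t - onset <= response_window_ms (both boundaries
    inclusive) makes the trial a hit, with response time t - onset.
    Distances are evaluated at the sample's own viewing distance: the
    physical stimulus position (fixed at onset) is re-expressed in degrees
    per sample when ``onset_distance_cm`` is given.
    """

    def __init__(self, stim_screen: AngularPoint, onset_ms: float,
                 cfg: EngineConfig, onset_distance_cm: float | None = None):
        self.stim_screen = stim_screen
        self.onset_ms = onset_ms
        self.cfg = cfg
        self.stim_cm = (cm_from_angle(stim_screen, onset_distance_cm)
                        if onset_distance_cm is not None else None)
        self.n_valid = 0
        self.hit_dt: float | None = None

    def offer(self, s: GazeSample) -> bool:
        """Feed one sample; returns True once the trial has resolved."""
        dt = s.t_ms - self.onset_ms
        if self.hit_dt is None and 0 <= dt <= self.cfg.response_window_ms and s.valid:
            self.n_valid += 1
            if self.stim_cm is not None and s.distance_cm > 0:
                stim_here = angular_position(self.stim_cm[0], self.stim_cm[1],
                                             s.distance_cm)
            else:
                stim_here = self.stim_screen
            if s.pos.distance_to(stim_here) <= self.cfg.hit_radius_deg:
                self.hit_dt = dt
        return self.hit_dt is not None or dt >= self.cfg.response_window_ms

    def result(self) -> tuple[str, float | None]:
        if self.hit_dt is not None:
            return HIT, self.hit_dt
        if self.n_valid < self.cfg.min_valid_samples:
            return UNTRACKABLE, None
        return MISS, None


def score_trial(samples: Sequence[GazeSample], stim_screen: AngularPoint,
                onset_ms: float, cfg: EngineConfig,
                onset_distance_cm: float | None = None) -> tuple[str, float | None]:
    """Score one trial from a gaze segment covering the response window.

    Returns ``(outcome, response_ms)``; see :class:`_TrialScorer` for the
    hit rule.  A trial with no hit and fewer than ``min_valid_samples`` valid
    samples in the window is flagged untrackable (tracker dropout, not field
    loss) and excluded from mapping downstream.
    """
    scorer = _TrialScorer(stim_screen, onset_ms, cfg, onset_distance_cm)
    for s in samples:
        if scorer.offer(s):
            break
    return scorer.result()


@dataclass
class _PendingRep:
    """One scheduled presentation of a grid location."""

    location: GridLocation
    unplaceable_count: int = 0
    last_attempt: float = -math.inf


def select_next_target(pending: Sequence[_PendingRep], fixation: AngularPoint,
                       screen: ScreenModel, distance_cm: float,
                       rng: np.random.Generator,
                       margin_deg: float = 0.0) -> tuple[int, bool]:
    """Choose which pending presentation to run next.

    Returns ``(index into pending, placeable)``.  A presentation is placeable
    when its stimulus position ``fixation + retinal offset`` fits fully on
    screen at the current viewing distance.  The test grid (42 x 30 deg) is
    wider than the screen (~28 x 19 deg), so peripheral rows are presentable
    only from eccentric fixations; the draw is therefore random *within the
    scarcest placeable geometry class* (the locations whose feasible fixation
    band is smallest), which schedules hard-to-place peripheral targets
    whenever gaze happens to allow them and keeps the end of the session from
    starving.  If nothing is placeable, the least-recently-attempted
    presentation is returned flagged unplaceable, so the caller can requeue
    or drop it.
    """
    if not pending:
        raise GazePerimError("no pending presentations: session complete")
    placeable = [i for i, rep in enumerate(pending)
                 if screen.contains(fixation + AngularPoint(rep.location.x_deg,
                                                            rep.location.y_deg),
                                    distance_cm, margin_deg=margin_deg)]
    if placeable:
        w, h = screen.angular_extent(distance_cm)
        # Feasible-fixation band area: small for peripheral rows/columns.
        def band(i: int) -> float:
            loc = pending[i].location
            return (w - abs(loc.x_deg)) * (h - abs(loc.y_deg))
        smallest = min(band(i) for i in placeable)
        scarce = [i for i in placeable if band(i) <= smallest + 1e-9]
        return int(scarce[int(rng.integers(len(scarce)))]), True
    stalest = min(range(len(pending)), key=lambda i: (pending[i].last_attempt, i))
    return stalest, False


def run_session(grid: MeasurementGrid, source: GazeSource, cfg: EngineConfig,
                screen: ScreenModel, seed: int | np.random.Generator) -> SessionResult:
    """Run a full session: every grid location attempted reps_per_location times.

    The gaze source is pulled one sample at a time; one sample elapses between
    trials.  The assumed fixation for each trial is the most recent valid gaze
    position at stimulus onset.  Returns the ordered trial log together with
    the full gaze log (the correction step needs it).  If the source is
    exhausted mid-session a partial log is returned with ``truncated=True``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pending = [_PendingRep(loc) for loc in grid.locations
               for _ in range(grid.reps_per_location)]
    margin = cfg.stimulus_size_deg / 2.0

    trials: list[TrialRecord] = []
    gaze: list[GazeSample] = []
    dropped: list[int] = []
    anchor: AngularPoint | None = None
    last_valid: GazeSample | None = None

    def pull() -> GazeSample | None:
        nonlocal last_valid
        s = source.next_sample()
        if s is not None:
            gaze.append(s)
            if s.valid:
                last_valid = s
        return s

    # Prime the stream until we have a fixation estimate.
    while last_valid is None:
        if pull() is None:
            return SessionResult(trials, gaze, truncated=True, dropped_locations=dropped)

    trial_index = 0
    while pending:
        sample = gaze[-1]
        fixation = last_valid.pos
        distance = last_valid.distance_cm
        idx, placeable = select_next_target(pending, fixation, screen, distance,
                                            rng, margin_deg=margin)
        if not placeable:
            rep = pending[idx]
            rep.unplaceable_count += 1
            rep.last_attempt = sample.t_ms
            if rep.unplaceable_count > cfg.max_requeue_attempts:
                logger.warning("dropping location %d after %d unplaceable attempts",
                               rep.location.id, rep.unplaceable_count)
                dropped.append(rep.location.id)
                pending.pop(idx)
            # Let time (and fixation) advance before retrying.
            if pull() is None:
                return SessionResult(trials, gaze, truncated=True,
                                     dropped_locations=dropped)
            continue

        rep = pending.pop(idx)
        intended = AngularPoint(rep.location.x_deg, rep.location.y_deg)
        stim = fixation + intended
        onset = sample.t_ms
        source.notify_stimulus(stim, onset)

        scorer = _TrialScorer(stim, onset, cfg, onset_distance_cm=distance)
        exhausted = False
        resolved = scorer.offer(sample)
        while not resolved:
            s = pull()
            if s is None:
                exhausted = True
                break
            resolved = scorer.offer(s)

        outcome, response = scorer.result()
        trials.append(TrialRecord(
            index=trial_index, target_id=rep.location.id, intended_retinal=intended,
            assumed_fixation=fixation, stim_screen=stim, onset_ms=onset,
            onset_distance_cm=distance, outcome=outcome, response_ms=response,
            anchor_screen=anchor))
        trial_index += 1
        if outcome == HIT:
            anchor = stim
        if exhausted:
            return SessionResult(trials, gaze, truncated=True, dropped_locations=dropped)
        # Inter-trial interval: one sample.
        if pull() is None:
            return SessionResult(trials, gaze, truncated=True, dropped_locations=dropped)

    return SessionResult(trials, gaze, truncated=False, dropped_locations=dropped)
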