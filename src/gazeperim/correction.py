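"""Post-hoc eye-movement correction of stimulus locations.

Because the participant is free to move their eyes, the retinal position a
stimulus actually occupied can differ from the intended grid offset.  After
each trial — hit or miss — the correction searches back 200 ms from the
trial's resolution and uses the gaze position at that prior time point to
replace the intended retinal location with the true one:

    true_retinal = stim_screen - gaze(resolution - lookback)

For hits the resolution is the response time; 200 ms earlier predates the
saccade (latencies exceed 200 ms), recovering the pre-saccadic fixation.  For
misses, where no response exists, the resolution is anchored at the end of
the response window.  The lookup takes the nearest valid sample; if none lies
within +-60 ms (three samples at 50 Hz) the intended location is retained and
flagged, rather than inventing a position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engine import HIT, MISS, EngineConfig, GazeSample, TrialRecord
from .errors import GazePerimError
from .geometry import AngularPoint

#: Maximum |sample time - reference time| before falling back to the
#: intended location (three samples at 50 Hz).
DEFAULT_TOLERANCE_MS = 60.0


@dataclass
class CorrectedTrial:
    """A trial annotated with its true retinal stimulus location."""

    trial: TrialRecord
    true_retinal: AngularPoint
    reference_t_ms: float
    fallback_used: bool

    @property
    def response(self) -> float:
        """Binary detection response: 1.0 for a hit, 0.0 for a miss."""
        return 1.0 if self.trial.outcome == HIT else 0.0


def _resolution_time(trial: TrialRecord, response_window_ms: float) -> float:
    if trial.outcome == HIT and trial.response_ms is not None:
        return trial.onset_ms + trial.response_ms
    return trial.onset_ms + response_window_ms


def correct_trial(trial: TrialRecord, gaze: Sequence[GazeSample],
                  lookback_ms: float = 200.0,
                  response_window_ms: float = 1500.0,
                  tolerance_ms: float = DEFAULT_TOLERANCE_MS) -> CorrectedTrial:
    """Correct one trial's retinal location from the session gaze log."""
    if len(gaze) == 0:
        raise GazePerimError("cannot correct trial: empty gaze stream")
    t = np.asarray([s.t_ms for s in gaze], dtype=float)
    valid = np.asarray([s.valid for s in gaze], dtype=bool)
    return _correct_one(trial, gaze, t, valid, lookback_ms,
                        response_window_ms, tolerance_ms)


def _correct_one(trial, gaze, t, valid, lookback_ms, response_window_ms,
                 tolerance_ms) -> CorrectedTrial:
    reference = _resolution_time(trial, response_window_ms) - lookback_ms
    offsets = np.abs(t - reference)
    offsets[~valid] = np.inf
    i = int(np.argmin(offsets))
    if not np.isfinite(offsets[i]) or offsets[i] > tolerance_ms:
        return CorrectedTrial(trial=trial, true_retinal=trial.intended_retinal,
                              reference_t_ms=reference, fallback_used=True)
    ref_gaze = gaze[i].pos
    true_retinal = trial.stim_screen - ref_gaze
    return CorrectedTrial(trial=trial, true_retinal=true_retinal,
                          reference_t_ms=reference, fallback_used=False)


def correct_session(trials: Sequence[TrialRecord], gaze: Sequence[GazeSample],
                    cfg: EngineConfig | None = None,
                    lookback_ms: float | None = None,
                    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
                    include_untrackable: bool = False) -> list[CorrectedTrial]:
    """Correct every scored trial of a session.

    Untrackable trials are excluded by default: they carry no usable response
    and would only dilute the field map.
    """
    if len(gaze) == 0:
        raise GazePerimError("cannot correct session: empty gaze stream")
    cfg = cfg or EngineConfig()
    lb = cfg.lookback_ms if lookback_ms is None else lookback_ms
    t = np.asarray([s.t_ms for s in gaze], dtype=float)
    valid = np.asarray([s.valid for s in gaze], dtype=bool)
    out = []
    for trial in trials:
        if trial.outcome not in (HIT, MISS) and not include_untrackable:
            continue
        out.append(_correct_one(trial, gaze, t, valid, lb,
                                cfg.response_window_ms, tolerance_ms))
    return out
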