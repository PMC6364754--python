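"""Agreement between the eye-movement test and standard automated perimetry.

Three comparisons against a Humphrey Field Analyzer (HFA) reference field:

* pointwise defect concordance — a 24-2 location counts as concordant when
  both tests classify it the same way, with defects defined as
  ``sensitivity < 25 dB`` (HFA) and ``hit rate < 0.5`` (this test).  Both
  cutoffs are parameters; conclusions should be robust to perturbing them.
* Pearson correlation between the summary measures (Mean Hit Rate vs MD).
* geometric-mean (standardized major axis) regression, the symmetric line
  fit appropriate when both axes carry error:
  slope = sign(r) * sd(y) / sd(x), intercept through the means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConcordanceError, ParseError
from .field_map import PoSSurface
from .grid import build_24_2

#: dB cutoff below which an HFA location counts as a defect.
DEFAULT_DB_CUTOFF = 25.0
#: hit-rate cutoff below which a kriged location counts as a defect.
DEFAULT_HR_CUTOFF = 0.5


@dataclass(frozen=True)
class HFAField:
    """A 24-2 field of decibel sensitivities plus its mean deviation."""

    laterality: str
    points: pd.DataFrame  # columns x_deg, y_deg, sensitivity_db (54 rows)
    md_db: float

    def __post_init__(self):
        required = {"x_deg", "y_deg", "sensitivity_db"}
        missing = required - set(self.points.columns)
        if missing:
            raise ParseError(f"HFA field missing columns {sorted(missing)}")
        if len(self.points) != 54:
            raise ParseError(f"HFA field must have 54 points, got {len(self.points)}")
        expected = {(loc.x_deg, loc.y_deg) for loc in build_24_2(self.laterality)}
        actual = set(zip(self.points["x_deg"].astype(float),
                         self.points["y_deg"].astype(float)))
        if actual != expected:
            raise ParseError(
                f"HFA point coordinates do not form the 24-2 lattice for a "
                f"{self.laterality} eye")
        s = self.points["sensitivity_db"].to_numpy(dtype=float)
        if np.any((s < 0) | (s > 50)):
            bad = int(np.argmax((s < 0) | (s > 50)))
            raise ParseError("sensitivity outside [0, 50] dB",
                             row=bad, column="sensitivity_db")


@dataclass
class ConcordanceResult:
    """Pointwise defect agreement between the two tests for one eye."""

    n_compared: int
    n_concordant: int
    n_excluded: int
    per_point: pd.DataFrame  # x_deg, y_deg, sensitivity_db, hit_rate, concordant

    @property
    def percent(self) -> float:
        return 100.0 * self.n_concordant / self.n_compared


def pointwise_concordance(surface: PoSSurface, hfa: HFAField,
                          db_cutoff: float = DEFAULT_DB_CUTOFF,
                          hr_cutoff: float = DEFAULT_HR_CUTOFF) -> ConcordanceResult:
    """Defect concordance at every 24-2 location inside the surface support.

    The hit rate at an HFA location is the kriged field evaluated at that
    exact coordinate; locations outside the support are excluded and counted.
    """
    pts = hfa.points[["x_deg", "y_deg"]].to_numpy(dtype=float)
    hr = surface.evaluate(pts)
    inside = np.isfinite(hr)
    if not inside.any():
        raise ConcordanceError("no HFA locations inside the surface support")
    db = hfa.points["sensitivity_db"].to_numpy(dtype=float)[inside]
    hr_in = hr[inside]
    defect_hfa = db < db_cutoff
    defect_ec = hr_in < hr_cutoff
    concordant = defect_hfa == defect_ec
    per_point = pd.DataFrame({
        "x_deg": pts[inside, 0], "y_deg": pts[inside, 1],
        "sensitivity_db": db, "hit_rate": hr_in,
        "defect_hfa": defect_hfa, "defect_ec": defect_ec,
        "concordant": concordant,
    })
    return ConcordanceResult(n_compared=int(inside.sum()),
                             n_concordant=int(concordant.sum()),
                             n_excluded=int((~inside).sum()),
                             per_point=per_point)


class AssociationResult(NamedTuple):
    r_squared: float
    pearson_p: float
    gmr_slope: float
    gmr_intercept: float
    n: int


def summary_association(x: Sequence[float], y: Sequence[float]) -> AssociationResult:
    """Pearson correlation and geometric-mean regression of paired summaries.

    ``x`` is typically Mean Hit Rate per eye and ``y`` the HFA mean deviation.
    The geometric-mean (standardized major axis) slope is
    ``sign(r) * sd(y) / sd(x)`` with the line passing through the means; it is
    symmetric in the sense that swapping the axes inverts the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ConcordanceError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ConcordanceError("zero variance on one axis")
    r, p = stats.pearsonr(x, y)
    slope = np.sign(r) * np.std(y, ddof=1) / np.std(x, ddof=1)
    intercept = float(y.mean() - slope * x.mean())
    return AssociationResult(r_squared=float(r ** 2), pearson_p=float(p),
                             gmr_slope=float(slope), gmr_intercept=intercept,
                             n=len(x))


def group_difference(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Convenience two-sample t-test (statistic, p) on per-eye summaries,
    e.g. Mean Hit Rate of patients vs controls."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(t), float(p)
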