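"""File formats: gaze/trial/corrected-trial/surface CSV, HFA fields, reports.

Fixed dialect: UTF-8 CSV with a header row, "." decimal separator, floats
serialized with ``%.12g`` (lossless round-trips to well below 1e-9 for the
magnitudes involved, and byte-stable for regression testing).  Provenance
metadata — the producing config hash and seed — is embedded as ``# key: value``
comment lines above the header; readers skip comment lines.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .concordance import HFAField
from .correction import CorrectedTrial
from .engine import GazeSample, TrialRecord
from .errors import ParseError
from .field_map import PoSSurface
from .geometry import AngularPoint

FLOAT_FMT = "%.12g"

GAZE_COLUMNS = ["t_ms", "x_deg", "y_deg", "distance_cm", "valid"]
TRIAL_COLUMNS = ["index", "target_id", "intended_x_deg", "intended_y_deg",
                 "fix_x_deg", "fix_y_deg", "stim_x_deg", "stim_y_deg",
                 "onset_ms", "onset_distance_cm", "outcome", "response_ms",
                 "anchor_x_deg", "anchor_y_deg"]
CORRECTED_COLUMNS = TRIAL_COLUMNS + ["true_x_deg", "true_y_deg",
                                     "reference_t_ms", "fallback_used"]
SURFACE_COLUMNS = ["x_deg", "y_deg", "p_seen", "in_support"]


def _write_csv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def write_frame_csv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write an arbitrary DataFrame in the package dialect."""
    _write_csv(df, path, meta)


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{Path(path).name}: missing columns {missing}",
                         column=missing[0])
    return df


def read_csv_meta(path) -> dict:
    """The ``# key: value`` comment header of one of our CSV files."""
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    return meta


# -- gaze logs ---------------------------------------------------------------

def write_gaze_csv(samples: Sequence[GazeSample], path, meta: dict | None = None):
    df = pd.DataFrame(samples, columns=GAZE_COLUMNS)
    df["valid"] = df["valid"].astype(int)
    _write_csv(df, path, meta)


def read_gaze_csv(path) -> list[GazeSample]:
    df = _read_csv(path, GAZE_COLUMNS)
    t = df["t_ms"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ParseError(f"{Path(path).name}: timestamps not strictly increasing",
                         row=int(bad[0] + 1), column="t_ms")
    if not df["valid"].isin([0, 1]).all():
        row = int(df.index[~df["valid"].isin([0, 1])][0])
        raise ParseError(f"{Path(path).name}: validity flag must be 0/1",
                         row=row, column="valid")
    return [GazeSample(float(r.t_ms), float(r.x_deg), float(r.y_deg),
                       float(r.distance_cm), bool(r.valid))
            for r in df.itertuples(index=False)]


# -- trial logs ----------------------------------------------------------------

def _trial_row(t: TrialRecord) -> dict:
    return {
        "index": t.index, "target_id": t.target_id,
        "intended_x_deg": t.intended_retinal.x_deg,
        "intended_y_deg": t.intended_retinal.y_deg,
        "fix_x_deg": t.assumed_fixation.x_deg,
        "fix_y_deg": t.assumed_fixation.y_deg,
        "stim_x_deg": t.stim_screen.x_deg, "stim_y_deg": t.stim_screen.y_deg,
        "onset_ms": t.onset_ms, "onset_distance_cm": t.onset_distance_cm,
        "outcome": t.outcome,
        "response_ms": t.response_ms if t.response_ms is not None else math.nan,
        "anchor_x_deg": t.anchor_screen.x_deg if t.anchor_screen else math.nan,
        "anchor_y_deg": t.anchor_screen.y_deg if t.anchor_screen else math.nan,
    }


def _trial_from_row(r) -> TrialRecord:
    anchor = None
    if not (isinstance(r.anchor_x_deg, float) and math.isnan(r.anchor_x_deg)):
        anchor = AngularPoint(float(r.anchor_x_deg), float(r.anchor_y_deg))
    response = None if math.isnan(r.response_ms) else float(r.response_ms)
    return TrialRecord(
        index=int(r.index), target_id=int(r.target_id),
        intended_retinal=AngularPoint(float(r.intended_x_deg), float(r.intended_y_deg)),
        assumed_fixation=AngularPoint(float(r.fix_x_deg), float(r.fix_y_deg)),
        stim_screen=AngularPoint(float(r.stim_x_deg), float(r.stim_y_deg)),
        onset_ms=float(r.onset_ms), onset_distance_cm=float(r.onset_distance_cm),
        outcome=str(r.outcome), response_ms=response, anchor_screen=anchor)


def write_trials_csv(trials: Sequence[TrialRecord], path, meta: dict | None = None):
    _write_csv(pd.DataFrame([_trial_row(t) for t in trials], columns=TRIAL_COLUMNS),
               path, meta)


def read_trials_csv(path) -> list[TrialRecord]:
    df = _read_csv(path, TRIAL_COLUMNS)
    return [_trial_from_row(r) for r in df.itertuples(index=False)]


# -- corrected trials ---------------------------------------------------------

def write_corrected_csv(corrected: Sequence[CorrectedTrial], path,
                        meta: dict | None = None):
    rows = []
    for c in corrected:
        row = _trial_row(c.trial)
        row.update(true_x_deg=c.true_retinal.x_deg, true_y_deg=c.true_retinal.y_deg,
                   reference_t_ms=c.reference_t_ms, fallback_used=int(c.fallback_used))
        rows.append(row)
    _write_csv(pd.DataFrame(rows, columns=CORRECTED_COLUMNS), path, meta)


def read_corrected_csv(path) -> list[CorrectedTrial]:
    df = _read_csv(path, CORRECTED_COLUMNS)
    out = []
    for r in df.itertuples(index=False):
        out.append(CorrectedTrial(
            trial=_trial_from_row(r),
            true_retinal=AngularPoint(float(r.true_x_deg), float(r.true_y_deg)),
            reference_t_ms=float(r.reference_t_ms),
            fallback_used=bool(r.fallback_used)))
    return out


# -- surfaces ------------------------------------------------------------------

def write_surface_csv(surface: PoSSurface, path, meta: dict | None = None):
    gx, gy = np.meshgrid(surface.x_deg, surface.y_deg)
    df = pd.DataFrame({
        "x_deg": gx.ravel(), "y_deg": gy.ravel(),
        "p_seen": surface.values.ravel(),
        "in_support": surface.support_mask.ravel().astype(int),
    })
    _write_csv(df, path, meta)


def read_surface_csv(path) -> PoSSurface:
    """Read a lattice surface (no fitted model: exact evaluation unavailable)."""
    df = _read_csv(path, SURFACE_COLUMNS)
    p = df["p_seen"].to_numpy(dtype=float)
    bad = np.nonzero(np.isfinite(p) & ((p < 0) | (p > 1)))[0]
    if bad.size:
        raise ParseError(f"{Path(path).name}: probability outside [0, 1]",
                         row=int(bad[0]), column="p_seen")
    xs = np.unique(df["x_deg"].to_numpy(dtype=float))
    ys = np.unique(df["y_deg"].to_numpy(dtype=float))
    if len(xs) * len(ys) != len(df):
        raise ParseError(f"{Path(path).name}: not a complete lattice")
    order = np.lexsort([df["x_deg"].to_numpy(), df["y_deg"].to_numpy()])
    values = p[order].reshape(len(ys), len(xs))
    mask = df["in_support"].to_numpy()[order].reshape(len(ys), len(xs)).astype(bool)
    return PoSSurface(x_deg=xs, y_deg=ys, values=values, support_mask=mask, model=None)


def plot_surface_png(surface: PoSSurface, path, title: str | None = None,
                     sites: np.ndarray | None = None):
    """Render the PoS heatmap (red = unlikely to see, green = likely)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    extent = (surface.x_deg[0], surface.x_deg[-1],
              surface.y_deg[0], surface.y_deg[-1])
    im = ax.imshow(surface.values, origin="lower", extent=extent,
                   cmap="RdYlGn", vmin=0.0, vmax=1.0, aspect="equal")
    if sites is not None and len(sites):
        ax.plot(sites[:, 0], sites[:, 1], "k.", ms=2, alpha=0.5)
    ax.set_xlabel("x (deg)")
    ax.set_ylabel("y (deg)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="probability of seeing")
    fig.savefig(path, dpi=120)
    plt.close(fig)


# -- HFA fields ----------------------------------------------------------------

def write_hfa_json(field: HFAField, path, meta: dict | None = None):
    payload = {
        "laterality": field.laterality,
        "md_db": field.md_db,
        "points": field.points[["x_deg", "y_deg", "sensitivity_db"]]
                       .to_dict(orient="records"),
    }
    if meta:
        payload["meta"] = meta
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def read_hfa_json(path) -> HFAField:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"{Path(path).name}: invalid JSON: {exc}") from exc
    for key in ("laterality", "md_db", "points"):
        if key not in payload:
            raise ParseError(f"{Path(path).name}: missing key {key!r}", column=key)
    points = pd.DataFrame(payload["points"])
    return HFAField(laterality=payload["laterality"], points=points,
                    md_db=float(payload["md_db"]))


def read_hfa_csv(path) -> HFAField:
    """CSV variant: x_deg, y_deg, sensitivity_db columns with laterality and
    md_db carried in the ``#`` comment header."""
    meta = read_csv_meta(path)
    for key in ("laterality", "md_db"):
        if key not in meta:
            raise ParseError(f"{Path(path).name}: missing '# {key}:' header",
                             column=key)
    df = _read_csv(path, ["x_deg", "y_deg", "sensitivity_db"])
    return HFAField(laterality=meta["laterality"], points=df,
                    md_db=float(meta["md_db"]))


def read_hfa(path) -> HFAField:
    path = Path(path)
    return read_hfa_json(path) if path.suffix.lower() == ".json" else read_hfa_csv(path)


def write_report_json(report: dict, path):
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
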