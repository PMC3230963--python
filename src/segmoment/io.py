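"""Session file formats and report rendering.

Session CSV dialect (comma-separated, UTF-8, header required, units in
the column names to prevent silent unit errors):

    set_id, state{alpha|beta}, support_id{1|2|3}, x_cm, y_cm, reading_g

one row per support reading, six rows per complete measurement set.  The
companion geometry JSON carries what the CSV cannot: the rotation center,
the per-set rotation angle in degrees, and optionally the calibrated
reference moment and the declared total mass for QC:

    {
      "rotation_center_cm": [0.0, 0.0],
      "theta_deg": 48.8                  # or {"set001": 30.0, ...}
      "calibrated_moment_kgcm": 116.3,   # optional
      "declared_total_kg": 66.706        # optional
    }
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .errors import ConfigError, SessionFormatError
from .estimator import MeasurementPair, MomentEstimate, SessionSummary
from .geometry import PlanarPoint
from .simulate import SimulatedRecord
from .supports import SupportSet, compute_com

SESSION_COLUMNS = ["set_id", "state", "support_id", "x_cm", "y_cm", "reading_g"]
_STATES = ("alpha", "beta")


def write_session_csv(records: Sequence[SimulatedRecord], path) -> None:
    """Write measurement sets in the session CSV dialect."""
    rows = []
    for rec in records:
        for state, sset in (("alpha", rec.alpha), ("beta", rec.beta)):
            for i in range(3):
                rows.append(
                    {
                        "set_id": rec.set_id,
                        "state": state,
                        "support_id": i + 1,
                        "x_cm": sset.points[i, 0],
                        "y_cm": sset.points[i, 1],
                        "reading_g": sset.readings_g[i],
                    }
                )
    pd.DataFrame(rows, columns=SESSION_COLUMNS).to_csv(path, index=False)


def read_session_csv(path) -> Dict[str, Dict[str, SupportSet]]:
    """Parse a session CSV into ``{set_id: {"alpha": SupportSet, "beta": ...}}``.

    Row order is irrelevant; a missing support row, unknown state label or
    non-numeric field raises :class:`SessionFormatError` naming the
    offending set/row.
    """
    try:
        df = pd.read_csv(path, dtype={"set_id": str})
    except Exception as exc:  # noqa: BLE001 - surface any parse failure uniformly
        raise SessionFormatError(f"cannot read session CSV {path}: {exc}") from exc
    missing_cols = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SessionFormatError(f"session CSV missing columns: {missing_cols}")
    for col in ("support_id", "x_cm", "y_cm", "reading_g"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header is line 1
            raise SessionFormatError(f"non-numeric value in column {col!r} at line {row}")
        df[col] = coerced
    bad_state = ~df["state"].isin(_STATES)
    if bad_state.any():
        row = int(df.index[bad_state][0]) + 2
        raise SessionFormatError(
            f"unknown state label {df.loc[df.index[bad_state][0], 'state']!r} at line {row}"
        )
    sets: Dict[str, Dict[str, SupportSet]] = {}
    for (set_id, state), grp in df.groupby(["set_id", "state"], sort=False):
        ids = sorted(grp["support_id"].tolist())
        if ids != [1, 2, 3]:
            raise SessionFormatError(
                f"set {set_id!r} state {state!r}: expected support rows [1, 2, 3], got {ids}"
            )
        grp = grp.sort_values("support_id")
        sets.setdefault(str(set_id), {})[str(state)] = SupportSet.from_grams(
            grp[["x_cm", "y_cm"]].to_numpy(), grp["reading_g"].to_numpy()
        )
    for set_id, states in sets.items():
        for st in _STATES:
            if st not in states:
                raise SessionFormatError(f"set {set_id!r} is missing state {st!r}")
    return sets


@dataclass(frozen=True)
class SessionGeometry:
    """Sidecar metadata for a session CSV."""

    rotation_center: PlanarPoint
    theta_deg: Union[float, Mapping[str, float]]
    calibrated_moment_kgcm: Optional[float] = None
    declared_total_kg: Optional[float] = None

    def theta_for(self, set_id: str) -> float:
        if isinstance(self.theta_deg, Mapping):
            try:
                return float(self.theta_deg[set_id])
            except KeyError:
                raise SessionFormatError(
                    f"geometry JSON has no rotation angle for set {set_id!r}"
                ) from None
        return float(self.theta_deg)


_GEOMETRY_KEYS = {
    "rotation_center_cm",
    "theta_deg",
    "calibrated_moment_kgcm",
    "declared_total_kg",
}


def read_geometry_json(path) -> SessionGeometry:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    unknown = set(raw) - _GEOMETRY_KEYS
    if unknown:
        raise ConfigError(f"unknown geometry keys: {sorted(unknown)}")
    for key in ("rotation_center_cm", "theta_deg"):
        if key not in raw:
            raise ConfigError(f"geometry JSON missing required key {key!r}")
    theta = raw["theta_deg"]
    if isinstance(theta, dict):
        theta = {str(k): float(v) for k, v in theta.items()}
    else:
        theta = float(theta)
    return SessionGeometry(
        rotation_center=PlanarPoint.from_array(raw["rotation_center_cm"]),
        theta_deg=theta,
        calibrated_moment_kgcm=(
            None if raw.get("calibrated_moment_kgcm") is None
            else float(raw["calibrated_moment_kgcm"])
        ),
        declared_total_kg=(
            None if raw.get("declared_total_kg") is None else float(raw["declared_total_kg"])
        ),
    )


def write_geometry_json(
    path,
    rotation_center=(0.0, 0.0),
    theta_deg: Union[float, Mapping[str, float]] = 0.0,
    calibrated_moment_kgcm: Optional[float] = None,
    declared_total_kg: Optional[float] = None,
) -> None:
    payload = {
        "rotation_center_cm": list(PlanarPoint.from_array(rotation_center)),
        "theta_deg": dict(theta_deg) if isinstance(theta_deg, Mapping) else float(theta_deg),
    }
    if calibrated_moment_kgcm is not None:
        payload["calibrated_moment_kgcm"] = float(calibrated_moment_kgcm)
    if declared_total_kg is not None:
        payload["declared_total_kg"] = float(declared_total_kg)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def build_pairs(
    sets: Mapping[str, Mapping[str, SupportSet]], geometry: SessionGeometry
) -> List[Tuple[str, MeasurementPair]]:
    """Combine parsed support sets with geometry into estimator inputs."""
    pairs = []
    for set_id, states in sets.items():
        pairs.append(
            (
                set_id,
                MeasurementPair(
                    state_alpha=compute_com(states["alpha"], label="alpha"),
                    state_beta=compute_com(states["beta"], label="beta"),
                    theta_deg=geometry.theta_for(set_id),
                    rotation_center=geometry.rotation_center,
                ),
            )
        )
    return pairs


def pairs_from_records(
    records: Sequence[SimulatedRecord], rotation_center=(0.0, 0.0)
) -> List[Tuple[str, MeasurementPair]]:
    """Turn simulated records directly into estimator inputs (no files)."""
    return [
        (
            rec.set_id,
            MeasurementPair(
                state_alpha=compute_com(rec.alpha, label="alpha"),
                state_beta=compute_com(rec.beta, label="beta"),
                theta_deg=rec.theta_recorded_deg,
                rotation_center=rotation_center,
            ),
        )
        for rec in records
    ]


def summary_to_dict(summary: SessionSummary) -> dict:
    """Full-precision JSON-ready representation of a session summary."""
    return {
        "n": summary.n,
        "mean_kgcm": summary.mean_kgcm,
        "sd_kgcm": summary.sd_kgcm,
        "calibrated_kgcm": summary.calibrated_kgcm,
        "rms_vs_calibrated_kgcm": summary.rms_vs_calibrated_kgcm,
        "relative_sd_pct": summary.relative_sd_pct,
        "relative_rms_pct": summary.relative_rms_pct,
    }


def summary_from_dict(d: Mapping) -> SessionSummary:
    return SessionSummary(
        n=int(d["n"]),
        mean_kgcm=float(d["mean_kgcm"]),
        sd_kgcm=None if d.get("sd_kgcm") is None else float(d["sd_kgcm"]),
        calibrated_kgcm=(
            None if d.get("calibrated_kgcm") is None else float(d["calibrated_kgcm"])
        ),
        rms_vs_calibrated_kgcm=(
            None
            if d.get("rms_vs_calibrated_kgcm") is None
            else float(d["rms_vs_calibrated_kgcm"])
        ),
        relative_sd_pct=(
            None if d.get("relative_sd_pct") is None else float(d["relative_sd_pct"])
        ),
        relative_rms_pct=(
            None if d.get("relative_rms_pct") is None else float(d["relative_rms_pct"])
        ),
    )


def render_report(summary: SessionSummary) -> str:
    """Human-readable summary; relative figures rounded to one decimal,
    SD/RMS lines omitted (not zeroed) when unavailable."""
    lines = [
        f"n sets:            {summary.n}",
        f"mean moment:       {summary.mean_kgcm:.1f} kg·cm",
    ]
    if summary.sd_kgcm is not None:
        lines.append(
            f"standard dev.:     {summary.sd_kgcm:.3f} kg·cm ({summary.relative_sd_pct:.1f}%)"
        )
    if summary.calibrated_kgcm is not None:
        lines.append(f"calibrated value:  {summary.calibrated_kgcm:.1f} kg·cm")
    if summary.rms_vs_calibrated_kgcm is not None:
        lines.append(
            f"RMS vs calibrated: {summary.rms_vs_calibrated_kgcm:.1f} kg·cm "
            f"({summary.relative_rms_pct:.1f}%)"
        )
    return "\n".join(lines)


def write_estimates_csv(estimates: Sequence[Tuple[str, MomentEstimate]], path) -> None:
    pd.DataFrame(
        [
            {
                "set_id": set_id,
                "theta_deg": est.theta_deg,
                "total_mass_kg": est.total_mass_kg,
                "moment_kgcm": est.moment_kgcm,
                "com1_scaled_x_cm": est.com1_alpha_scaled.x,
                "com1_scaled_y_cm": est.com1_alpha_scaled.y,
            }
            for set_id, est in estimates
        ]
    ).to_csv(path, index=False)
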