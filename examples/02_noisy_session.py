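"""A full noisy measurement campaign, end to end.

Simulates 30 measurement sets of the calibrated dummy-bar setup with the
default noise model (scale precision 1.5 g quantized to 0.1 g, protractor
sigma 0.5 deg, support-digitization sigma 0.2 cm) at rotation angles
spanning 30-180 degrees, writes the session to the CSV + geometry-JSON
interchange format, reads it back, re-estimates every set, and prints the
session summary against the calibrated reference moment.
"""

import tempfile
from pathlib import Path

import numpy as np

from segmoment import NoiseModel, dummy_bar_model, estimate_moment, simulate_session, summarize_session
from segmoment.io import (
    build_pairs,
    read_geometry_json,
    read_session_csv,
    render_report,
    write_geometry_json,
    write_session_csv,
)

model = dummy_bar_model()
session = simulate_session(
    model, np.linspace(30, 180, 30), noise=NoiseModel(), seed=2026
)

with tempfile.TemporaryDirectory() as tmp:
    csv, geom = Path(tmp) / "session.csv", Path(tmp) / "geometry.json"
    write_session_csv(session.records, csv)
    write_geometry_json(
        geom,
        theta_deg={r.set_id: r.theta_recorded_deg for r in session.records},
        calibrated_moment_kgcm=model.true_moment_kgcm,
    )
    sets = read_session_csv(csv)
    geometry = read_geometry_json(geom)
    estimates = [estimate_moment(pair) for _, pair in build_pairs(sets, geometry)]

summary = summarize_session(estimates, calibrated_kgcm=model.true_moment_kgcm)
print(render_report(summary))

# The mean sits within a fraction of a percent of the calibrated
# 116.3 kg·cm; the SD and the RMS-vs-calibrated lines quantify the
# session's precision and single-set accuracy under this noise model.
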