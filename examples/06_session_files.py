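"""File-based workflow: simulate a session directory, then re-extract it.

The session holds participants.csv, per-trial trace CSVs and a manifest
with the seed and config hash; extraction reproduces the assessment from
the files alone.  Uses the raw-voltage dialect to exercise the
calibration path (mV -> N via zero offset and gain factor).
"""

import tempfile
from pathlib import Path

from stancestrength import CohortGenConfig, PipelineConfig, extract_session, simulate_session
from stancestrength.cohort import TraceGenConfig

config = PipelineConfig(
    seed=5,
    cohort=CohortGenConfig(seed=5, n_per_stratum={("male", "G65"): 2, ("female", "G65"): 2}),
    trace=TraceGenConfig(seed=0, target_mvc=1.0, lead_in=0.2, ramp_time=0.4,
                         plateau_time=1.6, release_time=0.2),
    dialect="voltage",
)

with tempfile.TemporaryDirectory() as tmp:
    session = simulate_session(config, Path(tmp) / "session")
    print("session files:", sorted(p.name for p in session.iterdir()))
    n_traces = len(list((session / "traces").glob("*.csv")))
    print(f"{n_traces} voltage-dialect trace files (6 directions x 3 trials each)")

    assessment = extract_session(session)
    print("\nassessment (one row per participant x direction):")
    print(assessment.head(6).round(3).to_string(index=False))
# Re-running simulate_session with the same seed writes byte-identical
# files; the manifest's config hash makes any configuration drift visible.
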