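"""One participant's six-direction assessment, normalised to N/kg.

Builds three synthetic trials for each of the six directions (frontal
adduction/abduction on Fx; sagittal push/pull with either leg forward on
Fy), runs the full extraction, and prints absolute and relative scores.
"""

import numpy as np

from stancestrength import Participant, TraceGenConfig, generate_trace, run_assessment
from stancestrength.protocol import DIRECTIONS, mass_from_fz
from stancestrength.preprocess import ForceTrace

participant = Participant(id="demo", sex="male", age=25, height=186.0, mass=86.0)

# per-direction capacities for this subject, N/kg
capacity = {"A": 1.85, "B": 1.80, "D1": 2.85, "D2": 2.50, "K1": 2.82, "K2": 2.20}

trials = {}
seed = 0
for code, direction in DIRECTIONS.items():
    target = capacity[code] * participant.mass
    trials[code] = []
    for _ in range(3):
        seed += 1
        trials[code].append(
            generate_trace(
                TraceGenConfig(seed=seed, target_mvc=target),
                axis=direction.axis,
                effort_sign=direction.effort_sign,
                body_weight_n=participant.mass * 9.81,
            )
        )

result = run_assessment(participant, trials)
print(f"{participant.id}: {participant.sex}, {participant.age:.0f} y, "
      f"{participant.mass:.0f} kg (group {participant.age_group})")
for code in DIRECTIONS:
    print(f"  {code:>2}: best {result.best_mvc[code]:6.1f} N -> "
          f"{result.relative[code]:.3f} N/kg (configured {capacity[code]:.2f})")

# body mass can also come from the vertical channel during quiet standing
quiet = ForceTrace(
    fs=1400.0,
    fx=np.zeros(2800), fy=np.zeros(2800),
    fz=participant.mass * 9.81 + np.random.default_rng(0).normal(0, 4.0, 2800),
)
print(f"mass from quiet-stance Fz: {mass_from_fz(quiet):.2f} kg "
      f"(record says {participant.mass:.2f})")
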