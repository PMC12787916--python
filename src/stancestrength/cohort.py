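"""Synthetic participants, force traces, and full cohorts.

No raw recordings from the study are deposited, so every downstream
stage is exercised on synthetic data with the statistical structure the
analysis assumes:

* force traces are ramp-to-plateau maximal efforts with band-limited
  physiological tremor (8–12 Hz, below the 15 Hz cutoff so the filter is
  exercised meaningfully), wideband sensor noise, and sparse
  single-sample spike artifacts;
* participants are drawn per stratum (2 sexes x 3 age groups) from the
  published anthropometric means/SDs, truncated to the published ranges;
* relative strength per direction is Normal(stratum mean, SD) truncated
  at zero, with additive (non-interacting) sex and age effects by
  default — male > female in every direction and a decline with age.

Mean anchors come from the published group means where printed
(direction A in the youngest group, direction D2 in the middle group);
the remaining cell means and the within-stratum SDs are stated
assumptions: SDs are back-computed from the published two-way-ANOVA
error mean squares (sqrt(SS_error / 93) per direction), the rest chosen
to reproduce the published male-advantage and age-decline percentages to
first order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy import signal, special
from scipy.optimize import brentq

from .preprocess import ForceTrace, PreprocessConfig
from .protocol import (
    AGE_GROUP_RANGES,
    AGE_GROUPS,
    DIRECTION_CODES,
    SEXES,
    STANDARD_GRAVITY,
    AssessmentResult,
    Participant,
    run_assessment,
)

__all__ = [
    "TraceGenConfig",
    "CohortGenConfig",
    "CohortError",
    "generate_trace",
    "generate_participant",
    "generate_cohort",
    "ANTHROPOMETRICS",
    "DEFAULT_N_PER_STRATUM",
    "DEFAULT_DIRECTION_SD",
]


class CohortError(ValueError):
    """Invalid generator configuration."""


# (sex, age_group) -> height mean, height sd, height range, mass mean, mass sd, mass range
ANTHROPOMETRICS: dict[tuple[str, str], dict[str, tuple[float, ...]]] = {
    ("male", "G25"): {"height": (186.47, 8.50, 175, 205), "mass": (86.11, 15.52, 61, 117)},
    ("female", "G25"): {"height": (168.22, 7.29, 158, 183), "mass": (63.00, 11.12, 44, 91)},
    ("male", "G45"): {"height": (186.35, 8.05, 176, 202), "mass": (91.53, 15.91, 75, 123)},
    ("female", "G45"): {"height": (168.67, 15.95, 160, 175), "mass": (71.07, 10.99, 53, 95)},
    ("male", "G65"): {"height": (177.27, 5.58, 169, 186), "mass": (81.27, 12.83, 62, 106)},
    ("female", "G65"): {"height": (168.80, 5.04, 162, 179), "mass": (71.00, 11.05, 59, 98)},
}

# published per-group sample sizes (men 19/17/15, women 18/17/15)
DEFAULT_N_PER_STRATUM: dict[tuple[str, str], int] = {
    ("male", "G25"): 19,
    ("female", "G25"): 18,
    ("male", "G45"): 17,
    ("female", "G45"): 17,
    ("male", "G65"): 15,
    ("female", "G65"): 15,
}

# additive strength structure, N/kg: female G25 baseline + male advantage
# + age-group offset, per direction
_FEMALE_G25_MEAN = {"A": 1.3659, "B": 1.55, "D1": 2.35, "D2": 1.8909, "K1": 2.30, "K2": 1.70}
_MALE_ADVANTAGE = {"A": 0.4845, "B": 0.25, "D1": 0.50, "D2": 0.6130, "K1": 0.52, "K2": 0.50}
_AGE_OFFSET = {
    "G25": {d: 0.0 for d in DIRECTION_CODES},
    "G45": {"A": -0.10, "B": -0.15, "D1": -0.20, "D2": -0.20, "K1": -0.22, "K2": -0.25},
    "G65": {"A": -0.40, "B": -0.50, "D1": -0.65, "D2": -0.55, "K1": -0.70, "K2": -0.55},
}

# within-stratum SD of relative strength, N/kg: sqrt(error MS) of the
# published two-way ANOVA, error df = 93
_ERROR_SS = {"A": 8.47, "B": 14.05, "D1": 17.46, "D2": 10.73, "K1": 22.12, "K2": 14.59}
DEFAULT_DIRECTION_SD = {d: float(np.sqrt(ss / 93.0)) for d, ss in _ERROR_SS.items()}


@dataclass(frozen=True)
class TraceGenConfig:
    """One synthetic maximal-effort trace.

    The effort is zero baseline -> smooth (half-cosine) ramp -> plateau at
    ``target_mvc`` -> release.  ``tremor_sd``, ``wideband_noise_sd`` and
    ``spike_amplitude`` default to fractions of the target so that noise
    scales with effort the way physiological tremor does.
    """

    seed: int
    target_mvc: float  # newtons
    ramp_time: float = 1.0  # s
    plateau_time: float = 3.0  # s
    lead_in: float = 0.5  # s of zero baseline
    release_time: float = 0.5  # s
    tremor_band: tuple[float, float] = (8.0, 12.0)  # Hz
    tremor_sd: float | None = None  # N; default 2% of target
    wideband_noise_sd: float | None = None  # N; default 1% of target
    spike_rate: float = 0.2  # events/s
    spike_amplitude: float | None = None  # N; default 50% of target

    def __post_init__(self) -> None:
        if self.target_mvc <= 0:
            raise CohortError(f"target_mvc must be > 0, got {self.target_mvc}")
        for name in ("ramp_time", "plateau_time", "lead_in", "release_time"):
            if getattr(self, name) < 0:
                raise CohortError(f"{name} must be >= 0")
        if self.plateau_time < 1.5:
            raise CohortError(
                f"plateau_time {self.plateau_time} s is shorter than the 1.5 s "
                "sustained-effort window the protocol requires"
            )
        lo, hi = self.tremor_band
        if not 0 < lo < hi:
            raise CohortError(f"tremor_band must be increasing positive, got {self.tremor_band}")
        for name in ("tremor_sd", "wideband_noise_sd", "spike_amplitude"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise CohortError(f"{name} must be >= 0")
        if self.spike_rate < 0:
            raise CohortError("spike_rate must be >= 0")

    @property
    def resolved_tremor_sd(self) -> float:
        return 0.02 * self.target_mvc if self.tremor_sd is None else self.tremor_sd

    @property
    def resolved_wideband_sd(self) -> float:
        return 0.01 * self.target_mvc if self.wideband_noise_sd is None else self.wideband_noise_sd

    @property
    def resolved_spike_amplitude(self) -> float:
        return 0.5 * self.target_mvc if self.spike_amplitude is None else self.spike_amplitude


def _smoothstep(t: np.ndarray) -> np.ndarray:
    # C3 smoothstep: zero 1st-3rd derivatives at both ends, so the ramp
    # leaks almost nothing above the 15 Hz filter cutoff and the filtered
    # plateau carries no visible ringing
    return 35 * t**4 - 84 * t**5 + 70 * t**6 - 20 * t**7


def _effort_envelope(cfg: TraceGenConfig, fs: float) -> np.ndarray:
    n_lead = int(round(cfg.lead_in * fs))
    n_ramp = int(round(cfg.ramp_time * fs))
    n_plateau = int(round(cfg.plateau_time * fs))
    n_release = int(round(cfg.release_time * fs))
    ramp = _smoothstep(np.arange(1, n_ramp + 1) / n_ramp) if n_ramp else np.empty(0)
    release = _smoothstep(1 - np.arange(1, n_release + 1) / n_release) if n_release else np.empty(0)
    env = np.concatenate(
        [np.zeros(n_lead), ramp, np.ones(n_plateau), release]
    )
    return cfg.target_mvc * env


def _band_limited_noise(n: int, fs: float, band: tuple[float, float], sd: float,
                        rng: np.random.Generator) -> np.ndarray:
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    lo, hi = band
    hi = min(hi, 0.999 * fs / 2)
    sos = signal.butter(2, (lo, hi), btype="band", fs=fs, output="sos")
    shaped = signal.sosfiltfilt(sos, white)
    rms = float(np.sqrt(np.mean(shaped**2)))
    return shaped * (sd / rms) if rms > 0 else np.zeros(n)


def generate_trace(
    cfg: TraceGenConfig,
    fs: float = 1400.0,
    axis: str = "fy",
    effort_sign: int = +1,
    body_weight_n: float = 687.0,
) -> ForceTrace:
    """Synthesize one maximal-effort trace.

    The effort (with tremor, wideband noise and spikes, all gated by the
    effort envelope where physiologically appropriate) is written to
    ``axis`` with ``effort_sign``; the vertical channel carries body
    weight plus small balance noise; the unused horizontal channel
    carries sensor noise only.  Same seed, same trace — bit identical.
    """
    rng = np.random.default_rng(cfg.seed)
    env = _effort_envelope(cfg, fs)
    n = len(env)
    gate = env / cfg.target_mvc  # 0..1, tremor scales with effort
    tremor = _band_limited_noise(n, fs, cfg.tremor_band, cfg.resolved_tremor_sd, rng) * gate
    wide = (
        rng.standard_normal(n) * cfg.resolved_wideband_sd
        if cfg.resolved_wideband_sd > 0
        else np.zeros(n)
    )
    effort = env + tremor + wide
    if cfg.spike_rate > 0 and cfg.resolved_spike_amplitude > 0:
        n_spikes = rng.poisson(cfg.spike_rate * n / fs)
        if n_spikes:
            idx = rng.integers(0, n, size=n_spikes)
            amp = cfg.resolved_spike_amplitude * rng.choice([-1.0, 1.0], size=n_spikes)
            effort[idx] += amp

    other_axis = "fx" if axis == "fy" else "fy"
    channels = {
        axis: effort_sign * effort,
        other_axis: rng.standard_normal(n) * cfg.resolved_wideband_sd,
        "fz": body_weight_n
        + rng.standard_normal(n) * max(cfg.resolved_wideband_sd, 1e-12) * 2.0,
    }
    return ForceTrace(fs=fs, fx=channels["fx"], fy=channels["fy"], fz=channels["fz"])


@dataclass(frozen=True)
class CohortGenConfig:
    """Cohort structure: strata sizes, cell means, dispersion, noise model.

    ``interaction_additive`` keeps the cell means the sum of a sex effect
    and an age effect (the published interaction is near-null);
    ``cell_mean_override`` lets a study impose arbitrary cell means
    instead.  ``trace_noise`` scales the trace-level noise model (0
    disables tremor/noise/spikes for exact round-trips).
    """

    seed: int = 0
    n_per_stratum: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_STRATUM)
    )
    direction_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIRECTION_SD)
    )
    female_baseline: Mapping[str, float] = field(
        default_factory=lambda: dict(_FEMALE_G25_MEAN)
    )
    male_advantage: Mapping[str, float] = field(
        default_factory=lambda: dict(_MALE_ADVANTAGE)
    )
    age_offset: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in _AGE_OFFSET.items()}
    )
    interaction_additive: bool = True
    cell_mean_override: Mapping[tuple[str, str, str], float] | None = None
    trace_noise: float = 1.0

    def __post_init__(self) -> None:
        for stratum, n in self.n_per_stratum.items():
            if n < 2:
                raise CohortError(f"stratum {stratum} needs n >= 2, got {n}")
        for d, sd in self.direction_sd.items():
            if sd < 0:
                raise CohortError(f"direction {d}: sd must be >= 0")
        if self.trace_noise < 0:
            raise CohortError("trace_noise must be >= 0")

    def cell_mean(self, sex: str, age_group: str, direction: str) -> float:
        if not self.interaction_additive and self.cell_mean_override is None:
            raise CohortError(
                "interaction_additive=False requires explicit cell_mean_override"
            )
        if self.cell_mean_override is not None:
            return float(self.cell_mean_override[(sex, age_group, direction)])
        mean = self.female_baseline[direction] + self.age_offset[age_group][direction]
        if sex == "male":
            mean += self.male_advantage[direction]
        if mean <= 0:
            raise CohortError(f"cell mean for {(sex, age_group, direction)} is not positive")
        return mean


def _trunc_mean(loc: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - loc) / sd, (hi - loc) / sd
    z = special.ndtr(b) - special.ndtr(a)
    if z < 1e-12:  # all mass piled against one bound
        return lo if loc <= lo else hi
    phi = lambda t: np.exp(-0.5 * t * t) / np.sqrt(2 * np.pi)
    return loc + sd * (phi(a) - phi(b)) / z


@lru_cache(maxsize=256)
def _matched_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose [lo, hi]-truncated normal has the given mean.

    Plain truncation of Normal(mean, sd) shifts the realised mean (for an
    asymmetric range by as much as ~1 kg for the published mass rows), so
    the generator solves for the untruncated location that restores the
    published mean after truncation.
    """
    if not lo < mean < hi:
        raise CohortError(f"target mean {mean} must lie inside the range ({lo}, {hi})")
    return float(brentq(lambda loc: _trunc_mean(loc, sd, lo, hi) - mean,
                        mean - 10 * sd, mean + 10 * sd))


def _truncated_normal(mean: float, sd: float, lo: float, hi: float,
                      rng: np.random.Generator, size: int | None = None,
                      match_mean: bool = True):
    """Inverse-CDF truncated-normal draw; optionally moment-matched to ``mean``."""
    if np.isinf(hi) and not match_mean:
        loc = mean
    else:
        loc = _matched_loc(mean, sd, lo, min(hi, mean + 50 * sd)) if match_mean else mean
    a, b = special.ndtr((lo - loc) / sd), special.ndtr((hi - loc) / sd)
    u = rng.uniform(a, b, size=size)
    return loc + sd * special.ndtri(u)


def generate_participant(
    stratum: tuple[str, str],
    cfg: CohortGenConfig,
    rng: np.random.Generator,
    pid: str = "P000",
) -> Participant:
    """Draw one participant's anthropometrics from the stratum's published
    distribution, truncated to the published ranges; age uniform in the
    stratum decade; BMI recomputed from the drawn height and mass."""
    sex, group = stratum
    if stratum not in ANTHROPOMETRICS:
        raise CohortError(f"unknown stratum {stratum}")
    anthro = ANTHROPOMETRICS[stratum]
    h_mean, h_sd, h_lo, h_hi = anthro["height"]
    m_mean, m_sd, m_lo, m_hi = anthro["mass"]
    height = float(_truncated_normal(h_mean, h_sd, h_lo, h_hi, rng))
    mass = float(_truncated_normal(m_mean, m_sd, m_lo, m_hi, rng))
    lo, hi = AGE_GROUP_RANGES[group]
    age = float(rng.uniform(lo, hi))
    return Participant(id=pid, sex=sex, age=age, height=height, mass=mass)


def _draw_relative(cfg: CohortGenConfig, stratum: tuple[str, str],
                   rng: np.random.Generator) -> dict[str, float]:
    sex, group = stratum
    out = {}
    for d in DIRECTION_CODES:
        mean = cfg.cell_mean(sex, group, d)
        sd = cfg.direction_sd[d]
        if sd == 0.0:
            out[d] = mean
        else:
            out[d] = float(_truncated_normal(mean, sd, 0.0, np.inf, rng))
    return out


def generate_cohort(
    cfg: CohortGenConfig,
    with_traces: bool = False,
    preprocess_cfg: PreprocessConfig | None = None,
    fs: float = 1400.0,
    trace_cfg: TraceGenConfig | None = None,
) -> list[AssessmentResult]:
    """Generate a full cohort of assessment results.

    With ``with_traces=False`` the drawn relative strengths are reported
    directly (best MVC = relative x mass): fast, exact, suitable for the
    statistics layer.  With ``with_traces=True`` every participant gets
    3 trials x 6 directions of synthetic traces which are pushed through
    the filtering/windowing/best-of-three pipeline, so the whole chain is
    in the loop.  ``trace_cfg`` serves as a template for trace timing and
    noise (its seed and target are overridden per trial).
    """
    from .protocol import DIRECTIONS  # local to avoid cycle at import time

    # population draws and trace-noise seeds use separate streams so the
    # drawn cohort is identical whether or not traces are materialised
    pop_ss, trace_ss = np.random.SeedSequence(cfg.seed).spawn(2)
    rng = np.random.default_rng(pop_ss)
    trace_rng = np.random.default_rng(trace_ss)
    preprocess_cfg = preprocess_cfg or PreprocessConfig()
    template = trace_cfg or TraceGenConfig(seed=0, target_mvc=1.0)
    results: list[AssessmentResult] = []
    counter = 0
    for sex in SEXES:
        for group in AGE_GROUPS:
            stratum = (sex, group)
            if stratum not in cfg.n_per_stratum:
                continue
            for _ in range(cfg.n_per_stratum[stratum]):
                counter += 1
                pid = f"P{counter:03d}"
                participant = generate_participant(stratum, cfg, rng, pid=pid)
                relative = _draw_relative(cfg, stratum, rng)
                if not with_traces:
                    res = AssessmentResult(
                        participant=participant,
                        best_mvc={d: relative[d] * participant.mass for d in DIRECTION_CODES},
                        relative=dict(relative),
                    )
                else:
                    trials = {}
                    weight = participant.mass * STANDARD_GRAVITY
                    for d in DIRECTION_CODES:
                        direction = DIRECTIONS[d]
                        target = relative[d] * participant.mass
                        noise = cfg.trace_noise
                        traces = []
                        for _trial in range(3):
                            tcfg = replace(
                                template,
                                seed=int(trace_rng.integers(0, 2**31 - 1)),
                                target_mvc=target,
                                tremor_sd=(
                                    None if (template.tremor_sd is None and noise == 1.0)
                                    else noise * (template.tremor_sd
                                                  if template.tremor_sd is not None
                                                  else 0.02 * target)
                                ),
                                wideband_noise_sd=(
                                    None if (template.wideband_noise_sd is None and noise == 1.0)
                                    else noise * (template.wideband_noise_sd
                                                  if template.wideband_noise_sd is not None
                                                  else 0.01 * target)
                                ),
                                spike_rate=template.spike_rate if noise > 0 else 0.0,
                            )
                            traces.append(
                                generate_trace(
                                    tcfg,
                                    fs=fs,
                                    axis=direction.axis,
                                    effort_sign=direction.effort_sign,
                                    body_weight_n=weight,
                                )
                            )
                        trials[d] = traces
                    res = run_assessment(participant, trials, preprocess_cfg)
                results.append(res)
    return results
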