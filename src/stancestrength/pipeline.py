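"""End-to-end pipeline driver and on-disk session formats.

A *session* is a directory holding everything one simulated (or
recorded) measurement campaign produced:

``participants.csv``
    one row per participant (id, sex, age, age group, height, mass, BMI);
``traces/<pid>_<direction>_<trial>.csv``
    per-trial traces, either the force dialect ``time_s,fx_n,fy_n,fz_n``
    or the raw conditioned-voltage dialect ``time_s,fx_mv,fy_mv,fz_mv``
    (exercising the calibration path);
``manifest.json``
    seed, config hash, dialect and record counts, so re-runs are
    auditable and byte-reproducible.

The three drivers compose the library: :func:`simulate_session` writes a
synthetic session, :func:`extract_session` runs calibration ->
filtering -> windowing -> best-of-three -> normalisation and emits the
assessment table, and :func:`run_benchmark` produces the normative and
inferential tables from an assessment table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import signal_chain as sc
from .cohort import (
    CohortGenConfig,
    TraceGenConfig,
    _draw_relative,
    generate_participant,
    generate_trace,
)
from .preprocess import (
    ForceTrace,
    PreprocessConfig,
    PreprocessError,
    best_of_trials,
    read_force_csv,
    write_force_csv,
)
from .protocol import (
    DIRECTION_CODES,
    DIRECTIONS,
    STANDARD_GRAVITY,
    Participant,
    ProtocolError,
    extract_trial,
)
from .stats import ALPHA, games_howell, independent_t, one_way_anova, two_way_anova

logger = logging.getLogger("stancestrength")

__all__ = [
    "PipelineConfig",
    "simulate_session",
    "extract_session",
    "run_benchmark",
    "cohort_to_dataframe",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a reproducible run needs, in one validated block."""

    seed: int = 0
    chain: sc.SensorChainSpec = field(default_factory=sc.SensorChainSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cohort: CohortGenConfig | None = None
    trace: TraceGenConfig | None = None
    dialect: str = "force"  # "force" | "voltage"
    t_variant: str = "student"

    def __post_init__(self) -> None:
        if self.dialect not in ("force", "voltage"):
            raise ValueError(f"dialect must be 'force' or 'voltage', got {self.dialect!r}")
        if self.cohort is None:
            object.__setattr__(self, "cohort", CohortGenConfig(seed=self.seed))

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "chain": asdict(self.chain),
            "preprocess": asdict(self.preprocess),
            "cohort": {
                k: (dict(v) if isinstance(v, dict) else
                    {kk: dict(vv) for kk, vv in v.items()} if k == "age_offset" else v)
                for k, v in asdict(self.cohort).items()
                if k != "n_per_stratum"
            },
            "n_per_stratum": {f"{s}/{g}": n for (s, g), n in self.cohort.n_per_stratum.items()},
            "dialect": self.dialect,
            "t_variant": self.t_variant,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_voltage_csv(trace: ForceTrace, cal: sc.CalibrationSpec, path: Path,
                       quantized: bool, adc: sc.AdcSpec) -> None:
    cols = {"time_s": trace.time}
    for axis in ("fx", "fy", "fz"):
        mv = np.clip(trace.channel(axis) / cal.gain_factor + cal.zero_offset, 0.0, cal.supply)
        if quantized:
            lsb = sc.adc_lsb(adc)
            mv = np.round(mv / lsb) * lsb
        cols[f"{axis}_mv"] = mv
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9f")


def _read_voltage_csv(path: Path, cal: sc.CalibrationSpec) -> ForceTrace:
    df = pd.read_csv(path)
    required = {"time_s", "fx_mv", "fy_mv", "fz_mv"}
    if not required.issubset(df.columns):
        raise PreprocessError(f"{path}: expected columns {sorted(required)}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(t) < 2 or np.any(np.abs(dt - dt[0]) > 1e-6):
        raise PreprocessError(f"{path}: sampling is not uniform")
    return ForceTrace(
        fs=1.0 / dt[0],
        fx=sc.voltage_to_force(df["fx_mv"].to_numpy(), cal),
        fy=sc.voltage_to_force(df["fy_mv"].to_numpy(), cal),
        fz=sc.voltage_to_force(df["fz_mv"].to_numpy(), cal),
    )


def simulate_session(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Write a synthetic measurement session to ``out_dir``.

    Deterministic per seed: running twice with the same config yields
    byte-identical files.
    """
    out = Path(out_dir)
    traces_dir = out / "traces"
    traces_dir.mkdir(parents=True, exist_ok=True)
    cohort_cfg = config.cohort
    template = config.trace or TraceGenConfig(seed=0, target_mvc=1.0)
    # same stream split as generate_cohort: the session's drawn cohort is
    # identical to the in-memory one for the same seed
    pop_ss, trace_ss = np.random.SeedSequence(cohort_cfg.seed).spawn(2)
    rng = np.random.default_rng(pop_ss)
    trace_rng = np.random.default_rng(trace_ss)
    fs = config.chain.fs
    cal = config.chain.calibration

    from .protocol import SEXES, AGE_GROUPS  # ordering source of truth

    participants = []
    n_traces = 0
    counter = 0
    for sex in SEXES:
        for group in AGE_GROUPS:
            stratum = (sex, group)
            if stratum not in cohort_cfg.n_per_stratum:
                continue
            for _ in range(cohort_cfg.n_per_stratum[stratum]):
                counter += 1
                pid = f"P{counter:03d}"
                part = generate_participant(stratum, cohort_cfg, rng, pid=pid)
                participants.append(part)
                relative = _draw_relative(cohort_cfg, stratum, rng)
                weight = part.mass * STANDARD_GRAVITY
                for d in DIRECTION_CODES:
                    direction = DIRECTIONS[d]
                    target = relative[d] * part.mass
                    for trial_idx in range(1, 4):
                        from dataclasses import replace

                        tcfg = replace(
                            template,
                            seed=int(trace_rng.integers(0, 2**31 - 1)),
                            target_mvc=target,
                        )
                        trace = generate_trace(
                            tcfg, fs=fs, axis=direction.axis,
                            effort_sign=direction.effort_sign, body_weight_n=weight,
                        )
                        path = traces_dir / f"{pid}_{d}_t{trial_idx}.csv"
                        if config.dialect == "voltage":
                            _write_voltage_csv(trace, cal, path, quantized=True,
                                               adc=config.chain.adc)
                        else:
                            write_force_csv(trace, path)
                        n_traces += 1

    pd.DataFrame(
        [
            {
                "id": p.id, "sex": p.sex, "age": round(p.age, 1),
                "age_group": p.age_group, "height_cm": round(p.height, 1),
                "mass_kg": round(p.mass, 2), "bmi": p.bmi,
            }
            for p in participants
        ]
    ).to_csv(out / "participants.csv", index=False)

    manifest = {
        "seed": cohort_cfg.seed,
        "config_hash": config.config_hash(),
        "dialect": config.dialect,
        "fs_hz": fs,
        "n_participants": len(participants),
        "n_traces": n_traces,
        "zero_offset_mv": cal.zero_offset,
        "gain_factor_n_per_mv": cal.gain_factor,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("simulated session: %d participants, %d traces -> %s",
                len(participants), n_traces, out)
    return out


def extract_session(
    session_dir: str | Path,
    preprocess_cfg: PreprocessConfig | None = None,
    chain: sc.SensorChainSpec | None = None,
    write_csv: bool = True,
) -> pd.DataFrame:
    """Run the extraction pipeline over a session directory.

    Per-trial failures (malformed or too-short traces) are logged and the
    direction falls back to its remaining trials; a direction with no
    usable trial raises.  Returns one row per participant x direction
    with ``best_n`` and ``relative_n_per_kg``; also writes
    ``assessment.csv`` next to the traces unless told otherwise.
    """
    session = Path(session_dir)
    preprocess_cfg = preprocess_cfg or PreprocessConfig()
    chain = chain or sc.SensorChainSpec()
    manifest = json.loads((session / "manifest.json").read_text())
    dialect = manifest.get("dialect", "force")
    cal = sc.CalibrationSpec(
        zero_offset=manifest.get("zero_offset_mv", chain.calibration.zero_offset),
        gain_factor=manifest.get("gain_factor_n_per_mv", chain.calibration.gain_factor),
        supply=chain.calibration.supply,
    )
    parts = pd.read_csv(session / "participants.csv")
    rows = []
    for rec in parts.itertuples():
        participant = Participant(
            id=rec.id, sex=rec.sex, age=rec.age, height=rec.height_cm, mass=rec.mass_kg
        )
        for d in DIRECTION_CODES:
            mvcs = []
            for trial_idx in range(1, 4):
                path = session / "traces" / f"{rec.id}_{d}_t{trial_idx}.csv"
                if not path.exists():
                    logger.warning("%s: missing trace file", path)
                    continue
                try:
                    trace = (
                        _read_voltage_csv(path, cal) if dialect == "voltage"
                        else read_force_csv(path)
                    )
                    trial = extract_trial(trace, d, preprocess_cfg)
                except (PreprocessError, ValueError) as exc:
                    logger.warning("%s: trial skipped (%s)", path, exc)
                    continue
                logger.info("%s: MVC %.1f N at window start %.2f s",
                            path.name, trial.mvc, trial.result.window_start)
                mvcs.append(trial.mvc)
            if not mvcs:
                raise ProtocolError(
                    f"participant {rec.id}, direction {d}: no usable trial"
                )
            best = best_of_trials(mvcs)
            rows.append(
                {
                    "id": rec.id, "sex": rec.sex, "age_group": rec.age_group,
                    "mass_kg": rec.mass_kg, "direction": d,
                    "n_trials_used": len(mvcs), "best_n": best,
                    "relative_n_per_kg": best / rec.mass_kg,
                }
            )
    df = pd.DataFrame(rows)
    if write_csv:
        df.to_csv(session / "assessment.csv", index=False)
    logger.info("extracted %d direction scores for %d participants",
                len(df), parts.shape[0])
    return df


def cohort_to_dataframe(cohort) -> pd.DataFrame:
    """Flatten a list of assessment results into the long assessment table."""
    rows = []
    for res in cohort:
        p = res.participant
        for d in DIRECTION_CODES:
            rows.append(
                {
                    "id": p.id, "sex": p.sex, "age_group": p.age_group,
                    "mass_kg": p.mass, "direction": d,
                    "best_n": res.best_mvc[d],
                    "relative_n_per_kg": res.relative[d],
                }
            )
    return pd.DataFrame(rows)


def run_benchmark(
    assessment: pd.DataFrame,
    t_variant: str = "student",
    alpha: float = ALPHA,
) -> dict:
    """Produce the benchmarking tables from an assessment table.

    Returns a dict with:

    * ``normative`` — stratum x direction n/mean/SD table (DataFrame);
    * ``sex_ttests`` — per direction (overall and per age group) the
      male-vs-female t-test with the percent difference;
    * ``age_anova`` — per sex x direction the one-way ANOVA across age
      groups plus Games-Howell pairwise results;
    * ``two_way`` — per direction the sex x age-group ANOVA table with
      partial eta squared.

    Analyses whose groups are missing are skipped with a warning rather
    than failing the whole benchmark.
    """
    from .protocol import AGE_GROUPS, SEXES

    req = {"sex", "age_group", "direction", "relative_n_per_kg"}
    if not req.issubset(assessment.columns):
        raise ValueError(f"assessment table needs columns {sorted(req)}")

    norm_rows = []
    for (sex, grp, d), sub in assessment.groupby(["sex", "age_group", "direction"]):
        vals = sub["relative_n_per_kg"]
        if len(vals) < 2:
            continue
        norm_rows.append(
            {"sex": sex, "age_group": grp, "direction": d, "n": len(vals),
             "mean_n_per_kg": vals.mean(), "sd_n_per_kg": vals.std(ddof=1)}
        )
    normative = pd.DataFrame(norm_rows)

    def vals(sex=None, grp=None, d=None):
        sub = assessment
        if sex is not None:
            sub = sub[sub["sex"] == sex]
        if grp is not None:
            sub = sub[sub["age_group"] == grp]
        if d is not None:
            sub = sub[sub["direction"] == d]
        return sub["relative_n_per_kg"].to_numpy()

    sex_ttests = []
    for scope in [None, *AGE_GROUPS]:
        for d in DIRECTION_CODES:
            men, women = vals("male", scope, d), vals("female", scope, d)
            if len(men) < 2 or len(women) < 2:
                logger.warning("skipping t-test (%s, %s): missing group", scope, d)
                continue
            cmp_ = independent_t(men, women, variant=t_variant, labels=("male", "female"))
            sex_ttests.append(
                {"age_group": scope or "all", "direction": d,
                 "mean_male": cmp_.group1.mean, "mean_female": cmp_.group2.mean,
                 "pct_diff": cmp_.pct_diff, "t": cmp_.t, "df": cmp_.df, "p": cmp_.p,
                 "significant": cmp_.p < alpha}
            )

    age_anova = []
    for sex in SEXES:
        for d in DIRECTION_CODES:
            groups = [vals(sex, g, d) for g in AGE_GROUPS]
            if any(len(g) < 2 for g in groups):
                logger.warning("skipping one-way ANOVA (%s, %s): missing group", sex, d)
                continue
            rows = one_way_anova(groups, labels=list(AGE_GROUPS))
            gh = games_howell(groups, labels=list(AGE_GROUPS))
            age_anova.append(
                {"sex": sex, "direction": d,
                 "F": rows[0].f, "df1": rows[0].df, "df2": rows[1].df, "p": rows[0].p,
                 "games_howell": [
                     {"pair": (g.group_i, g.group_j), "mean_diff": g.mean_diff,
                      "p_adj": g.p_adj} for g in gh
                 ]}
            )

    two_way = {}
    for d in DIRECTION_CODES:
        data = {}
        ok = True
        for sex in SEXES:
            for grp in AGE_GROUPS:
                cell = vals(sex, grp, d)
                if len(cell) == 0:
                    ok = False
                data[(sex, grp)] = cell
        if not ok:
            logger.warning("skipping two-way ANOVA (%s): empty cell", d)
            continue
        rows = two_way_anova(data)
        two_way[d] = pd.DataFrame(
            [{"source": r.source, "ss": r.ss, "df": r.df, "ms": r.ms,
              "F": r.f, "p": r.p, "eta_p2": r.eta_p2} for r in rows]
        )

    return {
        "normative": normative,
        "sex_ttests": pd.DataFrame(sex_ttests),
        "age_anova": age_anova,
        "two_way": two_way,
    }
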