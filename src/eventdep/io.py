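"""Long-format trial CSV, run configuration, and the end-to-end pipeline.

One CSV row per encoding or retrieval trial:

participant_id, age_group, condition, phase, event_id, cue_role,
target_role, set_index, block_index, within_block_position, correct,
attended

``correct`` is 1/0/NA (NA = missing response, retrieval only; encoding rows
are always NA); ``attended`` is 1/0/NA (encoding only). Missing values are
written as ``NA``; files are UTF-8, comma-delimited, with a mandatory
header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import CONDITIONS, ROLES
from .screening import ScreeningConfig
from .simulate import (
    BindingParams,
    CohortSpec,
    DesignSpec,
    GroupSpec,
    default_cohort_spec,
    simulate_cohort,
)

logger = logging.getLogger("eventdep")

COLUMNS = [
    "participant_id",
    "age_group",
    "condition",
    "phase",
    "event_id",
    "cue_role",
    "target_role",
    "set_index",
    "block_index",
    "within_block_position",
    "correct",
    "attended",
]

_INT_COLUMNS = ["event_id", "block_index", "within_block_position"]
_RETRIEVAL_KEY = ["participant_id", "condition", "event_id", "cue_role", "target_role", "set_index"]


class TrialFormatError(ValueError):
    pass


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a long-format trial table, NA for missing, stable column order."""
    out = trials.reindex(columns=COLUMNS)
    out.to_csv(path, index=False, na_rep="NA", float_format="%g")


def validate_trials(trials: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    """Validate a trial table against the schema; returns a normalised copy.

    Raises :class:`TrialFormatError` naming the offending line (1-based,
    header = line 1) on malformed rows, and on duplicate retrieval keys.
    """
    missing = [c for c in COLUMNS if c not in trials.columns]
    if missing:
        raise TrialFormatError(f"{source}: missing columns {missing}")
    t = trials.copy()

    def bad(mask: pd.Series, why: str) -> None:
        if mask.any():
            line = int(np.flatnonzero(mask.to_numpy())[0]) + 2  # header + 1-based
            raise TrialFormatError(f"{source}: line {line}: {why}")

    bad(~t["phase"].isin(["encoding", "retrieval"]), "phase must be encoding|retrieval")
    bad(~t["condition"].isin(CONDITIONS), f"condition must be one of {CONDITIONS}")
    for col in _INT_COLUMNS:
        numeric = pd.to_numeric(t[col], errors="coerce")
        bad(numeric.isna(), f"{col} must be an integer")
        t[col] = numeric.astype(int)
    t["correct"] = pd.to_numeric(t["correct"], errors="coerce")
    t["attended"] = pd.to_numeric(t["attended"], errors="coerce")
    bad(~t["correct"].isin([0.0, 1.0]) & t["correct"].notna(), "correct must be 1, 0 or NA")

    ret = t["phase"] == "retrieval"
    bad(ret & (t["cue_role"] == t["target_role"]), "retrieval cue_role equals target_role")
    bad(ret & ~t["cue_role"].isin(ROLES), f"cue_role must be one of {ROLES}")
    bad(ret & ~t["target_role"].isin(ROLES), f"target_role must be one of {ROLES}")
    bad(~ret & t["correct"].notna(), "encoding rows must have correct = NA")

    dup = t.loc[ret].duplicated(subset=_RETRIEVAL_KEY, keep=False)
    if dup.any():
        key = t.loc[ret].loc[dup, _RETRIEVAL_KEY].iloc[0].tolist()
        raise TrialFormatError(f"{source}: duplicate retrieval key {key}")
    return t


def read_trials(path) -> pd.DataFrame:
    """Read and validate a long-format trial CSV."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, na_values=["NA"], keep_default_na=True, dtype={"participant_id": str})
    except pd.errors.ParserError as err:
        raise TrialFormatError(f"{path}: {err}") from err
    if list(raw.columns[:1]) and "participant_id" not in raw.columns:
        raise TrialFormatError(f"{path}: missing header row")
    return validate_trials(raw, source=str(path))


# ---------------------------------------------------------------------------
# Run configuration


_KNOWN_SECTIONS = {"design", "simulation", "screening", "analysis", "power", "seed", "output_dir", "verbosity"}


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``RunConfig.from_yaml``)."""

    seed: int = 0
    output_dir: str = "eventdep_out"
    verbosity: str = "INFO"
    design: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    screening: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    power: dict | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _KNOWN_SECTIONS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in data.items()})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        data = {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "verbosity": self.verbosity,
            "design": self.design,
            "simulation": self.simulation,
            "screening": self.screening,
            "analysis": self.analysis,
        }
        if self.power is not None:
            data["power"] = self.power
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def design_spec(self) -> DesignSpec:
        return DesignSpec(**self.design)

    def screening_config(self) -> ScreeningConfig:
        return ScreeningConfig(**self.screening)

    def cohort_spec(self) -> CohortSpec:
        """Build the simulation cohort; empty section = study-shaped default."""
        sim = dict(self.simulation)
        seed = sim.pop("base_seed", self.seed)
        if not sim:
            return default_cohort_spec(base_seed=seed)
        groups = {}
        for name, g in sim.pop("groups").items():
            params = {
                cond: BindingParams(**p) for cond, p in g.pop("params").items()
            }
            groups[name] = GroupSpec(params=params, **g)
        return CohortSpec(groups=groups, design=self.design_spec(), base_seed=seed, **sim)


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(config: RunConfig, trials: pd.DataFrame | None = None) -> dict:
    """simulate -> screen -> score -> analyze (-> power), writing results.

    If ``trials`` is None the cohort in the config's simulation section is
    generated first. Returns the bundle of in-memory results; CSVs land in
    ``config.output_dir``.
    """
    from .model import RetrievalDependency  # local import to avoid a cycle
    from .power import PowerSpec, power_curve

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))

    if trials is None:
        spec = config.cohort_spec()
        logger.info("simulating cohort (base_seed=%d)", spec.base_seed)
        trials = simulate_cohort(spec)
        write_trials(trials, outdir / "trials.csv")
    trials = validate_trials(trials)

    model = RetrievalDependency(trials, screening=config.screening_config())
    results = model.fit(
        n_perm=int(_cfg_get(config.analysis, "n_perm", 10_000)),
        seed=config.seed,
    )
    results.participant_scores.to_csv(outdir / "dependency_scores.csv", index=False)
    results.group_summary.to_csv(outdir / "group_summary.csv", index=False)
    results.tests.to_csv(outdir / "permutation_tests.csv", index=False)
    results.screening_report.to_frame().to_csv(outdir / "screening_report.csv", index=False)
    logger.info(
        "screened: %d participants excluded, %d timeouts resolved",
        len(results.screening_report.excluded_participants),
        results.screening_report.n_timeouts_resolved,
    )
    with open(outdir / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write(results.summary())

    bundle = {"trials": trials, "results": results}
    if config.power:
        pw = dict(config.power)
        pw.setdefault("seed", config.seed)
        pw["params"] = BindingParams(**pw["params"])
        pw["sample_sizes"] = tuple(pw["sample_sizes"])
        spec = PowerSpec(**pw)
        power = power_curve(spec) if len(spec.sample_sizes) > 1 else None
        if power is None:
            from .power import estimate_power

            power = estimate_power(spec)
        power.table.to_csv(outdir / "power.csv", index=False)
        bundle["power"] = power
    return bundle


def _cfg_get(section: dict, key: str, default):
    return section.get(key, default) if section else default
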