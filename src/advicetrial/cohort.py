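"""Synthetic trial data generator.

No raw data from the advice-taking trial being emulated are publicly
deposited, so every downstream stage (weight-of-advice scoring, multilevel
models) is exercised on synthetic cohorts drawn from an explicit generative
model with known ground truth:

* participant covariates are drawn independently from configurable marginal
  proportions (defaults match the published cohort: 49% doctors, 41% nurses,
  10% other professions, 65% with 15+ years' experience, ...);
* arms come from the blocked randomisation list in :mod:`advicetrial.design`;
* the initial estimate for a vignette is a truncated-normal draw around a
  vignette-specific anchor, rounded to an integer percent; with a small
  probability it is set exactly equal to the advice to exercise the
  tie-exclusion rule of the weight-of-advice statistic;
* the final estimate follows the linear advice-combination model
  ``f = i + w (a - i) + eps`` with ``w`` the true advice weight, so that
  ``w`` is exactly the estimand of the weight-of-advice statistic;
* a fraction of participants drops out before completing all five
  vignettes, feeding the per-protocol filter.

All randomness derives from a single master seed through named substreams,
so each component is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    ARM_ALGORITHM,
    ARM_CLINICIAN,
    VIGNETTE_IDS,
    VIGNETTE_STRENGTHS,
    BlockSpec,
    ConfigurationError,
    generate_allocation,
)

#: Marginal covariate proportions of the emulated cohort (total column of the
#: published demographics table, expressed as fractions).
DEFAULT_PROPORTIONS: dict[str, dict[str, float]] = {
    "profession": {"doctor": 0.49, "nurse": 0.41, "other": 0.10},
    "total_experience": {"<=14": 0.35, "15+": 0.65},
    "palliative_experience": {"<=5": 0.30, "6-14": 0.36, "15+": 0.34},
    "age_band": {"21-30": 0.07, "31-40": 0.24, "41-50": 0.38, "51+": 0.31},
    "gender": {"male": 0.08, "female": 0.92},
    "setting": {
        "hospice": 0.55,
        "hospital": 0.10,
        "community": 0.10,
        "other": 0.01,
        "multiple": 0.24,
    },
}

#: Mean initial estimate per vignette.  Anchors sit well below the advice
#: values so that, under the literal weight-of-advice formula with an
#: absolute-value denominator, movement toward advice yields positive raw
#: scores for essentially all records (see docs/methods.md).
DEFAULT_ANCHORS: dict[str, float] = {
    "v1": 68.0,  # advice 90
    "v2": 62.0,  # advice 90
    "v3": 52.0,  # advice 75
    "v4": 47.0,  # advice 75
    "v5": 28.0,  # advice 50
}

#: True mean advice weight per arm: algorithm advice is weighted more.
DEFAULT_ARM_WEIGHTS: dict[str, float] = {ARM_ALGORITHM: 0.44, ARM_CLINICIAN: 0.31}

DATASET_COLUMNS = [
    "participant_id",
    "arm",
    "profession",
    "total_experience",
    "palliative_experience",
    "age_band",
    "gender",
    "setting",
    "vignette_id",
    "position",
    "advice",
    "initial",
    "final",
    "completed",
]

TrueWeight = Callable[[str, int, str, str, str], float]


@dataclass(frozen=True)
class ParticipantProfile:
    """One enrolled clinician."""

    id: str
    arm: str
    profession: str
    total_experience: str
    palliative_experience: str
    age_band: str
    gender: str
    setting: str


@dataclass(frozen=True)
class ResponseRecord:
    """One participant x vignette trial: advice a, initial i, final f."""

    participant_id: str
    vignette_id: str
    a: int
    i: int
    f: int
    completed: bool = True


@dataclass
class SimConfig:
    """Full generative specification of a synthetic trial.

    Parameters
    ----------
    n_participants : number of enrolled participants.
    covariate_proportions : marginal category probabilities per covariate.
    vignette_anchors : mean initial estimate per vignette (percent).
    initial_sd : sd of the initial estimate around its anchor (percent).
    arm_weights : true mean advice weight per arm (used when ``true_weight``
        is None).
    true_weight : optional callable ``(arm, strength, profession,
        total_experience, palliative_experience) -> weight in [0, 1]``
        overriding ``arm_weights``.
    participant_weight_sd : sd of a participant-level random shift of the
        advice weight (weight scale); gives the mixed model's random
        intercept a true variance component.
    response_sd : sd of additive noise on the final estimate (percent).
    tie_probability : probability an initial estimate is set exactly equal
        to the advice (making the weight of advice undefined).
    dropout_probability : probability a participant completes fewer than
        five vignettes.
    integer_estimates : round estimates to integer percents (the elicitation
        scale); set False for raw real-valued estimates.
    seed : master seed; all substreams derive from it.
    """

    n_participants: int = 323
    covariate_proportions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PROPORTIONS.items()}
    )
    vignette_anchors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANCHORS)
    )
    initial_sd: float = 10.0
    arm_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARM_WEIGHTS)
    )
    true_weight: TrueWeight | None = None
    participant_weight_sd: float = 0.10
    response_sd: float = 2.5
    tie_probability: float = 0.03
    dropout_probability: float = 0.124
    block_spec: BlockSpec = field(default_factory=BlockSpec)
    integer_estimates: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for cov, props in self.covariate_proportions.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"proportions for {cov!r} sum to {total}, not 1"
                )
            if any(p < 0 for p in props.values()):
                raise ConfigurationError(f"negative proportion in {cov!r}")
        for vid, anchor in self.vignette_anchors.items():
            if not 0 <= anchor <= 100:
                raise ConfigurationError(f"anchor for {vid!r} outside [0, 100]")
        for name in ("tie_probability", "dropout_probability"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")

    # -- provenance -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["block_spec"] = {"allowed_sizes": list(self.block_spec.allowed_sizes)}
        d["true_weight"] = (
            None if self.true_weight is None else getattr(
                self.true_weight, "__qualname__", repr(self.true_weight)
            )
        )
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def weight_for(
        self,
        arm: str,
        strength: int,
        profession: str,
        total_experience: str,
        palliative_experience: str,
    ) -> float:
        if self.true_weight is not None:
            w = self.true_weight(
                arm, strength, profession, total_experience, palliative_experience
            )
        else:
            w = self.arm_weights[arm]
        if not 0 <= w <= 1:
            raise ValueError(f"true weight {w} outside [0, 1]")
        return w


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    names = ("allocation", "covariates", "schedule", "initial", "weights",
             "final", "dropout")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def sample_cohort(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[ParticipantProfile]:
    """Draw participant profiles with arms from the blocked allocation list."""
    rngs = None
    if rng is None:
        rngs = _substreams(config.seed)
        rng = rngs["covariates"]
        alloc_rng = rngs["allocation"]
    else:
        alloc_rng = rng
    n = config.n_participants
    alloc = generate_allocation(n, config.block_spec, seed=alloc_rng)
    draws = {}
    for cov, props in config.covariate_proportions.items():
        cats = list(props)
        p = np.array([props[c] for c in cats], dtype=float)
        p = p / p.sum()
        draws[cov] = rng.choice(cats, size=n, p=p)
    return [
        ParticipantProfile(
            id=f"p{k + 1:04d}",
            arm=alloc.entries[k],
            profession=draws["profession"][k],
            total_experience=draws["total_experience"][k],
            palliative_experience=draws["palliative_experience"][k],
            age_band=draws["age_band"][k],
            gender=draws["gender"][k],
            setting=draws["setting"][k],
        )
        for k in range(n)
    ]


def _draw_initials(
    anchors: np.ndarray,
    advice: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Truncated-normal initial estimates on [0, 100] with tie injection."""
    sd = config.initial_sd
    if sd == 0:
        i = anchors.astype(float).copy()
    else:
        a_std = (0.0 - anchors) / sd
        b_std = (100.0 - anchors) / sd
        i = stats.truncnorm.rvs(
            a_std, b_std, loc=anchors, scale=sd, size=anchors.size, random_state=rng
        )
    # tie injection must consume the uniform stream regardless of sd
    ties = rng.random(anchors.size) < config.tie_probability
    if config.integer_estimates:
        i = np.rint(i)
    i = np.clip(i, 0, 100)
    i[ties] = advice[ties]
    return i


def generate_initial(
    participant: ParticipantProfile,
    vignette_id: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> int:
    """Initial estimate for one participant x vignette (integer percent)."""
    if vignette_id not in config.vignette_anchors:
        raise ValueError(f"no anchor configured for vignette {vignette_id!r}")
    anchor = np.array([config.vignette_anchors[vignette_id]])
    advice = np.array([VIGNETTE_STRENGTHS[vignette_id]], dtype=float)
    i = _draw_initials(anchor, advice, config, rng)[0]
    return int(i) if config.integer_estimates else float(i)


def generate_final(
    i: float,
    a: float,
    w: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> int:
    """Final estimate under the linear advice-combination model.

    ``f = i + w (a - i) + eps`` with ``eps ~ N(0, response_sd)``, truncated
    to [0, 100] and rounded to the elicitation grid.
    """
    if not 0 <= w <= 1:
        raise ValueError(f"advice weight {w} outside [0, 1]")
    eps = rng.normal(0.0, config.response_sd) if config.response_sd > 0 else 0.0
    f = i + w * (a - i) + eps
    f = min(max(f, 0.0), 100.0)
    return int(np.rint(f)) if config.integer_estimates else float(f)


def apply_dropout(
    records: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Mark a random subset of each dropout participant's records incomplete.

    Each participant independently drops out with ``dropout_probability``;
    a dropout completes a uniformly chosen strict subset (0-4) of their five
    vignettes.
    """
    out = records.copy()
    out["completed"] = True
    pids = out["participant_id"].unique()
    drop = rng.random(pids.size) < config.dropout_probability
    for pid in pids[drop]:
        idx = out.index[out["participant_id"] == pid]
        k = int(rng.integers(0, len(idx)))  # number completed
        done = rng.choice(len(idx), size=k, replace=False)
        mask = np.ones(len(idx), dtype=bool)
        mask[done] = False
        out.loc[idx[mask], "completed"] = False
    return out


def simulate_trial(config: SimConfig) -> pd.DataFrame:
    """Generate a full synthetic trial dataset.

    Returns a long-format DataFrame with one row per participant x vignette
    (columns :data:`DATASET_COLUMNS`).  Byte-identical for identical configs.
    """
    rngs = _substreams(config.seed)
    n = config.n_participants
    alloc = generate_allocation(n, config.block_spec, seed=rngs["allocation"])
    cov_rng = rngs["covariates"]
    draws = {}
    for cov, props in config.covariate_proportions.items():
        cats = list(props)
        p = np.array([props[c] for c in cats], dtype=float)
        draws[cov] = cov_rng.choice(cats, size=n, p=p / p.sum())

    n_v = len(VIGNETTE_IDS)
    # per-participant random presentation order
    order = np.argsort(rngs["schedule"].random((n, n_v)), axis=1)
    vid_arr = np.asarray(VIGNETTE_IDS)[order].ravel()
    position = np.tile(np.arange(1, n_v + 1), n)
    pid = np.repeat([f"p{k + 1:04d}" for k in range(n)], n_v)
    arm = np.repeat(alloc.entries[:n], n_v)
    covs = {c: np.repeat(draws[c], n_v) for c in draws}

    advice = np.array([VIGNETTE_STRENGTHS[v] for v in vid_arr], dtype=float)
    anchors = np.array([config.vignette_anchors[v] for v in vid_arr], dtype=float)
    i = _draw_initials(anchors, advice, config, rngs["initial"])

    w_base = np.array(
        [
            config.weight_for(
                arm[k], int(advice[k]), covs["profession"][k],
                covs["total_experience"][k], covs["palliative_experience"][k],
            )
            for k in range(n * n_v)
        ]
    )
    u = rngs["weights"].normal(0.0, config.participant_weight_sd, size=n)
    w = np.clip(w_base + np.repeat(u, n_v), 0.0, 1.0)

    eps = rngs["final"].normal(0.0, config.response_sd, size=n * n_v)
    f = np.clip(i + w * (advice - i) + eps, 0.0, 100.0)
    if config.integer_estimates:
        f = np.rint(f)

    df = pd.DataFrame(
        {
            "participant_id": pid,
            "arm": arm,
            **covs,
            "vignette_id": vid_arr,
            "position": position,
            "advice": advice.astype(int),
            "initial": i.astype(int) if config.integer_estimates else i,
            "final": f.astype(int) if config.integer_estimates else f,
        }
    )[DATASET_COLUMNS[:-1]]
    return apply_dropout(df, config, rngs["dropout"])


def write_dataset(df: pd.DataFrame, path: str | Path, config: SimConfig | None = None) -> None:
    """Write a dataset CSV, with a JSON sidecar recording the full config."""
    path = Path(path)
    df.to_csv(path, index=False)
    if config is not None:
        config.to_json(path.with_suffix(".config.json"))


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read a dataset CSV, validating the expected schema."""
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    return df
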