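"""Trial design primitives: blocked randomisation, vignette scheduling,
advisor labelling and the power/sample-size helper.

The design being emulated is a two-arm 1:1 online randomised trial in which
each participant (a palliative-care clinician, the "judge") reviews five
patient vignettes in random order.  For every vignette the judge gives an
initial probability-of-survival estimate (0-100%), receives advice (another
estimate, nominally from a prognostic algorithm in one arm and from a
clinician of a different profession in the other), and gives a final
estimate.  Allocation uses a blocked randomisation list with mixed block
sizes so arm totals stay nearly equal throughout recruitment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

ARM_ALGORITHM = "ALGORITHM"
ARM_CLINICIAN = "CLINICIAN"
ARMS = (ARM_ALGORITHM, ARM_CLINICIAN)

PROFESSIONS = ("doctor", "nurse", "other")

#: Advisor labels shown to participants.  The algorithm arm is told the
#: advice comes from a validated prognostic tool; in the clinician arm,
#: doctors are told it comes from a nurse and everyone else from a doctor.
LABEL_ALGORITHM = "ALGORITHM_PIPS_B14"
LABEL_NURSE = "NURSE"
LABEL_DOCTOR = "DOCTOR"

#: The five vignettes and their advice strengths (percent probability of
#: two-week survival): two at 90%, two at 75%, one at 50%.
VIGNETTE_STRENGTHS: dict[str, int] = {
    "v1": 90,
    "v2": 90,
    "v3": 75,
    "v4": 75,
    "v5": 50,
}
VIGNETTE_IDS = tuple(VIGNETTE_STRENGTHS)


class ConfigurationError(ValueError):
    """Invalid design configuration (e.g. an odd block size)."""


@dataclass(frozen=True)
class BlockSpec:
    """Mixed-block randomisation specification.

    Every allowed block size must be even so that a 1:1 split is achievable
    within each block.
    """

    allowed_sizes: tuple[int, ...] = (4, 6, 8)
    ratio: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if not self.allowed_sizes:
            raise ConfigurationError("allowed_sizes must be non-empty")
        for s in self.allowed_sizes:
            if s <= 0 or s % 2 != 0:
                raise ConfigurationError(
                    f"block size {s} is not an even positive integer"
                )
        if self.ratio != (1, 1):
            raise ConfigurationError("only 1:1 allocation is supported")


@dataclass
class AllocationList:
    """An ordered arm-assignment list generated in complete balanced blocks.

    ``block_boundaries`` holds the cumulative end index of each block, so
    ``entries[block_boundaries[k-1]:block_boundaries[k]]`` is the k-th block.
    """

    entries: list[str]
    block_boundaries: list[int]

    def __len__(self) -> int:
        return len(self.entries)

    def counts(self) -> dict[str, int]:
        return {arm: self.entries.count(arm) for arm in ARMS}

    def blocks(self) -> list[list[str]]:
        out, start = [], 0
        for end in self.block_boundaries:
            out.append(self.entries[start:end])
            start = end
        return out


@dataclass
class VignetteSchedule:
    """Presentation order of the five vignettes for one participant."""

    vignette_ids: tuple[str, ...]
    advice_strengths: dict[str, int] = field(
        default_factory=lambda: dict(VIGNETTE_STRENGTHS)
    )

    def __post_init__(self) -> None:
        if sorted(self.vignette_ids) != sorted(VIGNETTE_IDS):
            raise ConfigurationError("schedule must permute the five vignettes")
        if sorted(self.advice_strengths.values()) != [50, 75, 75, 90, 90]:
            raise ConfigurationError("advice strengths must be {90,90,75,75,50}")


def generate_allocation(
    n: int, spec: BlockSpec | None = None, seed: int | np.random.Generator = 0
) -> AllocationList:
    """Generate a blocked 1:1 randomisation list of length >= ``n``.

    Block sizes are drawn uniformly (with replacement) from
    ``spec.allowed_sizes``; each block contains exactly half of each arm in
    random order.  Blocks are appended whole, so the list may exceed ``n``;
    surplus entries go unused, mirroring how a pre-generated list outlasts
    recruitment.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    spec = spec or BlockSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = np.asarray(spec.allowed_sizes)

    entries: list[str] = []
    boundaries: list[int] = []
    while len(entries) < n:
        size = int(rng.choice(sizes))
        block = [ARM_ALGORITHM] * (size // 2) + [ARM_CLINICIAN] * (size // 2)
        order = rng.permutation(size)
        entries.extend(block[k] for k in order)
        boundaries.append(len(entries))
    return AllocationList(entries=entries, block_boundaries=boundaries)


def schedule_vignettes(seed: int | np.random.Generator = 0) -> VignetteSchedule:
    """Draw a uniformly random presentation order of the five vignettes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(len(VIGNETTE_IDS))
    return VignetteSchedule(vignette_ids=tuple(VIGNETTE_IDS[k] for k in order))


def advisor_label(arm: str, profession: str) -> str:
    """Label of the purported advice source shown to a judge.

    In the algorithm arm everyone is told the advice comes from the
    prognostic tool.  In the clinician arm the advisor is presented as a
    colleague of a *different* profession: doctors are told the advice is
    from a nurse; nurses and other healthcare professionals are told it is
    from a doctor.
    """
    if profession not in PROFESSIONS:
        raise ValueError(f"unknown profession {profession!r}")
    if arm == ARM_ALGORITHM:
        return LABEL_ALGORITHM
    if arm == ARM_CLINICIAN:
        return LABEL_NURSE if profession == "doctor" else LABEL_DOCTOR
    raise ValueError(f"unknown arm {arm!r}")


def required_sample_size(
    sd: float, difference: float, alpha: float = 0.05, power: float = 0.80
) -> int:
    """Total sample size (both arms, 1:1) for a two-sample test of mean WOA.

    Uses the normal-approximation formula
    ``n_per_arm = 2 (z_{1-alpha/2} + z_power)^2 (sd / difference)^2``,
    rounded up, and returns ``2 * n_per_arm``.

    Parameters
    ----------
    sd : common standard deviation of the weight-of-advice outcome.
    difference : smallest arm difference in mean WOA to detect.
    alpha : two-sided significance level.
    power : target power.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if difference <= 0:
        raise ValueError("difference must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    n_per_arm = math.ceil(2 * (z_a + z_b) ** 2 * (sd / difference) ** 2)
    return 2 * n_per_arm


def schedule_frame(n: int, spec: BlockSpec | None = None, seed: int = 0):
    """Wide-format allocation + vignette schedule for ``n`` participants.

    Columns: participant_id, arm, vignette_position_1..5,
    advice_strength_1..5 -- the export format for a pre-generated
    randomisation and presentation plan.
    """
    import pandas as pd

    ss = np.random.SeedSequence(seed).spawn(2)
    alloc = generate_allocation(n, spec, seed=np.random.default_rng(ss[0]))
    sched_rng = np.random.default_rng(ss[1])
    rows = []
    for k in range(n):
        sched = schedule_vignettes(sched_rng)
        row = {"participant_id": f"p{k + 1:04d}", "arm": alloc.entries[k]}
        for pos, vid in enumerate(sched.vignette_ids, start=1):
            row[f"vignette_position_{pos}"] = vid
            row[f"advice_strength_{pos}"] = sched.advice_strengths[vid]
        rows.append(row)
    return pd.DataFrame(rows)


def allocation_to_frame(alloc: AllocationList, n: int | None = None):
    """Allocation list as a pandas DataFrame (participant_id, arm)."""
    import pandas as pd

    entries = alloc.entries if n is None else alloc.entries[:n]
    return pd.DataFrame(
        {"participant_id": [f"p{k + 1:04d}" for k in range(len(entries))],
         "arm": entries}
    )
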