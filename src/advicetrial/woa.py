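"""Weight-of-advice (WOA) scoring, exclusion rules, binning and summaries.

For a judge who gives an initial estimate ``i``, receives advice ``a`` and
gives a final estimate ``f``, the weight of advice is

    WOA = (f - i) / |a - i|

with the absolute value on the denominator only.  WOA is 0 when the advice
is fully discounted (f = i) and 1 when it is fully adopted (f = a, for
a > i).  Values above 1 (overshooting past the advice) are capped at 1.
When ``a == i`` the statistic is undefined and the record is excluded.
A consequence of the one-sided absolute value is that movement toward
advice lying *below* the initial estimate produces a negative raw score;
the default policy clamps negatives to 0 (consistent with the statistic's
stated 0-1 range) while retaining the raw value, with ``keep`` and ``drop``
policies available for sensitivity analyses.

Scores are also grouped into five ordinal categories
(<0.2, 0.2-<0.4, 0.4-<0.6, 0.6-<0.8, 0.8-1) for the ordinal sensitivity
model, and a per-protocol filter restricts analysis to participants who
completed all five vignettes.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

TRUNCATION_POLICIES = ("clamp", "keep", "drop")

#: Ordinal category edges: left-closed, right-open, last bin closed at 1.
BIN_EDGES = (0.2, 0.4, 0.6, 0.8)

WOA_COLUMNS = [
    "participant_id",
    "vignette_id",
    "arm",
    "strength",
    "raw_woa",
    "woa",
    "excluded",
    "reason",
    "bin",
]


def compute_woa(i: float, a: float, f: float) -> float | None:
    """Raw weight of advice, or None when undefined (a == i).

    Implements the literal formula ``(f - i) / |a - i|``: the numerator is
    signed, so the raw value may be negative or exceed 1; see
    :func:`truncate_woa` for the range policies.
    """
    for name, v in (("i", i), ("a", a), ("f", f)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name}={v} outside the 0-100 percent scale")
    if a == i:
        return None
    return (f - i) / abs(a - i)


def truncate_woa(raw: float, policy: str = "clamp") -> float | None:
    """Map a raw WOA onto [0, 1].

    Values above 1 are capped at 1 under every policy.  Negative raw values
    are clamped to 0 (``clamp``, default), passed through (``keep``) or
    removed (``drop``, returns None).
    """
    if policy not in TRUNCATION_POLICIES:
        raise ValueError(f"unknown truncation policy {policy!r}")
    if math.isnan(raw):
        raise ValueError("raw WOA is not defined")
    if raw > 1:
        return 1.0
    if raw < 0:
        if policy == "clamp":
            return 0.0
        if policy == "drop":
            return None
    return float(raw)


def bin_woa(woa: float) -> int:
    """Five-level ordinal category of a truncated WOA.

    Categories are 1: [0, 0.2), 2: [0.2, 0.4), 3: [0.4, 0.6),
    4: [0.6, 0.8), 5: [0.8, 1].
    """
    if not 0 <= woa <= 1:
        raise ValueError(f"woa={woa} outside [0, 1]")
    return 1 + int(np.searchsorted(BIN_EDGES, woa, side="right"))


def build_woa_table(dataset: pd.DataFrame, policy: str = "clamp") -> pd.DataFrame:
    """Score a trial dataset: per-record WOA with exclusions and bins.

    Applies, in order: the per-protocol filter (participants with fewer
    than five completed vignettes are excluded), the tie exclusion
    (``a == i``), the truncation ``policy``, and the ordinal binning.
    Covariate columns present in the dataset are carried through.
    """
    if policy not in TRUNCATION_POLICIES:
        raise ValueError(f"unknown truncation policy {policy!r}")
    required = ["participant_id", "vignette_id", "advice", "initial", "final"]
    missing = [c for c in required if c not in dataset.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")

    df = dataset.copy()
    df = df.rename(columns={"advice": "strength"})
    if "completed" not in df.columns:
        df["completed"] = True

    i = df["initial"].to_numpy(dtype=float)
    a = df["strength"].to_numpy(dtype=float)
    f = df["final"].to_numpy(dtype=float)

    tie = a == i
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (f - i) / np.abs(a - i)
    raw[tie] = np.nan

    woa = raw.copy()
    woa[woa > 1] = 1.0
    if policy in ("clamp",):
        woa[woa < 0] = 0.0
    elif policy == "drop":
        woa[woa < 0] = np.nan

    df["raw_woa"] = raw
    df["woa"] = woa
    df["excluded"] = False
    df["reason"] = ""

    # per-protocol: every record of an incomplete participant is excluded
    n_done = df.groupby("participant_id")["completed"].transform("sum")
    n_total = df.groupby("participant_id")["completed"].transform("size")
    incomplete = n_done < n_total
    df.loc[incomplete, ["excluded", "reason"]] = [True, "incomplete"]
    df.loc[~incomplete & tie, ["excluded", "reason"]] = [True, "tie"]
    if policy == "drop":
        neg = ~incomplete & ~tie & (df["raw_woa"] < 0)
        df.loc[neg, ["excluded", "reason"]] = [True, "negative"]
    df.loc[df["excluded"], "woa"] = np.nan

    df["bin"] = pd.array(
        [np.nan if not np.isfinite(w) else bin_woa(w) for w in df["woa"]],
        dtype="Int64",
    )
    front = [c for c in WOA_COLUMNS if c in df.columns]
    rest = [c for c in df.columns if c not in front]
    return df[front + rest]


def per_protocol_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Drop all records of participants who did not complete all vignettes.

    Idempotent: applying it twice changes nothing.
    """
    if "completed" not in records.columns:
        return records.copy()
    done = records.groupby("participant_id")["completed"].transform("all")
    return records[done].copy()


def analysis_records(woa_table: pd.DataFrame) -> pd.DataFrame:
    """Non-excluded records with a defined WOA (the analysed set)."""
    return woa_table[~woa_table["excluded"] & woa_table["woa"].notna()].copy()


GROUPINGS: dict[str, list[str]] = {
    "overall": [],
    "arm": ["arm"],
    "profession_by_arm": ["profession", "arm"],
    "total_experience_by_arm": ["total_experience", "arm"],
    "palliative_experience_by_arm": ["palliative_experience", "arm"],
    "strength_by_arm": ["strength", "arm"],
}


def summarize(
    records: pd.DataFrame,
    grouping: str | Iterable[str] = "overall",
    value: str = "woa",
) -> pd.DataFrame:
    """Descriptive summary (n, mean, sd, normal-approximation 95% CI).

    ``grouping`` is a named grouping (``overall``, ``arm``,
    ``profession_by_arm``, ...) or an explicit list of columns.  Excluded
    records are omitted.  Empty groups yield n=0 rows with undefined
    moments rather than an error.
    """
    if isinstance(grouping, str):
        try:
            cols = GROUPINGS[grouping]
        except KeyError:
            raise ValueError(
                f"unknown grouping {grouping!r}; known: {sorted(GROUPINGS)}"
            ) from None
    else:
        cols = list(grouping)

    df = records
    if "excluded" in df.columns:
        df = df[~df["excluded"]]
    df = df[df[value].notna()]

    def _row(vals: np.ndarray) -> dict:
        n = vals.size
        if n == 0:
            return {"n": 0, "mean": np.nan, "sd": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan}
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        half = stats.norm.ppf(0.975) * sd / math.sqrt(n) if n > 1 else 0.0
        return {"n": n, "mean": mean, "sd": sd,
                "ci_low": mean - half, "ci_high": mean + half}

    if not cols:
        return pd.DataFrame([{"group": "overall", **_row(df[value].to_numpy())}])

    rows = []
    for keys, sub in df.groupby(cols, dropna=False, observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        rows.append({**dict(zip(cols, keys)), **_row(sub[value].to_numpy())})
    out = pd.DataFrame(rows)
    return out.sort_values(cols).reset_index(drop=True)
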