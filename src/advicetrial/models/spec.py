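"""Model specification and treatment-coded design matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default reference levels (treatment contrasts): algorithm arm, doctors,
#: the least-experienced strata and the weakest advice.
DEFAULT_REFERENCES: dict[str, str] = {
    "arm": "ALGORITHM",
    "profession": "doctor",
    "total_experience": "<=14",
    "palliative_experience": "<=5",
    "strength": "50",
}

#: Covariates always treated as categorical even when stored numerically.
ALWAYS_CATEGORICAL = {"arm", "profession", "total_experience",
                      "palliative_experience", "age_band", "gender",
                      "setting", "strength", "vignette_id"}


class RankDeficientError(ValueError):
    """The fixed-effects design matrix is not full rank."""


@dataclass
class ModelSpec:
    """Fixed-effects structure of a multilevel model.

    ``fixed_effects`` lists main-effect column names and two-way
    interactions written ``"a:b"``.  Categorical terms get treatment
    contrasts against ``reference_levels`` (falling back to the first
    category in sorted order).  ``grouping`` names the cluster identifier
    for the random intercept.
    """

    response: str = "woa"
    fixed_effects: list[str] = field(default_factory=lambda: ["arm"])
    grouping: str = "participant_id"
    reference_levels: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCES)
    )

    def columns_used(self) -> list[str]:
        cols: list[str] = []
        for term in self.fixed_effects:
            for c in term.split(":"):
                if c not in cols:
                    cols.append(c)
        return cols


def _dummies(df: pd.DataFrame, col: str, ref: str | None) -> tuple[np.ndarray, list[str]]:
    vals = df[col].astype(str)
    levels = sorted(vals.unique())
    if ref is None or ref not in levels:
        ref = levels[0]
    keep = [lv for lv in levels if lv != ref]
    cols = np.column_stack([(vals == lv).to_numpy(float) for lv in keep]) if keep \
        else np.empty((len(df), 0))
    return cols, [f"{col}[{lv}]" for lv in keep]


def _term_matrix(df: pd.DataFrame, term: str, refs: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    parts = term.split(":")
    mats, names = [], []
    for col in parts:
        if col not in df.columns:
            raise ValueError(f"model term {term!r} references missing column {col!r}")
        if col in ALWAYS_CATEGORICAL or not pd.api.types.is_numeric_dtype(df[col]):
            m, nm = _dummies(df, col, refs.get(col))
        else:
            m, nm = df[[col]].to_numpy(float), [col]
        mats.append((m, nm))
    mat, names = mats[0]
    for m2, nm2 in mats[1:]:
        mat = np.einsum("ij,ik->ijk", mat, m2).reshape(len(df), -1)
        names = [f"{a}:{b}" for a in names for b in nm2]
    return mat, names


def build_design(df: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    """Intercept-plus-treatment-contrast design matrix.

    Returns (X, column names, term -> column-name map) and raises
    :class:`RankDeficientError` naming the collinear columns when X is not
    full rank.
    """
    mats = [np.ones((len(df), 1))]
    names = ["Intercept"]
    term_map: dict[str, list[str]] = {}
    for term in spec.fixed_effects:
        m, nm = _term_matrix(df, term, spec.reference_levels)
        mats.append(m)
        names.extend(nm)
        term_map[term] = nm
    X = np.hstack(mats)
    # QR-based rank check, naming the offending columns
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps * 100
    bad = [names[k] for k in np.nonzero(diag < tol)[0]]
    if bad:
        raise RankDeficientError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )
    return X, names, term_map
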