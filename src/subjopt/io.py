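"""Reading, writing and validation of trial-level choice data.

A choice dataset is a tidy pandas DataFrame with one row per viewed stimulus:

    subject_id  K  round  opportunity  value  choice  rt_ms  forced

``choice`` is "accept" or "reject"; ``rt_ms`` may be missing (empty field on
disk); ``forced`` is true exactly on last-opportunity rows.  Files are
tab-delimited UTF-8 with a '.' decimal separator.  Opportunity and round
indices are 1-based.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

__all__ = ["CHOICE_COLUMNS", "validate_choices", "read_choices", "write_choices"]

CHOICE_COLUMNS = [
    "subject_id",
    "K",
    "round",
    "opportunity",
    "value",
    "choice",
    "rt_ms",
    "forced",
]


class ChoiceDataError(ValueError):
    """A choice dataset violates the task-structure invariants."""


def validate_choices(df: pd.DataFrame, v_min: int = 0, v_max: int = 150) -> pd.DataFrame:
    """Validate task-structure invariants; return the frame on success.

    Checks: schema; integer stimulus values within [v_min, v_max]; forced
    exactly on opportunity-K rows; each (subject, round) ends with its single
    accept; opportunities consecutive from 1.  Raises `ChoiceDataError`
    naming the first offending row.
    """
    missing = [c for c in CHOICE_COLUMNS if c not in df.columns]
    if missing:
        raise ChoiceDataError(f"missing columns: {missing}")
    bad = df.index[(df["value"] < v_min) | (df["value"] > v_max)]
    if len(bad):
        raise ChoiceDataError(
            f"row {bad[0]}: value {df.loc[bad[0], 'value']} outside [{v_min}, {v_max}]"
        )
    if not df["choice"].isin(["accept", "reject"]).all():
        bad = df.index[~df["choice"].isin(["accept", "reject"])][0]
        raise ChoiceDataError(f"row {bad}: choice must be accept|reject")
    bad = df.index[df["forced"].astype(bool) != (df["opportunity"] == df["K"])]
    if len(bad):
        raise ChoiceDataError(
            f"row {bad[0]}: forced flag must be set iff opportunity == K"
        )
    final = df.index[(df["opportunity"] == df["K"]) & (df["choice"] != "accept")]
    if len(final):
        raise ChoiceDataError(f"row {final[0]}: reject recorded at opportunity K")
    for (subj, rnd), g in df.groupby(["subject_id", "round"], sort=False):
        opp = g["opportunity"].to_numpy()
        if not np.array_equal(opp, np.arange(1, len(opp) + 1)):
            raise ChoiceDataError(
                f"subject {subj} round {rnd}: opportunities not consecutive from 1"
            )
        acc = (g["choice"] == "accept").to_numpy()
        if acc.sum() != 1 or not acc[-1]:
            raise ChoiceDataError(
                f"subject {subj} round {rnd}: round must end with its single accept"
            )
    return df


def read_choices(path, validate: bool = True) -> pd.DataFrame:
    """Read a choice dataset from TSV (missing rt_ms as empty field)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    for col in ("K", "round", "opportunity", "value"):
        df[col] = df[col].astype(int)
    df["forced"] = df["forced"].astype(bool)
    if "rt_ms" in df.columns:
        df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    if validate:
        validate_choices(df)
    return df


def write_choices(df: pd.DataFrame, path) -> None:
    df = df[CHOICE_COLUMNS]
    df.to_csv(path, sep="\t", index=False)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
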