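"""Cohort container and CSV interfaces.

A cohort is a pandas DataFrame in wide format, one row per completer:
``patient_id, arm, age, sex, race`` followed by
``item01_baseline .. item17_baseline, item01_mid .. item17_end``.
A long format (``patient_id, visit, item_id, score`` plus per-patient
covariates) is also read and pivoted.  Only completers with all three
visits are analysed; records missing a visit are dropped with a count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import scale
from .scale import N_ITEMS, VISITS

ITEM_COLS = {
    v: [f"item{i:02d}_{v}" for i in range(1, N_ITEMS + 1)] for v in VISITS
}
META_COLS = ["patient_id", "arm", "age", "sex", "race"]

ARMS = ("fluoxetine", "duloxetine", "placebo")


@dataclass
class ValidationReport:
    """Per-record violations found by :func:`validate_cohort`."""

    n_records: int
    violations: dict[str, list[str]] = field(default_factory=dict)
    n_dropped_incomplete: int = 0

    @property
    def ok(self) -> bool:
        return not self.violations

    def summary(self) -> str:
        lines = [f"{self.n_records} records, {len(self.violations)} with violations"]
        if self.n_dropped_incomplete:
            lines.append(f"{self.n_dropped_incomplete} dropped (missing visit)")
        for pid, probs in self.violations.items():
            for p in probs:
                lines.append(f"  {pid}: {p}")
        return "\n".join(lines)


class Cohort:
    """Wide-format cohort of completers with all three CDRS-R visits."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in META_COLS if c not in frame.columns]
        for v in VISITS:
            missing += [c for c in ITEM_COLS[v] if c not in frame.columns]
        if missing:
            raise ValueError(f"cohort frame missing columns: {missing[:5]} ...")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    # -- raw accessors -------------------------------------------------
    def items(self, visit: str) -> np.ndarray:
        """(n, 17) integer item-score matrix at a visit."""
        return self.frame[ITEM_COLS[visit]].to_numpy(dtype=int)

    def totals(self, visit: str) -> np.ndarray:
        return self.items(visit).sum(axis=1)

    # -- derived labels ------------------------------------------------
    def outcomes(self, visit: str, response_reference: str = "scale_floor") -> np.ndarray:
        """Outcome label per patient at the mid or end visit."""
        base = self.totals("baseline")
        cur = self.totals(visit)
        return np.array(
            [
                scale.classify_outcome(int(b), int(c), response_reference)
                for b, c in zip(base, cur)
            ]
        )

    def followup_strata(self, visit: str) -> np.ndarray:
        return np.array(
            [scale.assign_followup_stratum(int(t), visit) for t in self.totals(visit)]
        )

    def derived_frame(self, response_reference: str = "scale_floor") -> pd.DataFrame:
        """Audit table of totals, outcome labels and fixed strata."""
        out = self.frame[META_COLS].copy()
        for v in VISITS:
            out[f"total_{v}"] = self.totals(v)
        for v in ("mid", "end"):
            out[f"outcome_{v}"] = self.outcomes(v, response_reference)
            out[f"stratum_{v}"] = self.followup_strata(v)
        return out

    def subset(self, index: np.ndarray) -> "Cohort":
        """Rows selected by a boolean mask or an integer index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            return Cohort(self.frame.loc[index].copy())
        return Cohort(self.frame.iloc[index].copy())

    # -- IO ------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Check score ranges and the baseline >= 40 inclusion rule.

    The report lists violations per patient; clean records pass through
    unchanged (validation never mutates the cohort).
    """
    report = ValidationReport(n_records=len(cohort))
    for _, row in cohort.frame.iterrows():
        pid = str(row["patient_id"])
        probs: list[str] = []
        for v in VISITS:
            scores = [row[c] for c in ITEM_COLS[v]]
            if any(pd.isna(scores)):
                probs.append(f"missing item scores at {v} visit")
                continue
            probs += [f"{v}: {m}" for m in scale.validate_items(int(s) for s in scores)]
        if not any(pd.isna(row[c]) for c in ITEM_COLS["baseline"]):
            base_total = int(sum(int(row[c]) for c in ITEM_COLS["baseline"]))
            if base_total < scale.ACTIVE_CUT:
                probs.append(
                    f"baseline total {base_total} below inclusion threshold "
                    f"{scale.ACTIVE_CUT}"
                )
        if probs:
            report.violations[pid] = probs
    return report


def read_cohort_csv(path: str | Path) -> tuple[Cohort, ValidationReport]:
    """Read a cohort CSV (wide or long), drop incompleters, validate.

    Long format is detected by the presence of ``visit``/``item_id``
    columns and pivoted to wide.  Lines starting with ``#`` are ignored.
    """
    df = pd.read_csv(path, comment="#")
    if {"visit", "item_id", "score"}.issubset(df.columns):
        df = _pivot_long(df)
    keep = df[[c for v in VISITS for c in ITEM_COLS[v]]].notna().all(axis=1)
    dropped = int((~keep).sum())
    cohort = Cohort(df.loc[keep].copy())
    report = validate_cohort(cohort)
    report.n_dropped_incomplete = dropped
    return cohort, report


def _pivot_long(df: pd.DataFrame) -> pd.DataFrame:
    meta = df[META_COLS].drop_duplicates("patient_id").set_index("patient_id")
    wide = df.pivot_table(
        index="patient_id", columns=["visit", "item_id"], values="score", aggfunc="first"
    )
    wide.columns = [f"item{int(i):02d}_{v}" for v, i in wide.columns]
    out = meta.join(wide).reset_index()
    return out
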