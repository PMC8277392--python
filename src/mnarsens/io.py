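"""CSV loading, validation, and the packaged attrition-table fixture.

Study tables need columns ``study_id, n_itt_active, drop_active,
n_itt_passive, drop_passive``; any further columns are kept as moderators.
The raw review coding columns (``diff``, ``method``, ``multiple_imputation``,
``maximum_likelihood``) are translated into the numeric moderators used by
the meta-analysis (``total_n``, ``overall_attrition``, ``tested_diff``,
``detected_diff``, ``used_ml_or_mi``). Subject-level trial CSVs need
``subject_id, arm, pretest, posttest`` with blank or NA posttest meaning
missing.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .meta_attrition import StudyRecord
from .pattern_mixture import TrialDataset

__all__ = [
    "load_study_table",
    "load_packaged_attrition_table",
    "load_trial",
    "write_study_table",
    "write_trial",
    "StudyTableError",
]

REQUIRED_STUDY_COLUMNS = [
    "study_id",
    "n_itt_active",
    "drop_active",
    "n_itt_passive",
    "drop_passive",
]

CODING_COLUMNS = ("diff", "method", "multiple_imputation", "maximum_likelihood")


class StudyTableError(ValueError):
    """Raised with a list of offending rows when a study table is malformed."""


def _derive_moderators(row: pd.Series) -> dict:
    mods: dict = {}
    total = float(row["n_itt_active"]) + float(row["n_itt_passive"])
    mods["total_n"] = total
    mods["overall_attrition"] = (
        float(row["drop_active"]) + float(row["drop_passive"])
    ) / total
    if "diff" in row.index:
        raw = "" if pd.isna(row["diff"]) else str(row["diff"]).strip().lower()
        mods["tested_diff"] = 0 if raw in ("n/a", "na", "") else 1
        mods["detected_diff"] = 1 if raw.startswith("yes") else 0
    if "method" in row.index and pd.notna(row["method"]):
        mods["method"] = str(row["method"]).strip()
    mi = ml = False
    if "multiple_imputation" in row.index and pd.notna(row["multiple_imputation"]):
        mi = str(row["multiple_imputation"]).strip().lower() == "yes"
    if "maximum_likelihood" in row.index and pd.notna(row["maximum_likelihood"]):
        # "Unclear" counts as not using ML
        ml = str(row["maximum_likelihood"]).strip().lower() == "yes"
    if any(c in row.index for c in ("multiple_imputation", "maximum_likelihood")):
        mods["used_ml_or_mi"] = int(mi or ml)
        mods["used_mi"] = int(mi)
        mods["used_ml"] = int(ml)
    # pass through any other numeric columns
    for col in row.index:
        if col in REQUIRED_STUDY_COLUMNS or col in CODING_COLUMNS or col in mods:
            continue
        try:
            mods[col] = float(row[col])
        except (TypeError, ValueError):
            mods[col] = row[col]
    return mods


def load_study_table(path) -> list[StudyRecord]:
    """Read and validate a study-level attrition CSV."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise StudyTableError(f"missing required columns: {missing}")
    records, problems = [], []
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based with header
        try:
            counts = {c: float(row[c]) for c in REQUIRED_STUDY_COLUMNS[1:]}
        except (TypeError, ValueError):
            problems.append(f"row {rownum}: non-numeric count")
            continue
        if any(v < 0 for v in counts.values()):
            problems.append(f"row {rownum} ({row['study_id']}): negative count")
            continue
        try:
            records.append(
                StudyRecord(
                    study_id=str(row["study_id"]),
                    moderators=_derive_moderators(row),
                    **counts,
                )
            )
        except ValueError as err:
            problems.append(f"row {rownum}: {err}")
    if problems:
        raise StudyTableError("invalid study table:\n" + "\n".join(problems))
    return records


def load_packaged_attrition_table() -> list[StudyRecord]:
    """The 36-study smartphone-RCT attrition table shipped with the package."""
    ref = resources.files("mnarsens.data").joinpath("attrition_studies.csv")
    with resources.as_file(ref) as path:
        return load_study_table(path)


def write_study_table(records: list[StudyRecord], path, header_comment: str | None = None) -> None:
    rows = []
    for r in records:
        row = {
            "study_id": r.study_id,
            "n_itt_active": r.n_itt_active,
            "drop_active": r.drop_active,
            "n_itt_passive": r.n_itt_passive,
            "drop_passive": r.drop_passive,
        }
        row.update(r.moderators)
        rows.append(row)
    _write_csv(pd.DataFrame(rows), path, header_comment)


def load_trial(
    path,
    direction: str = "lower_is_better",
    covariates: list[str] | None = None,
) -> TrialDataset:
    """Read a subject-level trial CSV; blank or NA posttest means missing."""
    df = pd.read_csv(path, comment="#", na_values=["NA", ""])
    needed = ["subject_id", "arm", "pretest", "posttest"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id: {sorted(map(str, dup.unique()))}")
    no_pre = df["pretest"].isna()
    if no_pre.any():
        import warnings

        warnings.warn(
            f"excluding {int(no_pre.sum())} subjects with missing pretest"
        )
        df = df[~no_pre]
    cov = df[covariates].astype(float) if covariates else None
    return TrialDataset(
        subject_id=df["subject_id"].to_numpy(),
        arm=df["arm"].str.strip().to_numpy(),
        pretest=df["pretest"].to_numpy(float),
        posttest=df["posttest"].to_numpy(float),
        covariates=cov,
        direction=direction,
    )


def write_trial(data: TrialDataset, path, header_comment: str | None = None) -> None:
    _write_csv(data.to_frame(), path, header_comment)


def _write_csv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, na_rep="")
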