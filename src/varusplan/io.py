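"""Readers and writers for landmark files, cohort tables and scenario configs.

Formats
-------
Landmarks (JSON): an object mapping each landmark name to ``[x, y]`` (mm),
plus ``"side": "left"|"right"`` and ``"talus_joint_line": [[x,y],[x,y]]``.

Landmarks (CSV): columns ``name,x,y``; the two talus joint-line points use
the names ``talus_joint_line_1`` and ``talus_joint_line_2``; the side is a
row with name ``side`` and the value in the ``x`` column.

Cohort (CSV): columns ``id,mFTA,mMPTA,mLDFA,JLCA,WBL_ratio`` (UTF-8, comma
separated, '.' decimal, header row mandatory).  Writers prepend ``#``
comment lines recording tool version, scenario and seed; readers skip them.

Scenario (JSON): ``{"mmpta_upper": 90|95, "mldfa_lower": 85,
"target_mfta_varus": -2}``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd

from . import __version__
from .geometry import POINT_FIELDS, KneeAlignment, LandmarkSet
from .planner import ScenarioLimits

__all__ = [
    "read_landmarks",
    "read_cohort",
    "write_cohort",
    "read_scenario",
    "cohort_to_frame",
    "frame_to_cohort",
]

COHORT_COLUMNS = ["id", "mFTA", "mMPTA", "mLDFA", "JLCA", "WBL_ratio"]


class InputFormatError(ValueError):
    """Malformed input file; the message carries file/line context."""


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark file (JSON or CSV, decided by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _landmarks_from_json(path)
    if path.suffix.lower() == ".csv":
        return _landmarks_from_csv(path)
    raise InputFormatError(f"{path}: unsupported landmark format {path.suffix!r}")


def _landmarks_from_json(path: Path) -> LandmarkSet:
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InputFormatError(f"{path}:{exc.lineno}: invalid JSON ({exc.msg})") from exc
    missing = [n for n in (*POINT_FIELDS, "talus_joint_line", "side") if n not in raw]
    if missing:
        raise InputFormatError(f"{path}: missing landmark(s): {', '.join(missing)}")
    try:
        return LandmarkSet(
            **{n: tuple(raw[n]) for n in POINT_FIELDS},
            talus_joint_line=tuple(tuple(p) for p in raw["talus_joint_line"]),
            side=raw["side"],
        )
    except (TypeError, ValueError) as exc:
        raise InputFormatError(f"{path}: {exc}") from exc


def _landmarks_from_csv(path: Path) -> LandmarkSet:
    df = pd.read_csv(path, comment="#")
    required = {"name", "x", "y"}
    if not required.issubset(df.columns):
        raise InputFormatError(f"{path}: landmark CSV needs columns name,x,y")
    rows = {str(r["name"]): r for _, r in df.iterrows()}
    if "side" not in rows:
        raise InputFormatError(f"{path}: missing 'side' row")
    side = str(rows["side"]["x"]).strip()
    missing = [n for n in POINT_FIELDS if n not in rows]
    for extra in ("talus_joint_line_1", "talus_joint_line_2"):
        if extra not in rows:
            missing.append(extra)
    if missing:
        raise InputFormatError(f"{path}: missing landmark(s): {', '.join(missing)}")

    def pt(name: str):
        r = rows[name]
        return (float(r["x"]), float(r["y"]))

    try:
        return LandmarkSet(
            **{n: pt(n) for n in POINT_FIELDS},
            talus_joint_line=(pt("talus_joint_line_1"), pt("talus_joint_line_2")),
            side=side,
        )
    except (TypeError, ValueError) as exc:
        raise InputFormatError(f"{path}: {exc}") from exc


def cohort_to_frame(
    cohort: Sequence[KneeAlignment], ids: Optional[Sequence] = None
) -> pd.DataFrame:
    if ids is None:
        ids = [f"leg{i + 1:04d}" for i in range(len(cohort))]
    return pd.DataFrame(
        {
            "id": list(ids),
            "mFTA": [k.mFTA for k in cohort],
            "mMPTA": [k.mMPTA for k in cohort],
            "mLDFA": [k.mLDFA for k in cohort],
            "JLCA": [k.JLCA for k in cohort],
            "WBL_ratio": [k.WBL_ratio for k in cohort],
        }
    )


def frame_to_cohort(df: pd.DataFrame) -> List[KneeAlignment]:
    return [
        KneeAlignment(
            mFTA=float(r.mFTA),
            mMPTA=float(r.mMPTA),
            mLDFA=float(r.mLDFA),
            JLCA=float(r.JLCA),
            WBL_ratio=float(r.WBL_ratio),
        )
        for r in df.itertuples(index=False)
    ]


def read_cohort(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pandas raises several parser error types
        raise InputFormatError(f"{path}: {exc}") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing column(s): {', '.join(missing)}")
    for col in COHORT_COLUMNS[1:]:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise InputFormatError(
                f"{path}:{bad[0] + 2}: non-numeric value in column {col!r}"
            )
        df[col] = pd.to_numeric(df[col])
    return df


def write_cohort(
    df: pd.DataFrame,
    path: str | Path,
    *,
    scenario: Optional[str] = None,
    seed: Optional[int] = None,
) -> None:
    """Write a cohort (or plan) table with a provenance comment header."""
    path = Path(path)
    header = [f"# varusplan {__version__}"]
    if scenario is not None:
        header.append(f"# scenario: {scenario}")
    if seed is not None:
        header.append(f"# seed: {seed}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False)


def read_scenario(path: str | Path) -> ScenarioLimits:
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InputFormatError(f"{path}:{exc.lineno}: invalid JSON ({exc.msg})") from exc
    try:
        return ScenarioLimits(
            mMPTA_upper=float(raw.get("mmpta_upper", 90.0)),
            mLDFA_lower=float(raw.get("mldfa_lower", 85.0)),
            target_mFTA=float(raw.get("target_mfta_varus", -2.0)),
        )
    except (TypeError, ValueError) as exc:
        raise InputFormatError(f"{path}: {exc}") from exc
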