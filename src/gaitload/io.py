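"""Result serialization: tidy CSV tables plus a JSON manifest.

Outputs are deterministic: fixed float formatting, sorted keys, no
timestamps, so re-running a study with the same configuration and master
seed produces byte-identical files (idempotent overwrite).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import InvalidInputError
from .study import StudyResult, speed_table

_FLOAT_FMT = "%.10g"

RESULT_TABLES = {
    "speeds.csv": "speeds",
    "stress_summary.csv": "stress",
    "percent_change.csv": "change",
    "pp_difference.csv": "pp",
    "cohort_change.csv": "cohort_change",
    "cohort_pp.csv": "cohort_pp",
    "peaks.csv": "peaks",
    "peak_tests.csv": "peak_tests",
}


def write_results(result: StudyResult, out_dir: str | Path) -> dict:
    """Write all study tables and the manifest; returns the manifest."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise InvalidInputError(f"cannot create output directory: {err}")
    if not out.is_dir():
        raise InvalidInputError(f"not a directory: {out}")

    for filename, attr in RESULT_TABLES.items():
        df: pd.DataFrame = getattr(result, attr)
        df.to_csv(out / filename, index=False, float_format=_FLOAT_FMT)
    speed_table(result.speeds).to_csv(out / "speed_table.csv", index=False,
                                      float_format=_FLOAT_FMT)
    result.late_stance_direction().to_csv(
        out / "late_stance_direction.csv", index=False,
        float_format=_FLOAT_FMT)

    manifest = dict(result.manifest)
    manifest["speed_anova"] = result.speed_anova
    manifest["notes"] = {
        "stress_metric": "upper-quartile mean of superficial contact "
                         "pressure (maximum-principal-stress surrogate), MPa",
        "anova_sphericity": "no sphericity correction applied",
        "alpha": 0.05,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def read_results(in_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read the result tables back as DataFrames (by table name)."""
    src = Path(in_dir)
    if not src.is_dir():
        raise InvalidInputError(f"not a directory: {src}")
    out = {}
    for filename, attr in RESULT_TABLES.items():
        path = src / filename
        if path.exists():
            out[attr] = pd.read_csv(path)
    return out
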