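"""CSV/JSON readers and writers binding the model and meta-analysis modules.

Study tables use the header ``study_id, mean_t, sd_t, n_t, mean_c, sd_c, n_c``
with any extra numeric columns treated as per-study moderators.  Result
writers keep full float precision (shortest round-trip repr) with optional
1-decimal display companions added by the callers.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .meta import StudySummary

__all__ = [
    "STUDY_COLUMNS",
    "read_study_table",
    "write_study_table",
    "studies_to_frame",
    "write_results",
    "read_results",
]

STUDY_COLUMNS = ["study_id", "mean_t", "sd_t", "n_t", "mean_c", "sd_c", "n_c"]


def studies_to_frame(studies: list[StudySummary]) -> pd.DataFrame:
    """Study summaries as a DataFrame in the canonical column order."""
    moderator_keys: list[str] = []
    for s in studies:
        for key in s.moderators:
            if key not in moderator_keys:
                moderator_keys.append(key)
    rows = []
    for s in studies:
        row = {c: getattr(s, c) for c in STUDY_COLUMNS}
        row.update({k: s.moderators.get(k) for k in moderator_keys})
        rows.append(row)
    return pd.DataFrame(rows, columns=STUDY_COLUMNS + moderator_keys)


def write_study_table(studies: list[StudySummary], path: str | Path) -> None:
    studies_to_frame(studies).to_csv(path, index=False)


def read_study_table(path: str | Path) -> list[StudySummary]:
    """Read and validate a study CSV; errors name the offending row.

    Rows are numbered from 1 (excluding the header) in diagnostics.
    """
    df = pd.read_csv(path)
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    moderator_cols = [c for c in df.columns if c not in STUDY_COLUMNS]
    studies: list[StudySummary] = []
    for idx, row in df.iterrows():
        rowno = idx + 1
        try:
            mean_t, mean_c = float(row.mean_t), float(row.mean_c)
            if mean_t <= 0 or mean_c <= 0:
                raise ValueError("arm means must be positive")
            studies.append(
                StudySummary(
                    study_id=str(row.study_id),
                    mean_t=mean_t,
                    sd_t=float(row.sd_t),
                    n_t=int(row.n_t),
                    mean_c=mean_c,
                    sd_c=float(row.sd_c),
                    n_c=int(row.n_c),
                    moderators={
                        c: float(row[c])
                        for c in moderator_cols
                        if pd.notna(row[c])
                    },
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, row {rowno}: {exc}") from exc
    return studies


def write_results(
    records: list[dict], path: str | Path, dialect: str = "csv"
) -> None:
    """Write records (list of flat dicts) as CSV or JSON with stable column order.

    Column order follows the keys of the first record; an empty record list
    yields a header-only CSV or an empty JSON array.
    """
    path = Path(path)
    if dialect == "csv":
        columns = list(records[0].keys()) if records else []
        pd.DataFrame(records, columns=columns).to_csv(path, index=False)
    elif dialect == "json":
        path.write_text(json.dumps(records, indent=2) + "\n")
    else:
        raise ValueError(f"dialect must be csv|json, got {dialect!r}")


def read_results(path: str | Path) -> list[dict]:
    """Read back a results file written by :func:`write_results`."""
    path = Path(path)
    if path.suffix == ".json":
        return json.loads(path.read_text())
    return pd.read_csv(path).to_dict(orient="records")
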