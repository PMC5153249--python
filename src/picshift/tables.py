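"""Delimited-table I/O for titrations, time courses, endpoints and fit results.

All tables are plain CSV/TSV with a mandatory header row, decimal points and
no thousands separators.  Schemas:

titrations   replicate_id, titrant, titrant_total_nM, frac_free, frac_43S, frac_43S_eIF3
timecourses  replicate_id, condition, mRNA_label, time_min, frac_recruited
endpoints    replicate_id, condition, mRNA_label, frac_recruited
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .equilibria import MixtureTotals
from .gelshift import Lane, TitrationExperiment
from .kinetics import TimeCourse

__all__ = [
    "read_titrations",
    "write_titrations",
    "read_timecourses",
    "write_timecourses",
    "read_endpoints",
    "write_endpoints",
]

TITRATION_COLUMNS = [
    "replicate_id", "titrant", "titrant_total_nM",
    "frac_free", "frac_43S", "frac_43S_eIF3",
]
TIMECOURSE_COLUMNS = ["replicate_id", "condition", "mRNA_label", "time_min", "frac_recruited"]
ENDPOINT_COLUMNS = ["replicate_id", "condition", "mRNA_label", "frac_recruited"]


def _sep(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return "\t" if fmt == "tsv" else ","
    return "\t" if str(path).endswith(".tsv") else ","


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def write_titrations(
    path: str | Path,
    experiments: Sequence[TitrationExperiment],
    fmt: str | None = None,
) -> None:
    rows = [
        {
            "replicate_id": exp.replicate_id,
            "titrant": exp.titrant,
            "titrant_total_nM": lane.titrant_total,
            "frac_free": lane.frac_free,
            "frac_43S": lane.frac_43s,
            "frac_43S_eIF3": lane.frac_43s_eif3,
        }
        for exp in experiments
        for lane in exp.lanes
    ]
    pd.DataFrame(rows, columns=TITRATION_COLUMNS).to_csv(path, sep=_sep(path, fmt), index=False)


def read_titrations(
    path: str | Path,
    fixed_totals: MixtureTotals,
    k3_assumed: float | None = None,
    fmt: str | None = None,
) -> list[TitrationExperiment]:
    """Read a titration table and regroup lanes into per-replicate experiments.

    The table carries lane-level quantities only; the fixed mixture totals
    and (for eIF3 titrations) the assumed K3 are experiment-level metadata
    supplied by the caller/config.
    """
    df = pd.read_csv(path, sep=_sep(path, fmt))
    _require_columns(df, TITRATION_COLUMNS, path)
    experiments = []
    for rep_id, group in df.groupby("replicate_id", sort=False):
        titrants = group["titrant"].unique()
        if len(titrants) != 1:
            raise ValueError(f"{path}: replicate {rep_id!r} mixes titrant types {list(titrants)}")
        group = group.sort_values("titrant_total_nM")
        lanes = tuple(
            Lane(
                float(row.titrant_total_nM),
                float(row.frac_free),
                float(row.frac_43S),
                float(row.frac_43S_eIF3),
            )
            for row in group.itertuples()
        )
        experiments.append(
            TitrationExperiment(str(rep_id), str(titrants[0]), lanes, fixed_totals, k3_assumed)
        )
    return experiments


def write_timecourses(
    path: str | Path, courses: Sequence[TimeCourse], fmt: str | None = None
) -> None:
    rows = [
        {
            "replicate_id": tc.replicate_id,
            "condition": tc.condition,
            "mRNA_label": tc.mrna_label,
            "time_min": t,
            "frac_recruited": f,
        }
        for tc in courses
        for t, f in zip(tc.times, tc.fractions)
    ]
    pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS).to_csv(path, sep=_sep(path, fmt), index=False)


def read_timecourses(path: str | Path, fmt: str | None = None) -> list[TimeCourse]:
    df = pd.read_csv(path, sep=_sep(path, fmt), keep_default_na=False)
    _require_columns(df, TIMECOURSE_COLUMNS, path)
    courses = []
    for (rep_id, condition, label), group in df.groupby(
        ["replicate_id", "condition", "mRNA_label"], sort=False
    ):
        group = group.sort_values("time_min")
        courses.append(
            TimeCourse(
                replicate_id=str(rep_id),
                times=tuple(group["time_min"].astype(float)),
                fractions=tuple(group["frac_recruited"].astype(float)),
                mrna_label=str(label),
                condition=str(condition),
            )
        )
    return courses


def write_endpoints(
    path: str | Path,
    fractions: Sequence[float],
    condition: str = "",
    mrna_label: str = "",
    fmt: str | None = None,
) -> None:
    rows = [
        {
            "replicate_id": f"rep{i}",
            "condition": condition,
            "mRNA_label": mrna_label,
            "frac_recruited": f,
        }
        for i, f in enumerate(fractions, start=1)
    ]
    pd.DataFrame(rows, columns=ENDPOINT_COLUMNS).to_csv(path, sep=_sep(path, fmt), index=False)


def read_endpoints(path: str | Path, fmt: str | None = None) -> list[float]:
    df = pd.read_csv(path, sep=_sep(path, fmt), keep_default_na=False)
    _require_columns(df, ENDPOINT_COLUMNS, path)
    return [float(v) for v in df["frac_recruited"]]
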