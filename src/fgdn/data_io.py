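"""On-disk dialects for cohorts, reports and model parameter files.

Time series are headerless TSV, one file per subject named ``<subject_id>.tsv``
with rows = timepoints and columns = ROIs in atlas order. Phenotypes are a CSV
with header ``subject_id,site,diagnosis``. Reports are JSON; parameter arrays
are persisted as compressed ``.npz`` with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reports import EvalReport

DIAGNOSES = ("ASD", "HC", "UNKNOWN")


@dataclass
class RoiTimeSeries:
    """One subject's ROI signal matrix (T timepoints x N ROIs) plus metadata."""

    subject_id: str
    site: str
    diagnosis: str
    signal: np.ndarray
    atlas_name: str = "unknown"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError(f"subject {self.subject_id}: signal must be 2-D (T x N)")
        if self.signal.shape[0] < 3:
            raise ValueError(
                f"subject {self.subject_id}: need at least 3 timepoints, got {self.signal.shape[0]}"
            )
        if not np.isfinite(self.signal).all():
            t, r = np.argwhere(~np.isfinite(self.signal))[0]
            raise ValueError(
                f"subject {self.subject_id}: non-finite value at timepoint {t}, ROI {r}"
            )
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(
                f"subject {self.subject_id}: diagnosis {self.diagnosis!r} not in {DIAGNOSES}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.signal.shape[0]

    @property
    def n_rois(self) -> int:
        return self.signal.shape[1]


def load_phenotypes(phenotype_path: str | Path) -> pd.DataFrame:
    """Read the phenotype CSV (``subject_id,site,diagnosis``); diagnoses are
    upper-cased and validated, subject ids must be unique."""
    path = Path(phenotype_path)
    df = pd.read_csv(path, dtype=str)
    required = {"subject_id", "site", "diagnosis"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: phenotype table missing columns {sorted(missing)}")
    df = df[["subject_id", "site", "diagnosis"]].copy()
    df["diagnosis"] = df["diagnosis"].str.upper().str.strip()
    bad = df.loc[~df["diagnosis"].isin(DIAGNOSES), "diagnosis"]
    if len(bad):
        raise ValueError(f"{path}: unknown diagnosis value(s) {sorted(bad.unique())}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate subject id(s) {sorted(dup.unique())}")
    return df


def load_cohort(
    timeseries_dir: str | Path,
    phenotype_path: str | Path,
    atlas_name: str = "unknown",
) -> list[RoiTimeSeries]:
    """Load one :class:`RoiTimeSeries` per phenotype row, in phenotype order.

    Fails with the offending subject id on missing files, with file/position
    on non-finite cells, and on ragged ROI counts across the cohort.
    """
    ts_dir = Path(timeseries_dir)
    pheno = load_phenotypes(phenotype_path)
    cohort: list[RoiTimeSeries] = []
    n_rois: int | None = None
    for row in pheno.itertuples(index=False):
        f = ts_dir / f"{row.subject_id}.tsv"
        if not f.exists():
            raise FileNotFoundError(f"no time-series file for subject {row.subject_id}: {f}")
        signal = pd.read_csv(f, sep="\t", header=None).to_numpy(dtype=float)
        if not np.isfinite(signal).all():
            t, r = np.argwhere(~np.isfinite(signal))[0]
            raise ValueError(f"{f}: non-finite value at row {t}, column {r}")
        if n_rois is None:
            n_rois = signal.shape[1]
        elif signal.shape[1] != n_rois:
            raise ValueError(
                f"{f}: subject {row.subject_id} has {signal.shape[1]} ROI columns, "
                f"cohort has {n_rois}"
            )
        cohort.append(
            RoiTimeSeries(
                subject_id=row.subject_id,
                site=row.site,
                diagnosis=row.diagnosis,
                signal=signal,
                atlas_name=atlas_name,
            )
        )
    return cohort


def write_cohort(cohort: list[RoiTimeSeries], out_dir: str | Path) -> None:
    """Write a cohort in the package dialect (TSVs + phenotypes.csv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in cohort:
        np.savetxt(out / f"{ts.subject_id}.tsv", ts.signal, delimiter="\t", fmt="%.10g")
        rows.append({"subject_id": ts.subject_id, "site": ts.site, "diagnosis": ts.diagnosis})
    pd.DataFrame(rows).to_csv(out / "phenotypes.csv", index=False)


def write_report(report: EvalReport, path: str | Path) -> None:
    """Serialize an :class:`EvalReport` (all folds + summary) as JSON."""
    if not report.folds:
        raise ValueError("refusing to write a report with no folds")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def read_report(path: str | Path) -> EvalReport:
    with open(path) as fh:
        return EvalReport.from_dict(json.load(fh))


def save_arrays(path: str | Path, arrays: dict[str, np.ndarray], meta: dict | None = None) -> None:
    """Persist named arrays as compressed npz with a JSON sidecar ``<path>.json``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **arrays)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta or {}, fh, indent=2)


def load_arrays(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    path = Path(path)
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return arrays, meta
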