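"""Readers/writers for feature tables, MS2 spectra and assay plates, plus
QC alignment and missing-value imputation.

Feature tables are CSV with columns ``feature_id, mz, rt`` followed by one
column per sample; blank cells are missing values (never zero). MS2 spectra
travel as MGF via pyteomics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

__all__ = [
    "Ms2Spectrum",
    "MsFeature",
    "SampleDesign",
    "read_feature_table",
    "write_feature_table",
    "read_mgf",
    "write_mgf",
    "align_to_qc",
    "impute_missing",
]


@dataclass
class Ms2Spectrum:
    """A centroided MS2 spectrum keyed to an LC-MS feature."""

    feature_id: str
    precursor_mz: float
    charge: int = 1
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if np.any(inten <= 0):
            raise ValueError("peak intensities must be positive")
        order = np.argsort(mz, kind="stable")
        self.mz = mz[order]
        self.intensity = inten[order]

    @property
    def n_peaks(self) -> int:
        return self.mz.size

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


@dataclass
class MsFeature:
    """An aligned LC-MS feature with per-sample peak areas.

    ``areas`` values may be NaN (missing in that sample); imputation fills
    them from the feature's observed minimum.
    """

    feature_id: str
    mz: float
    rt: float
    areas: dict[str, float] = field(default_factory=dict)
    ms2: Optional[Ms2Spectrum] = None
    polarity: str = "pos"
    aligned: bool = True

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"feature {self.feature_id}: mz must be > 0")
        if self.rt < 0:
            raise ValueError(f"feature {self.feature_id}: rt must be >= 0")

    def observed_areas(self) -> dict[str, float]:
        return {s: a for s, a in self.areas.items() if a is not None and not math.isnan(a)}

    def max_area(self) -> float:
        obs = self.observed_areas()
        return max(obs.values()) if obs else float("nan")


@dataclass(frozen=True)
class SampleDesign:
    """Maps sample ids to experiment arms (control vs. S9 reaction)."""

    samples: tuple[tuple[str, str], ...]  # (sample_id, arm)

    def __post_init__(self):
        arms = {arm for _, arm in self.samples}
        bad = arms - {"control", "reaction"}
        if bad:
            raise ValueError(f"unknown arms: {sorted(bad)}")

    @classmethod
    def three_vs_three(cls) -> "SampleDesign":
        return cls(
            tuple((f"ctrl_{i}", "control") for i in range(1, 4))
            + tuple((f"rxn_{i}", "reaction") for i in range(1, 4))
        )

    def ids(self, arm: str) -> list[str]:
        return [s for s, a in self.samples if a == arm]

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.samples]


_META_COLS = ("feature_id", "mz", "rt")


def read_feature_table(path, polarity: str = "pos") -> list[MsFeature]:
    """Read a feature table CSV; blank area cells become NaN (missing)."""
    df = pd.read_csv(path, dtype={"feature_id": str})
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df["feature_id"].duplicated().any():
        dups = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"{path}: duplicate feature_id(s) {dups}")
    sample_cols = [c for c in df.columns if c not in _META_COLS]
    for col in sample_cols:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric area in column {col!r}: {exc}") from exc
    features = []
    for _, row in df.iterrows():
        areas = {c: float(row[c]) for c in sample_cols}
        features.append(
            MsFeature(
                feature_id=str(row["feature_id"]),
                mz=float(row["mz"]),
                rt=float(row["rt"]),
                areas=areas,
                polarity=polarity,
            )
        )
    return features


def write_feature_table(features: Sequence[MsFeature], path) -> None:
    sample_ids: list[str] = []
    for f in features:
        for s in f.areas:
            if s not in sample_ids:
                sample_ids.append(s)
    rows = []
    for f in features:
        row = {"feature_id": f.feature_id, "mz": f.mz, "rt": f.rt}
        row.update({s: f.areas.get(s, float("nan")) for s in sample_ids})
        rows.append(row)
    pd.DataFrame(rows, columns=list(_META_COLS) + sample_ids).to_csv(path, index=False)


def read_mgf(path) -> list[Ms2Spectrum]:
    """Read MS2 spectra from an MGF file (peaks sorted on read)."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for i, block in enumerate(reader):
            params = block["params"]
            if "pepmass" not in params:
                raise ValueError(f"{path}: MGF block {i} lacks PEPMASS")
            fid = str(
                params.get("feature_id")
                or params.get("scans")
                or params.get("title")
                or i
            )
            charge = 1
            if params.get("charge"):
                charge = int(params["charge"][0])
            spectra.append(
                Ms2Spectrum(
                    feature_id=fid,
                    precursor_mz=float(params["pepmass"][0]),
                    charge=charge,
                    mz=block["m/z array"],
                    intensity=block["intensity array"],
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Ms2Spectrum], path) -> None:
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {
                "feature_id": s.feature_id,
                "pepmass": s.precursor_mz,
                "charge": s.charge,
                "scans": s.feature_id,
            },
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")


def align_to_qc(
    features: Sequence[MsFeature],
    qc_features: Sequence[MsFeature],
    rt_tol: float = 0.1,
    mz_tol: float = 0.02,
) -> list[MsFeature]:
    """Map features onto pooled-QC reference features.

    Greedy nearest-m/z matching: candidate (feature, QC) pairs within both
    the RT and m/z tolerances are taken in order of increasing |delta m/z|
    (ties broken by feature_id); each feature and each QC feature is used at
    most once. Matched features adopt the QC coordinates; unmatched features
    are retained with ``aligned=False``.
    """
    if rt_tol <= 0 or mz_tol <= 0:
        raise ValueError("tolerances must be > 0")
    candidates = []
    for f in features:
        for q in qc_features:
            dmz = abs(f.mz - q.mz)
            drt = abs(f.rt - q.rt)
            if dmz <= mz_tol and drt <= rt_tol:
                candidates.append((dmz, drt, f.feature_id, q.feature_id, f, q))
    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))
    used_f: set[str] = set()
    used_q: set[str] = set()
    mapping: dict[str, MsFeature] = {}
    for dmz, drt, fid, qid, f, q in candidates:
        if fid in used_f or qid in used_q:
            continue
        used_f.add(fid)
        used_q.add(qid)
        mapping[fid] = q
    out = []
    for f in features:
        if f.feature_id in mapping:
            q = mapping[f.feature_id]
            out.append(replace(f, mz=q.mz, rt=q.rt, aligned=True))
        else:
            out.append(replace(f, aligned=False))
    return out


def impute_missing(
    features: Sequence[MsFeature], fraction: float = 0.10
) -> tuple[list[MsFeature], list[str]]:
    """Fill missing areas with ``fraction`` x the feature's observed minimum.

    Features with no observed value at all cannot be imputed and are dropped;
    their ids are returned as the second element for logging.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    kept: list[MsFeature] = []
    dropped: list[str] = []
    for f in features:
        obs = f.observed_areas()
        if not obs:
            dropped.append(f.feature_id)
            continue
        fill = fraction * min(obs.values())
        areas = {
            s: (a if (a is not None and not math.isnan(a)) else fill)
            for s, a in f.areas.items()
        }
        kept.append(replace(f, areas=areas))
    return kept, dropped
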