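"""Match LC-MS features to predicted biotransformants and score MS2 support.

Annotation is suspect screening on accurate mass: a feature is annotated
with a predicted product when its m/z lies within the MS1 tolerance (default
5 ppm) of the product's adduct m/z. MS2 support is scored as fragment-ion
coverage: the fraction of the feature's signal fragments explainable by the
parent compound's fragments or by those fragments shifted by the reaction's
mass delta (a formula-level approximation to fragment ion search; no
bond-level in-silico fragmentation is attempted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .chemcore import (
    ElementalComposition,
    PredictedCompound,
    ReactionPath,
    adduct_for_polarity,
    delta_mass,
    ppm_error,
)
from .msio import Ms2Spectrum, MsFeature

__all__ = ["Annotation", "match_features", "fish_coverage", "filter_annotations", "annotations_frame"]


@dataclass
class Annotation:
    """One feature <-> predicted-compound match."""

    feature_id: str
    predicted: PredictedCompound
    adduct: str
    ppm: float
    rt_group: int = -1
    ambiguous: bool = False
    fish_coverage: Optional[float] = None
    passed_filter: bool = False
    filter_reasons: tuple[str, ...] = ()


def match_features(
    features: Sequence[MsFeature],
    predictions: Sequence[PredictedCompound],
    ms1_ppm: float = 5.0,
    rt_tol: float = 0.1,
    polarity: str | None = None,
) -> list[Annotation]:
    """Annotate features whose m/z matches a predicted adduct within tolerance.

    A feature may match several isobaric predictions; all matches are kept
    and flagged ambiguous. Features matching the same prediction within
    ``rt_tol`` minutes of each other share an RT group (isomer grouping).
    """
    if polarity is None:
        pols = {f.polarity for f in features}
        if len(pols) > 1:
            raise ValueError(f"mixed polarities in feature list: {sorted(pols)}")
        polarity = pols.pop() if pols else "pos"
    else:
        bad = [f.feature_id for f in features if f.polarity != polarity]
        if bad:
            raise ValueError(f"features with polarity != {polarity!r}: {bad[:5]}")
    adduct = adduct_for_polarity(polarity)

    annotations: list[Annotation] = []
    per_feature: dict[str, list[Annotation]] = {}
    per_prediction: dict[int, list[tuple[MsFeature, Annotation]]] = {}
    for f in sorted(features, key=lambda f: f.feature_id):
        for pi, pc in enumerate(predictions):
            theo = pc.expected_mz(adduct)
            err = ppm_error(f.mz, theo)
            if err <= ms1_ppm:
                ann = Annotation(feature_id=f.feature_id, predicted=pc, adduct=adduct, ppm=err)
                annotations.append(ann)
                per_feature.setdefault(f.feature_id, []).append(ann)
                per_prediction.setdefault(pi, []).append((f, ann))

    for anns in per_feature.values():
        if len(anns) > 1:
            for a in anns:
                a.ambiguous = True

    # RT groups: per prediction, cluster matched features by retention time.
    group_id = 0
    for pi in sorted(per_prediction):
        matched = sorted(per_prediction[pi], key=lambda fa: (fa[0].rt, fa[0].feature_id))
        prev_rt = None
        for f, ann in matched:
            if prev_rt is None or f.rt - prev_rt > rt_tol:
                group_id += 1
            ann.rt_group = group_id
            prev_rt = f.rt
    return annotations


def _candidate_shifts(delta: ElementalComposition | ReactionPath | None) -> list[float]:
    """Mass shifts explainable by the transformation: the aggregate net shift
    plus, for multi-step paths, each cumulative partial sum."""
    shifts = [0.0]
    if delta is None:
        return shifts
    if isinstance(delta, ReactionPath):
        running = ElementalComposition()
        for step in delta.steps:
            running = running + step.delta
            shifts.append(delta_mass(running))
    else:
        shifts.append(delta_mass(delta))
    # dedupe while preserving order
    out: list[float] = []
    for s in shifts:
        if not any(abs(s - t) < 1e-9 for t in out):
            out.append(s)
    return out


def fish_coverage(
    feature_ms2: Ms2Spectrum,
    parent_ms2: Ms2Spectrum,
    delta: ElementalComposition | ReactionPath | None,
    ms2_ppm: float = 10.0,
    snr: float = 3.0,
) -> Optional[float]:
    """Fragment-coverage score (percent) of a product spectrum.

    Candidate fragments are the parent's fragment m/z values and each of them
    shifted by the transformation's mass delta (for multi-step paths, every
    cumulative partial-sum shift is allowed). The score is the percentage of
    the feature's fragments at or above the signal floor that match any
    candidate within ``ms2_ppm``. The floor is ``snr`` x the median peak
    intensity of the feature spectrum, a spectrum-internal noise estimate.
    Returns None when no fragment clears the floor (score undefined).
    """
    if feature_ms2.n_peaks == 0 or parent_ms2.n_peaks == 0:
        raise ValueError("both spectra must be nonempty")
    floor = snr * float(np.median(feature_ms2.intensity))
    signal_mz = feature_ms2.mz[feature_ms2.intensity >= floor]
    if signal_mz.size == 0:
        return None
    shifts = _candidate_shifts(delta)
    candidates = np.unique(
        np.concatenate([parent_ms2.mz + s for s in shifts])
    )
    candidates = candidates[candidates > 0]
    matched = 0
    for mz in signal_mz:
        tol = ms2_ppm * 1e-6 * mz
        idx = np.searchsorted(candidates, mz)
        best = np.inf
        for j in (idx - 1, idx):
            if 0 <= j < candidates.size:
                best = min(best, abs(candidates[j] - mz))
        if best <= tol:
            matched += 1
    return 100.0 * matched / signal_mz.size


def score_annotations(
    annotations: Sequence[Annotation],
    features: Sequence[MsFeature],
    parent_ms2: Ms2Spectrum | None,
    ms2_ppm: float = 10.0,
    snr: float = 3.0,
) -> None:
    """Attach fragment-coverage scores in place, where MS2 is available."""
    by_id = {f.feature_id: f for f in features}
    for ann in annotations:
        f = by_id.get(ann.feature_id)
        if f is None or f.ms2 is None or parent_ms2 is None:
            ann.fish_coverage = None
            continue
        ann.fish_coverage = fish_coverage(
            f.ms2, parent_ms2, ann.predicted.path, ms2_ppm=ms2_ppm, snr=snr
        )


def filter_annotations(
    annotations: Sequence[Annotation],
    features: Sequence[MsFeature],
    min_area: float = 1e5,
    min_fish: float = 50.0,
) -> list[Annotation]:
    """Keep annotations passing the area OR fragment-coverage gate.

    An annotation survives iff the feature's maximum per-sample area is at
    least ``min_area`` or its coverage score is at least ``min_fish``. Both
    checks are recorded per annotation in ``filter_reasons``.
    """
    by_id = {f.feature_id: f for f in features}
    kept = []
    for ann in annotations:
        f = by_id.get(ann.feature_id)
        reasons = []
        max_area = f.max_area() if f is not None else float("nan")
        if f is not None and max_area == max_area and max_area >= min_area:
            reasons.append(f"max_area {max_area:.3g} >= {min_area:.3g}")
        if ann.fish_coverage is not None and ann.fish_coverage >= min_fish:
            reasons.append(f"fish_coverage {ann.fish_coverage:.1f} >= {min_fish:.1f}")
        ann.passed_filter = bool(reasons)
        ann.filter_reasons = tuple(reasons)
        if ann.passed_filter:
            kept.append(ann)
    return kept


def annotations_frame(annotations: Iterable[Annotation]) -> pd.DataFrame:
    """Tabulate annotations for CSV export."""
    rows = []
    for a in annotations:
        rows.append(
            {
                "feature_id": a.feature_id,
                "parent": a.predicted.parent_formula.format(),
                "transformations": str(a.predicted.path),
                "composition_change": net_delta_str(a.predicted),
                "product_formula": a.predicted.product_formula.format(),
                "adduct": a.adduct,
                "ppm": a.ppm,
                "rt_group": a.rt_group,
                "ambiguous": a.ambiguous,
                "fish_coverage": a.fish_coverage,
                "passed_filter": a.passed_filter,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "parent", "transformations", "composition_change",
            "product_formula", "adduct", "ppm", "rt_group", "ambiguous",
            "fish_coverage", "passed_filter",
        ],
    )


def net_delta_str(pc: PredictedCompound) -> str:
    from .chemcore import net_delta

    return net_delta(pc.path).format_delta()
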