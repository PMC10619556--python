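"""End-to-end orchestration: predict -> annotate -> filter -> network ->
subnetwork annotation -> statistics (-> assay verdicts), with a resolved-
parameter manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import annotate as _annotate
from . import assay as _assay
from . import network as _network
from . import stats as _stats
from .chemcore import (
    PredictedCompound,
    Transformation,
    adduct_for_polarity,
    default_library,
    enumerate_biotransformants,
    expected_mz,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
)
from .msio import MsFeature, Ms2Spectrum, SampleDesign, impute_missing

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_report"]


@dataclass
class RunConfig:
    """All tolerances and thresholds of the workflow (defaults = the
    published acquisition/processing parameters)."""

    ms1_ppm: float = 5.0
    rt_tol: float = 0.1
    ms2_ppm: float = 10.0
    snr: float = 3.0
    frag_tol: float = 0.05
    min_cosine: float = 0.5
    min_matched: int = 6
    max_shift: float = 500.0
    top_k: int = 10
    min_area: float = 1e5
    min_fish: float = 50.0
    impute_fraction: float = 0.10
    alpha: float = 0.05
    rta_threshold: float = 10.0
    max_total: int = 5
    max_phase2: int = 1
    polarity: str = "pos"
    seed: int = 0
    stat_method: str = "auto"
    use_continuity: bool = True

    def manifest(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    config: RunConfig
    predictions: list[PredictedCompound]
    features: list[MsFeature]
    dropped_features: list[str]
    annotations: list
    filtered_annotations: list
    network: Optional[_network.MolecularNetwork]
    subnetwork: Optional[pd.DataFrame]
    stats: list
    volcano: pd.DataFrame
    volcano_counts: dict
    metabolic_rate: Optional[float]
    parent_feature_id: Optional[str]
    rta_results: list = field(default_factory=list)
    verdicts: Optional[pd.DataFrame] = None


def find_parent_feature(
    features: Sequence[MsFeature], parent_mz: float, ms1_ppm: float = 5.0
) -> Optional[str]:
    best = None
    for f in features:
        err = ppm_error(f.mz, parent_mz)
        if err <= ms1_ppm and (best is None or err < best[0]):
            best = (err, f.feature_id)
    return best[1] if best else None


def run_pipeline(
    features: Sequence[MsFeature],
    spectra: Sequence[Ms2Spectrum],
    parent_formula: str,
    design: SampleDesign,
    config: RunConfig | None = None,
    library: Sequence[Transformation] | None = None,
    plate: pd.DataFrame | None = None,
    parent_feature_id: str | None = None,
    predictions: Sequence[PredictedCompound] | None = None,
) -> PipelineResult:
    """Run the full screening workflow on one experiment."""
    config = config or RunConfig()
    library = default_library() if library is None else list(library)
    parent = parse_formula(parent_formula)
    adduct = adduct_for_polarity(config.polarity)

    if predictions is None:
        predictions = enumerate_biotransformants(
            parent, library, max_total=config.max_total, max_phase2=config.max_phase2
        )
    predictions = list(predictions)

    # attach MS2 spectra to features by id
    by_id = {s.feature_id: s for s in spectra}
    for f in features:
        if f.ms2 is None and f.feature_id in by_id:
            f.ms2 = by_id[f.feature_id]

    features, dropped = impute_missing(list(features), fraction=config.impute_fraction)

    parent_mz = expected_mz(monoisotopic_mass(parent), adduct)
    if parent_feature_id is None:
        parent_feature_id = find_parent_feature(features, parent_mz, config.ms1_ppm)

    annotations = _annotate.match_features(
        features, predictions, ms1_ppm=config.ms1_ppm, rt_tol=config.rt_tol,
        polarity=config.polarity,
    )
    # the parent's own feature is not a biotransformant annotation
    annotations = [a for a in annotations if a.feature_id != parent_feature_id]

    parent_ms2 = by_id.get(parent_feature_id) if parent_feature_id else None
    _annotate.score_annotations(
        annotations, features, parent_ms2, ms2_ppm=config.ms2_ppm, snr=config.snr
    )
    filtered = _annotate.filter_annotations(
        annotations, features, min_area=config.min_area, min_fish=config.min_fish
    )

    net = None
    subnetwork = None
    if len(spectra) >= 2:
        net = _network.build_network(
            list(spectra),
            min_cosine=config.min_cosine,
            min_matched=config.min_matched,
            max_shift=config.max_shift,
            top_k=config.top_k,
            frag_tol=config.frag_tol,
        )
        if parent_feature_id and parent_feature_id in net.graph:
            subnetwork = _network.annotate_subnetwork(
                net, parent_feature_id, predictions,
                ms1_ppm=config.ms1_ppm, polarity=config.polarity,
            )

    stat_features = [f for f in features]
    stats = _stats.feature_stats(
        stat_features, design, alpha=config.alpha,
        method=config.stat_method, use_continuity=config.use_continuity,
    )
    volcano, counts = _stats.volcano_table(stats, alpha=config.alpha)

    met_rate = None
    if parent_feature_id:
        parent_feat = next(f for f in features if f.feature_id == parent_feature_id)
        met_rate = _stats.metabolic_rate(parent_feat, design)

    if net is not None:
        meta = {
            s.feature_id: {"log2fc": s.log2fc, "p": s.p, "significant": s.significant}
            for s in stats
        }
        _network.attach_node_metadata(net, meta)

    rta_results: list = []
    verdicts = None
    if plate is not None:
        rta_results = _assay.rta(plate)
        verdicts = _assay.call_agonist(rta_results, threshold=config.rta_threshold)

    return PipelineResult(
        config=config,
        predictions=predictions,
        features=list(features),
        dropped_features=dropped,
        annotations=annotations,
        filtered_annotations=filtered,
        network=net,
        subnetwork=subnetwork,
        stats=stats,
        volcano=volcano,
        volcano_counts=counts,
        metabolic_rate=met_rate,
        parent_feature_id=parent_feature_id,
        rta_results=rta_results,
        verdicts=verdicts,
    )


def write_report(result: PipelineResult, out_dir) -> dict[str, Path]:
    """Write the report bundle (CSV/TSV/GraphML/JSON) deterministically."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ann_df = _annotate.annotations_frame(result.annotations)
    paths["annotations"] = out / "annotations.csv"
    ann_df.to_csv(paths["annotations"], index=False, float_format="%.6g")

    paths["stats"] = out / "feature_stats.csv"
    _stats.stats_frame(result.stats).to_csv(paths["stats"], index=False, float_format="%.6g")

    paths["volcano"] = out / "volcano.tsv"
    result.volcano.to_csv(paths["volcano"], sep="\t", index=False, float_format="%.6g")

    if result.network is not None:
        paths["graphml"] = out / "network.graphml"
        _network.write_graphml(result.network, paths["graphml"])
        paths["edges"] = out / "edges.tsv"
        _network.write_edge_list(result.network, paths["edges"])
    if result.subnetwork is not None:
        paths["subnetwork"] = out / "parent_subnetwork.csv"
        result.subnetwork.to_csv(paths["subnetwork"], index=False, float_format="%.6g")
    if result.verdicts is not None:
        paths["rta"] = out / "rta_results.csv"
        _assay.results_frame(result.rta_results).to_csv(
            paths["rta"], index=False, float_format="%.6g"
        )
        paths["verdicts"] = out / "verdicts.csv"
        result.verdicts.to_csv(paths["verdicts"], index=False, float_format="%.6g")

    summary = {
        "n_predictions": len(result.predictions),
        "n_features": len(result.features),
        "n_dropped_features": len(result.dropped_features),
        "n_annotations": len(result.annotations),
        "n_filtered_annotations": len(result.filtered_annotations),
        "parent_feature_id": result.parent_feature_id,
        "metabolic_rate_percent": result.metabolic_rate,
        "volcano_counts": result.volcano_counts,
        "n_network_edges": (
            result.network.graph.number_of_edges() if result.network else 0
        ),
        "n_components": (
            len(set(result.network.components.values())) if result.network else 0
        ),
        "manifest": result.config.manifest(),
    }
    paths["summary"] = out / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=1, sort_keys=True))
    return paths


def report_checksum(paths: dict[str, Path]) -> str:
    """SHA256 over the report files, for determinism checks."""
    h = hashlib.sha256()
    for key in sorted(paths):
        h.update(key.encode())
        h.update(paths[key].read_bytes())
    return h.hexdigest()
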