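"""Feature-based molecular networking.

Nodes are MS2-bearing features; edges connect spectrally similar pairs under
the modified cosine score, which allows fragment pairs offset by the
precursor mass difference, so a metabolite and its conjugate align on their
shared substructure fragments. Edge gates (cosine > 0.5, >= 6 matched ions,
|precursor shift| <= 500, mutual top-10 neighbors) follow standard FBMN
practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .chemcore import PredictedCompound, adduct_for_polarity, ppm_error
from .msio import Ms2Spectrum

__all__ = [
    "NetworkEdge",
    "MolecularNetwork",
    "modified_cosine",
    "build_network",
    "component_summary",
    "annotate_subnetwork",
    "write_graphml",
    "write_edge_list",
]


@dataclass(frozen=True)
class NetworkEdge:
    node_a: str
    node_b: str
    cosine: float
    matched_ions: int
    precursor_shift: float


@dataclass
class MolecularNetwork:
    graph: nx.Graph
    components: dict[str, int]

    @property
    def edges(self) -> list[NetworkEdge]:
        return [
            NetworkEdge(a, b, d["cosine"], d["matched_ions"], d["precursor_shift"])
            for a, b, d in self.graph.edges(data=True)
        ]

    def component_nodes(self, component_id: int) -> list[str]:
        return [n for n, c in self.components.items() if c == component_id]


def _weighted(spectrum: Ms2Spectrum) -> np.ndarray:
    """Square-root transformed, L2-normalized peak weights."""
    w = np.sqrt(spectrum.intensity)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def modified_cosine(
    a: Ms2Spectrum, b: Ms2Spectrum, frag_tol: float = 0.05
) -> tuple[float, int]:
    """Modified cosine similarity between two MS2 spectra.

    Peak pairs are eligible when their m/z values match directly within
    ``frag_tol`` or when they match after shifting by the precursor mass
    difference. A one-to-one matching is assembled greedily by descending
    pair score (product of sqrt-normalized intensities); the cosine is the
    sum of matched pair scores, in [0, 1].
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("spectra must be nonempty")
    wa, wb = _weighted(a), _weighted(b)
    shift = a.precursor_mz - b.precursor_mz
    pairs = []
    for i in range(a.n_peaks):
        for j in range(b.n_peaks):
            d = a.mz[i] - b.mz[j]
            if abs(d) <= frag_tol or abs(d - shift) <= frag_tol:
                pairs.append((wa[i] * wb[j], i, j))
    # stable deterministic order: best score first, then indices
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    score = 0.0
    matched = 0
    for s, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += s
        matched += 1
    return min(score, 1.0), matched


def build_network(
    spectra: Sequence[Ms2Spectrum],
    min_cosine: float = 0.5,
    min_matched: int = 6,
    max_shift: float = 500.0,
    top_k: int = 10,
    frag_tol: float = 0.05,
    mutual: bool = True,
) -> MolecularNetwork:
    """Construct the molecular network over a set of MS2 spectra.

    Candidate edges must exceed ``min_cosine`` (strict), carry at least
    ``min_matched`` matched fragment ions, and join precursors no more than
    ``max_shift`` apart. Top-K pruning then keeps an edge only if it ranks
    within each endpoint's ``top_k`` best edges by cosine (mutual semantics;
    set ``mutual=False`` for single-sided retention). All spectra appear as
    nodes; connected components are computed on the surviving edges.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra to build a network")
    ids = [s.feature_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate feature ids among spectra")

    order = sorted(range(len(spectra)), key=lambda i: ids[i])
    candidates: list[NetworkEdge] = []
    for x in range(len(order)):
        for y in range(x + 1, len(order)):
            sa, sb = spectra[order[x]], spectra[order[y]]
            dshift = sa.precursor_mz - sb.precursor_mz
            if abs(dshift) > max_shift:
                continue
            cos, n = modified_cosine(sa, sb, frag_tol=frag_tol)
            if cos > min_cosine and n >= min_matched:
                candidates.append(NetworkEdge(sa.feature_id, sb.feature_id, cos, n, dshift))

    # rank each node's candidate edges by cosine (ties: lexicographic partner)
    ranks: dict[tuple[str, str], int] = {}
    per_node: dict[str, list[NetworkEdge]] = {}
    for e in candidates:
        per_node.setdefault(e.node_a, []).append(e)
        per_node.setdefault(e.node_b, []).append(e)
    for node, edges in per_node.items():
        edges.sort(key=lambda e: (-e.cosine, e.node_a if e.node_a != node else e.node_b))
        for r, e in enumerate(edges):
            ranks[(node, _other(e, node))] = r

    surviving = []
    for e in candidates:
        ra = ranks[(e.node_a, e.node_b)]
        rb = ranks[(e.node_b, e.node_a)]
        ok = (ra < top_k and rb < top_k) if mutual else (ra < top_k or rb < top_k)
        if ok:
            surviving.append(e)

    g = nx.Graph()
    for s in spectra:
        g.add_node(s.feature_id, precursor_mz=float(s.precursor_mz), charge=int(s.charge))
    for e in surviving:
        g.add_edge(
            e.node_a,
            e.node_b,
            cosine=float(e.cosine),
            matched_ions=int(e.matched_ions),
            precursor_shift=float(e.precursor_shift),
        )
    components: dict[str, int] = {}
    for cid, nodes in enumerate(
        sorted(nx.connected_components(g), key=lambda ns: (-len(ns), min(ns)))
    ):
        for n in nodes:
            components[n] = cid
    return MolecularNetwork(graph=g, components=components)


def _other(edge: NetworkEdge, node: str) -> str:
    return edge.node_b if edge.node_a == node else edge.node_a


def component_summary(net: MolecularNetwork, min_size: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-component node counts, annotated-node counts and mean log2 FC.

    Returns ``(full, headline)`` where the headline table keeps components
    with more than ``min_size`` nodes (the reporting rule for cluster
    tables). Annotation and fold-change node attributes, where present, feed
    the respective columns.
    """
    rows = []
    for cid in sorted(set(net.components.values())):
        nodes = net.component_nodes(cid)
        annotated = sum(1 for n in nodes if net.graph.nodes[n].get("annotation"))
        fcs = [
            net.graph.nodes[n]["log2fc"]
            for n in nodes
            if net.graph.nodes[n].get("log2fc") is not None
        ]
        rows.append(
            {
                "component": cid,
                "n_nodes": len(nodes),
                "n_annotated": annotated,
                "mean_log2fc": float(np.mean(fcs)) if fcs else float("nan"),
            }
        )
    full = pd.DataFrame(rows, columns=["component", "n_nodes", "n_annotated", "mean_log2fc"])
    headline = full[full["n_nodes"] > min_size].reset_index(drop=True)
    return full, headline


def annotate_subnetwork(
    net: MolecularNetwork,
    parent_feature_id: str,
    predictions: Sequence[PredictedCompound],
    ms1_ppm: float = 5.0,
    polarity: str = "pos",
) -> pd.DataFrame:
    """Annotate the parent-containing component by precursor m/z difference.

    Each node in the parent's component is tested against the predicted
    adduct masses at the MS1 tolerance; matches are tagged with the reaction
    path, the parent with "parent", and the rest as candidate novel
    biotransformants with their m/z offset from the parent. Tags are written
    onto the graph nodes and returned as a table.
    """
    if parent_feature_id not in net.graph:
        raise KeyError(f"parent feature {parent_feature_id!r} not in network")
    adduct = adduct_for_polarity(polarity)
    cid = net.components[parent_feature_id]
    parent_mz = net.graph.nodes[parent_feature_id]["precursor_mz"]
    rows = []
    for node in sorted(net.component_nodes(cid)):
        mz = net.graph.nodes[node]["precursor_mz"]
        if node == parent_feature_id:
            tag, detail = "parent", ""
        else:
            tag, detail = "candidate-novel", f"dmz={mz - parent_mz:+.4f}"
            best = None
            for pc in predictions:
                err = ppm_error(mz, pc.expected_mz(adduct))
                if err <= ms1_ppm and (best is None or err < best[0]):
                    best = (err, pc)
            if best is not None:
                tag, detail = "predicted", str(best[1].path)
        net.graph.nodes[node]["annotation"] = detail if tag == "predicted" else tag
        net.graph.nodes[node]["subnetwork_tag"] = tag
        rows.append(
            {
                "feature_id": node,
                "component": cid,
                "precursor_mz": mz,
                "dmz_from_parent": mz - parent_mz,
                "tag": tag,
                "detail": detail,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "component", "precursor_mz", "dmz_from_parent", "tag", "detail"],
    )


def attach_node_metadata(net: MolecularNetwork, metadata: Mapping[str, Mapping[str, object]]) -> None:
    """Attach per-node attributes (fold change, p-value, chemical class, ...).

    Chemical-class labels are accepted as externally supplied metadata (e.g.
    a CSV exported from a class-annotation workflow); they are never computed
    here.
    """
    for node, attrs in metadata.items():
        if node in net.graph:
            for k, v in attrs.items():
                net.graph.nodes[node][k] = v


def write_graphml(net: MolecularNetwork, path) -> None:
    g = net.graph.copy()
    for n, c in net.components.items():
        g.nodes[n]["component"] = int(c)
    # GraphML cannot carry None values
    for _, attrs in g.nodes(data=True):
        for k in [k for k, v in attrs.items() if v is None]:
            del attrs[k]
    nx.write_graphml(g, str(path))


def write_edge_list(net: MolecularNetwork, path) -> None:
    rows = [
        {
            "node_a": e.node_a,
            "node_b": e.node_b,
            "cosine": e.cosine,
            "matched_ions": e.matched_ions,
            "precursor_shift": e.precursor_shift,
        }
        for e in sorted(net.edges, key=lambda e: (e.node_a, e.node_b))
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "cosine", "matched_ions", "precursor_shift"]).to_csv(
        path, sep="\t", index=False
    )
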