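"""Modified-cosine similarity and molecular-network construction."""

import itertools

import numpy as np
import pytest

from biotransnet.chemcore import (
    ReactionPath,
    PredictedCompound,
    delta_mass,
    monoisotopic_mass,
    net_delta,
    parse_formula,
)
from biotransnet.msio import Ms2Spectrum
from biotransnet.network import (
    annotate_subnetwork,
    build_network,
    component_summary,
    modified_cosine,
)


def random_spectrum(rng, fid, n_peaks=None, mz_range=(100.0, 900.0)):
    n = n_peaks or int(rng.integers(3, 7))
    mz = np.sort(rng.uniform(*mz_range, size=n))
    inten = 10 ** rng.uniform(3, 6, size=n)
    prec = float(rng.uniform(200, 1000))
    return Ms2Spectrum(fid, prec, mz=mz, intensity=inten)


def oracle_modified_cosine(a, b, frag_tol=0.05):
    """Exhaustive optimal one-to-one matching over all eligible peak pairs."""
    wa = np.sqrt(a.intensity); wa /= np.linalg.norm(wa)
    wb = np.sqrt(b.intensity); wb /= np.linalg.norm(wb)
    shift = a.precursor_mz - b.precursor_mz
    pairs = [
        (wa[i] * wb[j], i, j)
        for i in range(a.n_peaks)
        for j in range(b.n_peaks)
        if abs(a.mz[i] - b.mz[j]) <= frag_tol
        or abs((a.mz[i] - b.mz[j]) - shift) <= frag_tol
    ]

    best = 0.0
    def search(idx, used_a, used_b, acc):
        nonlocal best
        best = max(best, acc)
        for k in range(idx, len(pairs)):
            s, i, j = pairs[k]
            if i not in used_a and j not in used_b:
                search(k + 1, used_a | {i}, used_b | {j}, acc + s)

    search(0, frozenset(), frozenset(), 0.0)
    return min(best, 1.0)


def test_self_cosine_is_one(rng):
    for _ in range(5):
        s = random_spectrum(rng, "s", n_peaks=8)
        cos, n = modified_cosine(s, s)
        assert cos == pytest.approx(1.0, abs=1e-12)
        assert n == s.n_peaks


def test_disjoint_peaks_zero(spectrum_factory):
    a = spectrum_factory("a", 500.0, [(100.0, 1.0), (200.0, 1.0)])
    b = spectrum_factory("b", 500.0, [(150.0, 1.0), (250.0, 1.0)])
    cos, n = modified_cosine(a, b)
    assert cos == 0.0 and n == 0


def test_precursor_shifted_fragments_match(spectrum_factory):
    # fragments offset exactly by the precursor difference still align
    a = spectrum_factory("a", 500.0, [(100.0, 5.0), (200.0, 3.0), (300.0, 2.0)])
    b = spectrum_factory("b", 676.0, [(276.0, 5.0), (376.0, 3.0), (476.0, 2.0)])
    cos, n = modified_cosine(a, b)
    assert cos == pytest.approx(1.0, abs=1e-9)
    assert n == 3


def test_symmetry_and_scale_invariance(rng):
    for _ in range(20):
        a = random_spectrum(rng, "a")
        b = random_spectrum(rng, "b")
        ca, na = modified_cosine(a, b)
        cb, nb = modified_cosine(b, a)
        assert ca == pytest.approx(cb, abs=1e-12)
        assert na == nb
        scaled = Ms2Spectrum("a", a.precursor_mz, mz=a.mz, intensity=a.intensity * 37.5)
        cs, ns = modified_cosine(scaled, b)
        assert cs == pytest.approx(ca, abs=1e-12) and ns == na


def test_greedy_matches_exhaustive_oracle(rng):
    """On small spectra the greedy one-to-one matching attains the optimal
    total matched score (verified against complete enumeration)."""
    for _ in range(300):
        a = random_spectrum(rng, "a")
        b = random_spectrum(rng, "b")
        cos, _ = modified_cosine(a, b)
        assert cos == pytest.approx(oracle_modified_cosine(a, b), abs=1e-9)


# ---------------------------------------------------------------------------
# network construction


def _clone(spec, fid, rng=None, precursor=None):
    inten = spec.intensity.copy()
    if rng is not None:
        inten = inten * rng.uniform(0.9, 1.1, size=inten.size)
    return Ms2Spectrum(fid, precursor or spec.precursor_mz, mz=spec.mz.copy(),
                       intensity=inten)


def test_three_identical_spectra_form_triangle(rng):
    base = random_spectrum(rng, "x", n_peaks=8)
    spectra = [_clone(base, f"n{i}") for i in range(3)]
    net = build_network(spectra)
    assert net.graph.number_of_edges() == 3
    assert len(set(net.components.values())) == 1


def test_max_precursor_shift_blocks_edge(rng):
    base = random_spectrum(rng, "x", n_peaks=8, mz_range=(100, 300))
    a = _clone(base, "a", precursor=400.0)
    b = _clone(base, "b", precursor=1000.1)  # shift 600.1 > 500
    net = build_network([a, b])
    assert net.graph.number_of_edges() == 0


def test_star_center_keeps_at_most_top_k_neighbors(rng):
    """A hub with 12 near-identical neighbors retains exactly 10 edges."""
    base = random_spectrum(rng, "x", n_peaks=9, mz_range=(100, 350))
    center = _clone(base, "center")
    # neighbors share all fragments with the center but are pairwise distinct
    # enough in intensity to produce a strict cosine ordering
    neighbors = []
    for i in range(12):
        inten = base.intensity * (1 + 0.04 * (i + 1) * np.linspace(-1, 1, base.n_peaks))
        neighbors.append(Ms2Spectrum(f"n{i:02d}", base.precursor_mz, mz=base.mz.copy(),
                                     intensity=inten))
    net = build_network([center] + neighbors, top_k=10)
    assert net.graph.degree("center") <= 10
    for node in net.graph.nodes:
        assert net.graph.degree(node) <= 10


def test_edge_constraints_never_violated(rng):
    for trial in range(5):
        spectra = [random_spectrum(rng, f"s{trial}_{i}", n_peaks=int(rng.integers(6, 12)))
                   for i in range(15)]
        net = build_network(spectra)
        for e in net.edges:
            assert e.cosine > 0.5
            assert e.matched_ions >= 6
            assert abs(e.precursor_shift) <= 500


def test_build_network_determinism(rng):
    spectra = [random_spectrum(rng, f"s{i}", n_peaks=8) for i in range(10)]
    n1 = build_network(spectra)
    n2 = build_network(list(reversed(spectra)))
    assert set(map(frozenset, ((e.node_a, e.node_b) for e in n1.edges))) == set(
        map(frozenset, ((e.node_a, e.node_b) for e in n2.edges))
    )
    assert n1.components == n2.components


# ---------------------------------------------------------------------------
# component summary & subnetwork annotation


def _transformant_family(rng, library_by_name, names_list, parent_text="C15 H12 I3 N O4"):
    """One parent spectrum + one shifted spectrum per reaction path."""
    parent = parse_formula(parent_text)
    parent_mz = monoisotopic_mass(parent) + 1.007276466879
    base = random_spectrum(rng, "parent", n_peaks=9, mz_range=(150, 500))
    base = Ms2Spectrum("parent", parent_mz, mz=base.mz, intensity=base.intensity)
    spectra = [base]
    preds = []
    for k, names in enumerate(names_list):
        path = ReactionPath(tuple(library_by_name[n] for n in names))
        delta = net_delta(path)
        product = parent + delta
        pc = PredictedCompound(parent, path, product, monoisotopic_mass(product))
        preds.append(pc)
        shift = delta_mass(delta)
        spectra.append(
            Ms2Spectrum(f"t{k}", parent_mz + shift, mz=base.mz + shift,
                        intensity=base.intensity * rng.uniform(0.9, 1.1, base.n_peaks))
        )
    return spectra, preds


def test_component_summary_tables(rng, library_by_name):
    spectra, _ = _transformant_family(
        rng, library_by_name,
        [("Glucuronide Conjugation",), ("Sulfation",), ("Oxidation",)],
    )
    # add an unrelated pair forming its own component
    extra = random_spectrum(rng, "e0", n_peaks=8, mz_range=(100, 400))
    spectra += [extra, _clone(extra, "e1")]
    net = build_network(spectra)
    full, headline = component_summary(net, min_size=3)
    assert set(full["n_nodes"]) == {4, 2}
    assert len(headline) == 1 and headline.iloc[0]["n_nodes"] == 4


def test_component_summary_empty_headline(rng):
    a = random_spectrum(rng, "a", n_peaks=7)
    b = random_spectrum(rng, "b", n_peaks=7, mz_range=(400, 800))
    net = build_network([a, b])
    full, headline = component_summary(net, min_size=10)
    assert len(headline) == 0
    assert len(full) == len(set(net.components.values()))


def test_annotate_subnetwork_tags(rng, library_by_name):
    spectra, preds = _transformant_family(
        rng, library_by_name,
        [("Glucuronide Conjugation",), ("Deiodination",)],
    )
    net = build_network(spectra)
    table = annotate_subnetwork(net, "parent", preds, polarity="pos")
    tags = dict(zip(table["feature_id"], table["tag"]))
    assert tags["parent"] == "parent"
    assert tags["t0"] == "predicted" and tags["t1"] == "predicted"
    details = dict(zip(table["feature_id"], table["detail"]))
    assert "Glucuronide Conjugation" in details["t0"]
    parent_row = table[table["feature_id"] == "parent"].iloc[0]
    assert parent_row["dmz_from_parent"] == pytest.approx(0.0)


def test_annotate_subnetwork_candidate_novel(rng, library_by_name):
    spectra, preds = _transformant_family(rng, library_by_name, [("Sulfation",)])
    # an extra node connected to the parent but matching no prediction
    base = spectra[0]
    odd = Ms2Spectrum("novel", base.precursor_mz + 17.5, mz=base.mz + 17.5,
                      intensity=base.intensity.copy())
    net = build_network(spectra + [odd])
    table = annotate_subnetwork(net, "parent", preds)
    row = table[table["feature_id"] == "novel"].iloc[0]
    assert row["tag"] == "candidate-novel"
    assert row["dmz_from_parent"] == pytest.approx(17.5, abs=1e-6)


def test_annotate_subnetwork_missing_parent(rng):
    net = build_network([random_spectrum(rng, "a", n_peaks=7),
                         random_spectrum(rng, "b", n_peaks=7)])
    with pytest.raises(KeyError):
        annotate_subnetwork(net, "ghost", [])


def test_transformants_cluster_with_parent_decoys_do_not(rng, library_by_name):
    spectra, _ = _transformant_family(
        rng, library_by_name,
        [("Glucuronide Conjugation",), ("Sulfation",), ("Deiodination",),
         ("Oxidation",), ("Deiodination", "Sulfation")],
    )
    decoys = [random_spectrum(rng, f"d{i}", n_peaks=int(rng.integers(7, 11)))
              for i in range(15)]
    net = build_network(spectra + decoys)
    parent_comp = net.components["parent"]
    members = set(net.component_nodes(parent_comp))
    assert {s.feature_id for s in spectra} <= members
    assert not any(d.feature_id in members for d in decoys)


def test_modified_cosine_against_independent_library(rng):
    """Cross-check against matchms's ModifiedCosine on random spectra
    (sqrt weighting applied by passing root intensities)."""
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import ModifiedCosine

    sim = ModifiedCosine(tolerance=0.05)
    for _ in range(25):
        a = random_spectrum(rng, "a", n_peaks=int(rng.integers(4, 9)))
        b = random_spectrum(rng, "b", n_peaks=int(rng.integers(4, 9)))
        ma = matchms.Spectrum(mz=a.mz, intensities=np.sqrt(a.intensity),
                              metadata={"precursor_mz": a.precursor_mz})
        mb = matchms.Spectrum(mz=b.mz, intensities=np.sqrt(b.intensity),
                              metadata={"precursor_mz": b.precursor_mz})
        ref = sim.pair(ma, mb)
        cos, n = modified_cosine(a, b)
        assert cos == pytest.approx(float(ref["score"]), abs=1e-6)
        assert n == int(ref["matches"])
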