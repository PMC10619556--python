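"""Elemental-composition algebra and combinatorial biotransformant prediction.

Predicted metabolites ("biotransformants") of a parent compound are generated
at the formula level: each hepatic phase I/II reaction is a signed elemental
delta (e.g. glucuronide conjugation adds C6H8O6), and a candidate product is
the parent formula plus the element-wise sum of an unordered multiset of
reaction deltas, bounded in depth (default: at most 5 reactions in total, at
most 1 phase II conjugation). Mass-based LC-MS matching cannot distinguish the
order in which reactions occurred, so paths are treated as multisets and one
canonical representative path is kept per distinct product formula.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ElementalComposition",
    "Phase",
    "Transformation",
    "ReactionPath",
    "PredictedCompound",
    "FormulaError",
    "parse_formula",
    "parse_delta",
    "monoisotopic_mass",
    "delta_mass",
    "net_delta",
    "default_library",
    "load_library",
    "save_library",
    "enumerate_biotransformants",
    "expected_mz",
    "ppm_error",
    "PROTON_MASS",
    "ISOTOPE_MASS",
]

# Monoisotopic masses of the most abundant isotope (IUPAC/CIAAW 2021, Da).
ISOTOPE_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984031627,
    "Na": 22.9897692820,
    "Si": 27.9769265347,
    "P": 30.9737615120,
    "S": 31.9720706912,
    "Cl": 34.9688527100,
    "K": 38.9637064864,
    "Se": 79.9165218,
    "Br": 78.9183376,
    "I": 126.9044719,
}

#: Mass of a proton, Da (charge carrier for [M+H]+ / [M-H]-).
PROTON_MASS = 1.007276466879


class FormulaError(ValueError):
    """Raised for malformed or unknown-element formula strings."""


_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalComposition:
    """A signed element -> count map with composition arithmetic.

    Supports addition, subtraction and integer scaling; zero counts are
    normalized away so that equal compositions compare and hash equal.
    Negative counts are legal (reaction deltas are signed); they are only
    rejected when a monoisotopic mass of a real molecule is requested.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for elem, n in (counts or {}).items():
            if elem not in ISOTOPE_MASS:
                raise FormulaError(f"unknown element symbol: {elem!r}")
            n = int(n)
            if n != 0:
                clean[elem] = n
        self._counts = clean

    @property
    def counts(self) -> dict[str, int]:
        return dict(self._counts)

    def __getitem__(self, elem: str) -> int:
        return self._counts.get(elem, 0)

    def __iter__(self):
        return iter(self._counts.items())

    def __len__(self) -> int:
        return len(self._counts)

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self._counts)
        for elem, n in other._counts.items():
            merged[elem] = merged.get(elem, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self._counts)
        for elem, n in other._counts.items():
            merged[elem] = merged.get(elem, 0) - n
        return ElementalComposition(merged)

    def __mul__(self, k: int) -> "ElementalComposition":
        return ElementalComposition({e: n * k for e, n in self._counts.items()})

    __rmul__ = __mul__

    def __neg__(self) -> "ElementalComposition":
        return self * -1

    def __eq__(self, other) -> bool:
        if not isinstance(other, ElementalComposition):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def is_nonnegative(self) -> bool:
        return all(n >= 0 for n in self._counts.values())

    def _sorted_items(self):
        # Hill order: C first, H second, then alphabetical.
        def key(item):
            elem = item[0]
            return {"C": (0,), "H": (1,)}.get(elem, (2, elem))

        return sorted(self._counts.items(), key=key)

    def format(self, compact: bool = False) -> str:
        """Format a non-negative composition, e.g. ``"C6 H8 O6"``."""
        sep = "" if compact else " "
        parts = []
        for elem, n in self._sorted_items():
            if n < 0:
                raise FormulaError(
                    "cannot format signed composition as a plain formula; "
                    "use format_delta()"
                )
            parts.append(elem if n == 1 else f"{elem}{n}")
        return sep.join(parts)

    def format_delta(self) -> str:
        """Format as a signed delta in the ``-(H2 Cl2) +(O5 S)`` dialect."""
        neg = ElementalComposition({e: -n for e, n in self._counts.items() if n < 0})
        pos = ElementalComposition({e: n for e, n in self._counts.items() if n > 0})
        parts = []
        if neg:
            parts.append(f"-({neg.format()})")
        if pos:
            parts.append(f"+({pos.format()})")
        return " ".join(parts) if parts else "+()"

    def __repr__(self) -> str:
        inner = ", ".join(f"{e}:{n}" for e, n in self._sorted_items())
        return f"ElementalComposition({{{inner}}})"


def parse_formula(text: str) -> ElementalComposition:
    """Parse a molecular-formula string into an :class:`ElementalComposition`.

    Both the spaced dialect (``"C6 H8 O6"``) and the compact one
    (``"C6H8O6"``) are accepted; markdown-style subscript underscores
    (``"Cl_2_"``) are tolerated. An omitted count means 1. The empty string
    parses to the empty composition.
    """
    cleaned = text.replace("_", "").strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        if cleaned[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(cleaned, pos)
        if not m or not m.group(1):
            raise FormulaError(
                f"malformed formula near {cleaned[pos:pos + 8]!r} "
                f"(offset {pos} in {text!r})"
            )
        elem, digits = m.group(1), m.group(2)
        if elem not in ISOTOPE_MASS:
            raise FormulaError(f"unknown element symbol {elem!r} in {text!r}")
        counts[elem] = counts.get(elem, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalComposition(counts)


_DELTA_GROUP_RE = re.compile(r"([+-])\s*\(([^)]*)\)")


def parse_delta(text: str) -> ElementalComposition:
    """Parse a signed composition change such as ``"-(H2 Cl2) +(O5 S)"``.

    Bare signed formulas (``"+O"``, ``"-H2"``, ``"+H -I"``) are also
    accepted. Unsigned input is parsed as a plain (positive) formula.
    """
    text = text.strip()
    if not text:
        return ElementalComposition()
    if "(" in text:
        total = ElementalComposition()
        consumed = 0
        for m in _DELTA_GROUP_RE.finditer(text):
            part = parse_formula(m.group(2))
            total = total + part if m.group(1) == "+" else total - part
            consumed += len(m.group(0))
        if not _DELTA_GROUP_RE.search(text):
            raise FormulaError(f"no signed groups found in delta {text!r}")
        return total
    if text[0] in "+-":
        total = ElementalComposition()
        for token in re.findall(r"[+-]\s*[A-Za-z0-9_ ]+?(?=\s*[+-]|$)", text):
            sign, body = token[0], token[1:]
            part = parse_formula(body)
            total = total + part if sign == "+" else total - part
        return total
    return parse_formula(text)


def monoisotopic_mass(comp: ElementalComposition | Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of a non-negative composition.

    Signed deltas must not be massed directly without a parent; use
    :func:`delta_mass` for the (possibly negative) mass shift of a delta.
    """
    if not isinstance(comp, ElementalComposition):
        comp = ElementalComposition(comp)
    if not comp.is_nonnegative():
        raise ValueError(
            "composition has negative counts; monoisotopic_mass is defined "
            "only for real molecules"
        )
    return sum(n * ISOTOPE_MASS[e] for e, n in comp)


def delta_mass(comp: ElementalComposition) -> float:
    """Signed mass shift (Da) of a composition delta."""
    return sum(n * ISOTOPE_MASS[e] for e, n in comp)


class Phase(str, Enum):
    phase1 = "phase1"
    phase2 = "phase2"


@dataclass(frozen=True)
class Transformation:
    """A named hepatic reaction as a signed composition delta."""

    name: str
    phase: Phase
    delta: ElementalComposition

    def __post_init__(self):
        if not self.delta:
            raise ValueError(f"transformation {self.name!r} has a zero delta")

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class ReactionPath:
    """An ordered sequence of transformations applied to a parent."""

    steps: tuple[Transformation, ...]

    def __post_init__(self):
        object.__setattr__(self, "steps", tuple(self.steps))

    @property
    def depth(self) -> int:
        return len(self.steps)

    @property
    def n_phase2(self) -> int:
        return sum(1 for s in self.steps if s.phase is Phase.phase2)

    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.steps)

    def __str__(self) -> str:
        return ", ".join(self.names())


def net_delta(path: ReactionPath | Iterable[Transformation]) -> ElementalComposition:
    """Element-wise sum of the step deltas; invariant to step order."""
    steps = path.steps if isinstance(path, ReactionPath) else tuple(path)
    if not steps:
        raise ValueError("reaction path is empty")
    total = ElementalComposition()
    for step in steps:
        total = total + step.delta
    return total


@dataclass(frozen=True)
class PredictedCompound:
    """A formula-level predicted biotransformant of a parent compound."""

    parent_formula: ElementalComposition
    path: ReactionPath
    product_formula: ElementalComposition
    neutral_mass: float
    name: str = ""

    def expected_mz(self, adduct: str) -> float:
        return expected_mz(self.neutral_mass, adduct)


# (name, phase, delta) triplets for the shipped reaction library. Phase I
# covers functionalization (redox, hydration, dealkylation, dehalogenation);
# phase II covers conjugations. Deiodination and the other dehalogenations
# apply only when the (intermediate) product still holds that halogen — the
# negative-count pruning in enumerate_biotransformants enforces this.
_DEFAULT_LIBRARY_SPEC: list[tuple[str, str, str]] = [
    ("Oxidation", "phase1", "+(O)"),
    ("Reduction", "phase1", "+(H2)"),
    ("Desaturation", "phase1", "-(H2)"),
    ("Hydration", "phase1", "+(H2 O)"),
    ("Dehydration", "phase1", "-(H2 O)"),
    ("Methylation", "phase1", "+(C H2)"),
    ("Demethylation", "phase1", "-(C H2)"),
    ("Deethylation", "phase1", "-(C2 H4)"),
    ("Acetylation", "phase1", "+(C2 H2 O)"),
    ("Decarboxylation", "phase1", "-(C O2)"),
    ("Ring Open", "phase1", "+(H2 O)"),
    ("Hydrolysis", "phase1", "+(H2 O)"),
    ("Nitro Reduction", "phase1", "-(O2) +(H2)"),
    ("Deiodination", "phase1", "-(I) +(H)"),
    ("Reductive Dechlorination", "phase1", "-(Cl) +(H)"),
    ("Oxidative Dechlorination", "phase1", "-(Cl) +(H O)"),
    ("Oxidative Debromination", "phase1", "-(Br) +(H O)"),
    ("Oxidative Deamination to Alcohol", "phase1", "-(H N) +(O)"),
    ("Oxidative Deamination to Ketone", "phase1", "-(H3 N) +(O)"),
    ("Glucuronide Conjugation", "phase2", "+(C6 H8 O6)"),
    ("Sulfation", "phase2", "+(O3 S)"),
    ("GSH Conjugation", "phase2", "+(C10 H15 N3 O6 S)"),
    ("Glucoside Conjugation", "phase2", "+(C6 H10 O5)"),
    ("Taurine Conjugation", "phase2", "+(C2 H5 N O2 S)"),
    ("Glutamine Conjugation", "phase2", "+(C5 H8 N2 O2)"),
    ("Arginine Conjugation", "phase2", "+(C6 H12 N4 O)"),
    ("Palmitoyl Conjugation", "phase2", "+(C16 H30 O)"),
    ("Stearyl Conjugation", "phase2", "+(C18 H34 O)"),
]


def default_library() -> list[Transformation]:
    """The shipped phase I/II reaction library."""
    return [
        Transformation(name, Phase(phase), parse_delta(delta))
        for name, phase, delta in _DEFAULT_LIBRARY_SPEC
    ]


def load_library(path) -> list[Transformation]:
    """Load a reaction library from a YAML/JSON file.

    Expected format: a list of ``{name, phase, delta}`` mappings where
    ``delta`` is a signed composition-change string.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"reaction library {path} must be a list of mappings")
    lib = []
    seen: set[str] = set()
    for entry in raw:
        name = entry["name"]
        if name in seen:
            raise ValueError(f"duplicate transformation name {name!r} in {path}")
        seen.add(name)
        lib.append(Transformation(name, Phase(entry["phase"]), parse_delta(entry["delta"])))
    return lib


def save_library(library: Iterable[Transformation], path) -> None:
    rows = [
        {"name": t.name, "phase": t.phase.value, "delta": t.delta.format_delta()}
        for t in library
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(rows, fh, sort_keys=False)


def enumerate_biotransformants(
    parent: ElementalComposition,
    library: Iterable[Transformation] | None = None,
    max_total: int = 5,
    max_phase2: int = 1,
    parent_name: str = "parent",
) -> list[PredictedCompound]:
    """Enumerate all distinct predicted products of ``parent``.

    Every unordered multiset of at most ``max_total`` transformations with at
    most ``max_phase2`` phase II steps is applied; products with any negative
    element count are pruned (a dehalogenation cannot fire without the
    halogen), and duplicates on product formula are collapsed to one
    representative path (shallowest, then lexicographically first by step
    names). Output is sorted by product mass, then by path names.
    """
    if max_total < 1:
        raise ValueError("max_total must be >= 1")
    if max_phase2 < 0:
        raise ValueError("max_phase2 must be >= 0")
    if not parent.is_nonnegative():
        raise ValueError("parent formula must have non-negative counts")
    library = default_library() if library is None else list(library)
    if not library:
        return []

    phase1 = sorted((t for t in library if t.phase is Phase.phase1), key=lambda t: t.name)
    phase2 = sorted((t for t in library if t.phase is Phase.phase2), key=lambda t: t.name)

    best: dict[ElementalComposition, tuple] = {}

    def consider(steps: tuple[Transformation, ...]):
        product = parent + net_delta(steps)
        if not product.is_nonnegative() or not product:
            return
        ordered = tuple(sorted(steps, key=lambda t: t.name))
        key = (len(ordered), tuple(t.name for t in ordered))
        prev = best.get(product)
        if prev is None or key < prev[0]:
            best[product] = (key, ordered)

    for n2 in range(0, min(max_phase2, max_total) + 1):
        for conj in itertools.combinations_with_replacement(phase2, n2):
            for n1 in range(0, max_total - n2 + 1):
                if n1 + n2 == 0:
                    continue
                for funcs in itertools.combinations_with_replacement(phase1, n1):
                    consider(conj + funcs)

    out = []
    for product, (_, steps) in best.items():
        path = ReactionPath(steps)
        out.append(
            PredictedCompound(
                parent_formula=parent,
                path=path,
                product_formula=product,
                neutral_mass=monoisotopic_mass(product),
                name=f"{parent_name} [{path}]",
            )
        )
    out.sort(key=lambda pc: (pc.neutral_mass, pc.path.names()))
    return out


_ADDUCTS = {"M+H": +1.0, "M-H": -1.0, "[M+H]+": +1.0, "[M-H]-": -1.0}


def expected_mz(neutral_mass: float, adduct: str) -> float:
    """Singly-charged adduct m/z: M+H adds a proton mass, M-H removes one."""
    key = adduct.replace("−", "-")
    if key not in _ADDUCTS:
        raise ValueError(f"unsupported adduct {adduct!r}; use 'M+H' or 'M-H'")
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be > 0")
    return neutral_mass + _ADDUCTS[key] * PROTON_MASS


def adduct_for_polarity(polarity: str) -> str:
    if polarity == "pos":
        return "M+H"
    if polarity == "neg":
        return "M-H"
    raise ValueError(f"unknown polarity {polarity!r}")


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be > 0")
    return 1e6 * abs(observed - theoretical) / theoretical
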