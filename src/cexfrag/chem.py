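"""Molecular formulas, masses/m-z, the cystine topology, and fragments.

The unit of account is the :class:`Composition` — an element→count map plus a
charge.  Fragment identification is purely graph-theoretic: remove a set of
broken bonds from the molecular graph and read off connected components.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import networkx as nx

from .elements import DEFAULT_ELEMENTS, ElementTable

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_CHARGE_TOKEN = re.compile(r"([+-])(\d*)$")


@dataclass(frozen=True)
class Composition:
    """Elemental composition with an integer charge (elementary charges)."""

    counts: tuple  # sorted tuple of (element, count) pairs — hashable
    charge: int = 0

    @classmethod
    def from_dict(cls, counts: dict, charge: int = 0) -> "Composition":
        if not counts:
            raise ValueError("empty composition")
        for el, n in counts.items():
            if el not in DEFAULT_ELEMENTS.monoisotopic:
                raise ValueError(f"unknown element {el!r}")
            if not isinstance(n, int) or n <= 0:
                raise ValueError(f"count for {el} must be a positive integer")
        return cls(tuple(sorted(counts.items())), charge)

    def as_dict(self) -> dict:
        return dict(self.counts)

    def with_charge(self, charge: int) -> "Composition":
        return replace(self, charge=charge)

    def __add__(self, other: "Composition") -> "Composition":
        merged = self.as_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) + n
        return Composition.from_dict(merged, self.charge + other.charge)

    def formula(self) -> str:
        """Hill-style string (C, H, then alphabetical) for display."""
        d = self.as_dict()
        order = [e for e in ("C", "H") if e in d] + sorted(
            e for e in d if e not in ("C", "H")
        )
        return "".join(f"{e}{d[e] if d[e] > 1 else ''}" for e in order)


def parse_formula(text: str, elements: ElementTable = DEFAULT_ELEMENTS) -> Composition:
    """Parse a molecular formula such as ``"C2SNH4"`` or ``"COOH+"``.

    The grammar is order-preserving with no parentheses; repeated element
    symbols accumulate (``"COOH"`` → C1 O2 H1).  An optional trailing ``+``/
    ``-`` token (optionally followed by a magnitude, e.g. ``"2+"`` style is
    written ``"+2"``) sets the charge.
    """
    if not text or not text.strip():
        raise ValueError("empty formula")
    body = text.strip()
    charge = 0
    m = _CHARGE_TOKEN.search(body)
    if m:
        sign = 1 if m.group(1) == "+" else -1
        charge = sign * (int(m.group(2)) if m.group(2) else 1)
        body = body[: m.start()]
    counts: dict = {}
    pos = 0
    while pos < len(body):
        m = _FORMULA_TOKEN.match(body, pos)
        if not m or not m.group(1):
            raise ValueError(f"cannot parse formula at {body[pos:]!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in elements.monoisotopic:
            raise ValueError(f"unknown element {sym!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise ValueError(f"zero count for {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return Composition.from_dict(counts, charge)


def mass(
    comp: Composition,
    scale: str = "monoisotopic",
    elements: ElementTable = DEFAULT_ELEMENTS,
    electron_correction: bool = True,
) -> float:
    """Mass in u: Σ count·element-mass, minus charge·electron-mass.

    The electron correction is what separates e.g. C2SNH4+ at 74.00590 from
    the uncorrected 74.00645; it is applied whenever a charge is set unless
    explicitly disabled.
    """
    if scale == "monoisotopic":
        table = elements.monoisotopic
    elif scale in ("average", "nominal"):
        table = elements.average
    else:
        raise ValueError(f"unknown mass scale {scale!r}")
    m = sum(n * table[el] for el, n in comp.counts)
    if electron_correction:
        m -= comp.charge * elements.electron_mass
    if scale == "nominal":
        return float(round(m))
    return m


def mz(
    comp: Composition,
    scale: str = "monoisotopic",
    elements: ElementTable = DEFAULT_ELEMENTS,
    electron_correction: bool = True,
) -> float:
    """m/z in u per elementary charge: |mass/charge|.

    ``nominal`` is defined as the average mass rounded to the nearest integer
    before division — this reproduces the integer peak labels of unit-
    resolution TOF spectra (e.g. the disulfide cation S2+ at m/z 64 despite
    an average mass of 64.12).
    """
    if comp.charge == 0:
        raise ValueError("m/z undefined for charge 0 (mass is still defined)")
    return abs(mass(comp, scale, elements, electron_correction) / comp.charge)


# ---------------------------------------------------------------------------
# Molecular graph


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    label: str  # e.g. "C1", "S2", "H7"; unique within a molecule


@dataclass
class MolecularGraph:
    """Labeled atoms + a simple undirected bond set + total charge."""

    atoms: list
    bonds: set  # of frozenset({i, j}) atom-index pairs
    charge: int = 0

    def __post_init__(self) -> None:
        idx = {a.index for a in self.atoms}
        if len(idx) != len(self.atoms):
            raise ValueError("duplicate atom indices")
        labels = [a.label for a in self.atoms]
        if len(set(labels)) != len(labels):
            raise ValueError("atom labels must be unique")
        for b in self.bonds:
            if len(b) != 2 or not b <= idx:
                raise ValueError(f"bond {set(b)} has invalid endpoints")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_by_label(self, label: str) -> Atom:
        for a in self.atoms:
            if a.label == label:
                return a
        raise KeyError(label)

    def bond(self, label_a: str, label_b: str) -> frozenset:
        """The bond between two labeled atoms, e.g. ``bond("S1", "S2")``."""
        b = frozenset(
            {self.atom_by_label(label_a).index, self.atom_by_label(label_b).index}
        )
        if b not in self.bonds:
            raise KeyError(f"no bond {label_a}-{label_b}")
        return b

    def bond_label(self, bond: frozenset) -> str:
        i, j = sorted(bond)
        by_index = {a.index: a.label for a in self.atoms}
        return f"{by_index[i]}-{by_index[j]}"

    def composition(self) -> Composition:
        counts: dict = {}
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
        return Composition.from_dict(counts, self.charge)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.index, element=a.element, label=a.label)
        g.add_edges_from(tuple(b) for b in self.bonds)
        return g

    # --- JSON bond-list serialization ---

    def to_json(self) -> str:
        return json.dumps(
            {
                "charge": self.charge,
                "atoms": [
                    {"index": a.index, "element": a.element, "label": a.label}
                    for a in self.atoms
                ],
                "bonds": sorted(sorted(b) for b in self.bonds),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MolecularGraph":
        d = json.loads(text)
        atoms = [Atom(a["index"], a["element"], a["label"]) for a in d["atoms"]]
        bonds = {frozenset(b) for b in d["bonds"]}
        return cls(atoms, bonds, d.get("charge", 0))


@dataclass(frozen=True)
class Fragment:
    """A connected piece of a parent molecule.

    Charge is deliberately unassigned (0) by default: a classical trajectory
    cannot partition charge among fragments, so downstream reporting quotes
    neutral formulas plus hypothetical +1 m/z values.
    """

    atom_indices: frozenset
    composition: Composition

    def mz_as_cation(self, scale: str = "nominal") -> float:
        return mz(self.composition.with_charge(+1), scale)

    @property
    def nominal_mz(self) -> int:
        return int(round(self.mz_as_cation("nominal")))


def fragments_from_broken_bonds(graph: MolecularGraph, broken) -> list:
    """Connected components of the graph after removing ``broken`` bonds.

    Returns fragments sorted by descending atom count (parent first when
    nothing broke).  The fragments partition the parent's atoms, so their
    compositions always sum to the parent composition.
    """
    broken = {frozenset(b) for b in broken}
    unknown = broken - graph.bonds
    if unknown:
        raise ValueError(f"broken bonds not in graph: {sorted(map(sorted, unknown))}")
    g = graph.to_networkx()
    g.remove_edges_from(tuple(b) for b in broken)
    element = {a.index: a.element for a in graph.atoms}
    frags = []
    for comp_nodes in nx.connected_components(g):
        counts: dict = {}
        for i in comp_nodes:
            counts[element[i]] = counts.get(element[i], 0) + 1
        frags.append(
            Fragment(frozenset(comp_nodes), Composition.from_dict(counts, 0))
        )
    frags.sort(key=lambda f: (-len(f.atom_indices), sorted(f.atom_indices)))
    return frags


# ---------------------------------------------------------------------------
# Cystine fixture


def cystine_topology(protonated_nitrogen: str = "N2") -> MolecularGraph:
    """Protonated cystine [C6H12N2O4S2 + H]+ as a labeled molecular graph.

    Cystine is two cysteines joined by a disulfide bridge:
    HOOC–CH(NH2)–CH2–S–S–CH2–CH(NH2)–COOH, with one extra proton on one of
    the two (symmetry-equivalent) amine nitrogens.  Heavy-atom labels follow
    the convention used for the fragmentation pathways: C1/C4 are the alpha
    carbons, C2/C5 the carboxyl carbons, C3/C6 the CH2 carbons bound to
    S1/S2.  27 atoms, +1 total charge.

    protonated_nitrogen: "N1" or "N2" — which amine carries the extra proton
    (the two sites are chemically equivalent; exposed for sensitivity tests).
    """
    if protonated_nitrogen not in ("N1", "N2"):
        raise ValueError("protonation site must be 'N1' or 'N2'")
    atoms = []
    bonds = set()
    label_index: dict = {}

    def add(element: str, label: str) -> str:
        i = len(atoms)
        atoms.append(Atom(i, element, label))
        label_index[label] = i
        return label

    def link(la: str, lb: str) -> None:
        bonds.add(frozenset({label_index[la], label_index[lb]}))

    # Heavy atoms, half A: C1 alpha, C2 carboxyl (O1=O, O2-H), C3 CH2, N1, S1
    for el, lab in [
        ("C", "C1"), ("C", "C2"), ("C", "C3"), ("N", "N1"),
        ("O", "O1"), ("O", "O2"), ("S", "S1"),
        ("C", "C4"), ("C", "C5"), ("C", "C6"), ("N", "N2"),
        ("O", "O3"), ("O", "O4"), ("S", "S2"),
    ]:
        add(el, lab)
    for pair in [
        ("C1", "C2"), ("C1", "C3"), ("C1", "N1"), ("C2", "O1"), ("C2", "O2"),
        ("C3", "S1"), ("S1", "S2"),
        ("C4", "C5"), ("C4", "C6"), ("C4", "N2"), ("C5", "O3"), ("C5", "O4"),
        ("C6", "S2"),
    ]:
        link(*pair)

    # Hydrogens: 13 total — 2 carboxyl OH, 2 alpha CH, 4 CH2, NH2 + NH3+.
    h = 0

    def add_h(heavy: str) -> None:
        nonlocal h
        h += 1
        add("H", f"H{h}")
        link(heavy, f"H{h}")

    for heavy, n in [("O2", 1), ("C1", 1), ("C3", 2), ("N1", 2),
                     ("O4", 1), ("C4", 1), ("C6", 2), ("N2", 2)]:
        for _ in range(n):
            add_h(heavy)
    add_h(protonated_nitrogen)  # the extra proton -> NH3+

    return MolecularGraph(atoms, bonds, charge=+1)


#: Symmetry-equivalent bond classes monitored in the fragmentation analysis,
#: as (class label, [(atom label, atom label), ...]).
CYSTINE_BOND_CLASSES = {
    "Calpha-CH2S": [("C1", "C3"), ("C4", "C6")],
    "Calpha-COOH": [("C1", "C2"), ("C4", "C5")],
    "S-C": [("S1", "C3"), ("S2", "C6")],
    "S-S": [("S1", "S2")],
}
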