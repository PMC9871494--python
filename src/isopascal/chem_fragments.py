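"""Molecular formulas, nominal masses, and the TMS/MEOX fragment registry.

GC-MS analysis of silylated metabolites monitors fragment ions whose formula
mixes carbons from the metabolite backbone with atoms added by derivatization
(trimethylsilyl and methoxyamine groups).  Each registry entry records the ion
formula, its nominal m/z, and which backbone carbon positions the fragment
retains — the information needed to build isotope-correction matrices and to
interpret isotopologue indices as backbone ¹³C counts.

Fragment names follow the ``Metabolite_kTMS_CxCy`` convention (for example
``Malate_3TMS_C1C4`` is the malate tri-TMS fragment retaining carbons C1–C4)
and are used as exact join keys throughout the package.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

__all__ = [
    "ELEMENTS", "NOMINAL_MASSES", "FormulaError", "RegistryError",
    "parse_formula", "write_formula", "nominal_mass",
    "FragmentDef", "Registry", "load_registry", "default_registry",
]

#: Elements that occur in TMS/MEOX-derivative fragment ions.
ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "S", "Si")

#: Nominal (lightest-isotope) masses in Da.
NOMINAL_MASSES: Mapping[str, int] = {
    "C": 12, "H": 1, "N": 14, "O": 16, "S": 32, "Si": 28,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or unsupported chemical formulas."""


class RegistryError(ValueError):
    """Raised when a fragment registry fails validation."""


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style formula string into element counts.

    Two-letter symbols (``Si``) are matched greedily before one-letter ones,
    and an omitted count means 1, so ``"C10H24NO2Si2"`` parses to
    ``{"C": 10, "H": 24, "N": 1, "O": 2, "Si": 2}``.

    Raises
    ------
    FormulaError
        If the string is empty, contains an unsupported element, or has
        malformed tokens.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token at {text[pos:]!r}"
            )
        symbol, digits = m.group(1), m.group(2)
        if symbol not in ELEMENTS:
            raise FormulaError(
                f"unknown element {symbol!r} in formula {text!r} "
                f"(supported: {', '.join(ELEMENTS)})"
            )
        count = int(digits) if digits else 1
        if count < 1:
            raise FormulaError(f"non-positive count for {symbol} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + count
        pos = m.end()
    return counts


def write_formula(counts: Mapping[str, int]) -> str:
    """Write element counts as a canonical Hill string (C, H, then others
    alphabetically); inverse of :func:`parse_formula` on canonical input."""
    _check_counts(counts)
    order = ["C", "H"] + sorted(e for e in counts if e not in ("C", "H"))
    parts = []
    for el in order:
        n = counts.get(el, 0)
        if n:
            parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def nominal_mass(counts: Mapping[str, int]) -> int:
    """Nominal mass in Da: sum of lightest-isotope integer masses
    (C=12, H=1, N=14, O=16, S=32, Si=28)."""
    _check_counts(counts)
    return sum(NOMINAL_MASSES[el] * n for el, n in counts.items())


def _check_counts(counts: Mapping[str, int]) -> None:
    if not counts:
        raise FormulaError("empty element mapping")
    for el, n in counts.items():
        if el not in ELEMENTS:
            raise FormulaError(f"unknown element {el!r}")
        if not isinstance(n, int) or n < 1:
            raise FormulaError(f"invalid count {n!r} for element {el!r}")


@dataclass(frozen=True)
class FragmentDef:
    """One monitored fragment ion.

    Attributes
    ----------
    name : str
        Join key, ``Metabolite_kTMS_CxCy``.
    metabolite, derivative : str
        Parent metabolite and derivatization label (e.g. ``"3TMS"``).
    ion_formula : dict
        Element counts of the monitored ion (backbone + derivative atoms).
    nominal_mz : int
        Nominal m/z of the unlabeled ion; always equals
        ``nominal_mass(ion_formula)``.
    backbone_positions : tuple of int
        Metabolite carbon positions retained by the fragment, in order.
    note : str
        Free-text annotation (e.g. ``molecular_ion`` when no neutral loss
        is listed and the full derivative is monitored).
    """

    name: str
    metabolite: str
    derivative: str
    ion_formula: Mapping[str, int]
    nominal_mz: int
    backbone_positions: tuple[int, ...]
    note: str = ""

    @property
    def n_backbone(self) -> int:
        """Number of backbone carbons monitored (length of the CID minus 1)."""
        return len(self.backbone_positions)

    def __post_init__(self) -> None:
        computed = nominal_mass(self.ion_formula)
        if computed != self.nominal_mz:
            raise RegistryError(
                f"{self.name}: stated m/z {self.nominal_mz} != computed "
                f"nominal mass {computed} for {write_formula(self.ion_formula)}"
            )
        if self.n_backbone < 1:
            raise RegistryError(f"{self.name}: empty carbon skeleton")
        if self.n_backbone > self.ion_formula.get("C", 0):
            raise RegistryError(
                f"{self.name}: {self.n_backbone} backbone carbons exceed the "
                f"{self.ion_formula.get('C', 0)} carbons of the ion formula"
            )


@dataclass
class Registry:
    """Ordered collection of :class:`FragmentDef` with unique names."""

    fragments: list[FragmentDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.fragments]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RegistryError(f"duplicate fragment names: {sorted(dupes)}")
        self._index = {f.name: f for f in self.fragments}

    def __getitem__(self, name: str) -> FragmentDef:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(
                f"unknown fragment {name!r}; valid names: "
                f"{', '.join(self.names)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __iter__(self) -> Iterator[FragmentDef]:
        return iter(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.fragments]


_COLUMNS = ("name", "metabolite", "derivative", "ion_formula",
            "nominal_mz", "skeleton")


def load_registry(path: str | Path) -> Registry:
    """Load and validate a fragment registry from a TSV file.

    Expected columns: ``name``, ``metabolite``, ``derivative``,
    ``ion_formula``, ``nominal_mz``, ``skeleton`` (dash-separated backbone
    positions), plus an optional ``note``.  Every row's nominal mass is
    recomputed from the formula and checked against the stated m/z.

    Raises
    ------
    RegistryError
        Listing every row whose stated m/z disagrees with the computed mass,
        or on structural problems (missing columns, duplicate names).
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        warnings.warn(f"registry file {path} is empty", stacklevel=2)
        return Registry([])
    header = [h.strip() for h in lines[0].split("\t")]
    missing = [c for c in _COLUMNS if c not in header]
    if missing:
        raise RegistryError(f"registry {path} missing columns: {missing}")
    idx = {c: header.index(c) for c in header}
    fragments, errors = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in line.split("\t")]
        row = {c: cells[i] if i < len(cells) else "" for c, i in idx.items()}
        try:
            frag = FragmentDef(
                name=row["name"],
                metabolite=row["metabolite"],
                derivative=row["derivative"],
                ion_formula=parse_formula(row["ion_formula"]),
                nominal_mz=int(row["nominal_mz"]),
                backbone_positions=tuple(
                    int(p) for p in row["skeleton"].split("-") if p
                ),
                note=row.get("note", ""),
            )
        except (FormulaError, RegistryError, ValueError) as exc:
            errors.append(f"line {lineno} ({row.get('name', '?')}): {exc}")
            continue
        fragments.append(frag)
    if errors:
        raise RegistryError(
            "registry validation failed:\n  " + "\n  ".join(errors)
        )
    return Registry(fragments)


def default_registry() -> Registry:
    """The packaged registry of TMS/MEOX fragment ions for organic and amino
    acids (36 fragments of 25 metabolites)."""
    with resources.as_file(
        resources.files("isopascal").joinpath("data/fragments.tsv")
    ) as p:
        return load_registry(p)
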