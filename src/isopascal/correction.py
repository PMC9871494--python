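"""Natural-isotope-abundance correction of GC-MS isotopic clusters.

A measured isotopic cluster of a derivatized fragment mixes the ¹³C tracer
signal of the metabolite backbone with naturally occurring heavy isotopes of
every other atom — derivative carbons, H, N, O, S and, dominantly for TMS
derivatives, ²⁹Si/³⁰Si.  Correction is a linear deconvolution: column *j* of
the correction matrix is the isotopic fine structure a molecule with exactly
*j* labeled backbone carbons would produce on the nominal-mass ladder, and the
backbone CID is recovered by solving ``raw ≈ matrix · x`` under ``x ≥ 0``
(non-negative least squares), then normalizing to unit sum.

Low-resolution semantics: heavy isotopes of all elements are projected onto a
single integer mass-shift axis, so ¹⁸O and ³⁰Si both contribute at +2.

Two correction tiers are exposed:

* derivative + heteroatom correction (always applied) — natural isotopes of
  everything except the backbone carbons;
* backbone-carbon natural-abundance correction (``CorrectionOptions.
  correct_backbone_natural_abundance``) — additionally attributes natural ¹³C
  of the unlabeled backbone carbons, appropriate for unlabeled samples where
  the residual molecular ¹³C enrichment should then be 0.  Samples with fully
  controlled backbone labeling (binomial ¹³C-PT standards, tracer
  experiments) must keep this tier off so backbone signal is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import nnls

from isopascal.chem_fragments import FragmentDef

__all__ = [
    "IsotopeAbundanceTable", "load_isotope_table",
    "CorrectionOptions", "RawIsotopicCluster", "CID",
    "natural_pattern", "build_correction_matrix",
    "correct_cluster", "forward_convolve",
]

#: element -> ordered list of (integer mass shift, abundance fraction)
IsotopeAbundanceTable = Mapping[str, Sequence[tuple[int, float]]]


def load_isotope_table(path: str | Path | None = None) -> dict[str, list[tuple[int, float]]]:
    """Load an isotope abundance table (packaged defaults if *path* is None).

    Validates that each element's abundances sum to 1 within 1e-9 and that
    shifts start at 0 and strictly increase.
    """
    if path is None:
        src = resources.files("isopascal").joinpath("data/isotopes.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    table: dict[str, list[tuple[int, float]]] = {}
    for el, pairs in raw["elements"].items():
        pairs = [(int(s), float(a)) for s, a in pairs]
        shifts = [s for s, _ in pairs]
        if shifts[0] != 0 or any(b <= a for a, b in zip(shifts, shifts[1:])):
            raise ValueError(f"{el}: shifts must start at 0 and increase")
        total = sum(a for _, a in pairs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{el}: abundances sum to {total}, not 1")
        table[el] = pairs
    return table


@dataclass(frozen=True)
class CorrectionOptions:
    """Options controlling matrix construction and the NNLS inversion.

    Parameters
    ----------
    correct_backbone_natural_abundance : bool
        Second correction tier (see module docstring). Default off.
    tracer_purity : float
        Isotopic purity of the ¹³C tracer in (0, 1]; below 1, a binomial
        purity kernel is convolved into each column. Default 1.0 (no purity
        correction).
    tolerance : float
        Truncation tolerance for convolved isotope patterns.
    residual_warn : float
        Relative residual above which the corrected CID is flagged.
    tail_shifts : int
        Mass shifts carried beyond the last tracer isotopologue; six capture
        >99.9% of the pattern mass for Si-rich TMS fragments.
    """

    correct_backbone_natural_abundance: bool = False
    tracer_purity: float = 1.0
    tolerance: float = 1e-9
    residual_warn: float = 0.05
    tail_shifts: int = 6

    def __post_init__(self) -> None:
        if not (0.0 < self.tracer_purity <= 1.0):
            raise ValueError("tracer_purity must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class RawIsotopicCluster:
    """Uncorrected area ladder for one fragment in one sample.

    ``areas[k]`` is the integrated area at nominal m/z + k.
    """

    fragment: str
    areas: np.ndarray
    sample: str = ""

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.ndim != 1 or self.areas.size == 0:
            raise ValueError("areas must be a non-empty 1-D vector")
        if np.any(self.areas < 0):
            raise ValueError(f"{self.fragment}: negative areas")


@dataclass
class CID:
    """Corrected carbon isotopologue distribution of one fragment.

    ``fractions[i]`` is the fraction of molecules carrying exactly *i* labeled
    backbone carbons; ``mean_enrichment = Σ i·mᵢ / n``.
    """

    fragment: str
    fractions: np.ndarray
    mean_enrichment: float
    residual: float = 0.0
    sample: str = ""
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions < -1e-12):
            raise ValueError(f"{self.fragment}: negative isotopologue fraction")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.fragment}: fractions sum to "
                             f"{self.fractions.sum()}, not 1")

    @property
    def n(self) -> int:
        return self.fractions.size - 1


def _mean_enrichment(fractions: np.ndarray) -> float:
    n = fractions.size - 1
    if n == 0:
        return 0.0
    return float(np.arange(n + 1) @ fractions / n)


def _truncate(pattern: np.ndarray, tol: float) -> np.ndarray:
    tail = np.cumsum(pattern[::-1])[::-1]
    keep = int(np.searchsorted(-tail, -tol))  # first index with tail < tol
    return pattern[: max(keep, 1)]


def natural_pattern(
    formula: Mapping[str, int],
    table: IsotopeAbundanceTable | None = None,
    exclude_backbone_carbons: int = 0,
    tolerance: float = 1e-12,
) -> np.ndarray:
    """Isotopic pattern of a formula on the integer mass-shift ladder.

    Convolves the per-atom isotope distributions of every atom in *formula*,
    excluding ``exclude_backbone_carbons`` carbons (the tracer positions,
    handled separately by the correction matrix).  Entries sum to 1 up to
    trailing truncation below *tolerance*.
    """
    if table is None:
        table = load_isotope_table()
    n_c = formula.get("C", 0)
    if exclude_backbone_carbons > n_c:
        raise ValueError(
            f"cannot exclude {exclude_backbone_carbons} backbone carbons from "
            f"a formula with {n_c} carbons"
        )
    pattern = np.array([1.0])
    for el, count in formula.items():
        if el == "C":
            count -= exclude_backbone_carbons
        if count == 0:
            continue
        pairs = table[el]
        dist = np.zeros(max(s for s, _ in pairs) + 1)
        for s, a in pairs:
            dist[s] = a
        for _ in range(count):
            pattern = np.convolve(pattern, dist)
    return _truncate(pattern, tolerance)


def _purity_kernel(j: int, purity: float) -> np.ndarray:
    """Distribution of actual ¹³C count among j tracer positions at the given
    isotopic purity (binomial)."""
    return np.array([comb(j, i) * purity**i * (1 - purity) ** (j - i)
                     for i in range(j + 1)])


def build_correction_matrix(
    frag: FragmentDef,
    table: IsotopeAbundanceTable | None = None,
    opts: CorrectionOptions = CorrectionOptions(),
) -> np.ndarray:
    """Correction matrix for a fragment.

    Rows index measured mass shifts 0..n+tail_shifts, columns index tracer
    isotopologues 0..n.  Column *j* is the natural pattern of all non-tracer
    atoms shifted by *j*; with the backbone tier on, the ``n - j`` unlabeled
    backbone carbons additionally contribute natural ¹³C, and with
    ``tracer_purity < 1`` a binomial purity kernel is convolved in.
    """
    if table is None:
        table = load_isotope_table()
    n = frag.n_backbone
    rows = n + opts.tail_shifts + 1
    base = natural_pattern(frag.ion_formula, table,
                           exclude_backbone_carbons=n,
                           tolerance=opts.tolerance)
    carbon = np.zeros(max(s for s, _ in table["C"]) + 1)
    for s, a in table["C"]:
        carbon[s] = a
    matrix = np.zeros((rows, n + 1))
    for j in range(n + 1):
        col = base
        if opts.correct_backbone_natural_abundance:
            for _ in range(n - j):
                col = np.convolve(col, carbon)
        if opts.tracer_purity < 1.0:
            col = np.convolve(col, _purity_kernel(j, opts.tracer_purity))
            shift = 0  # kernel already places the labeled mass
        else:
            shift = j
        stop = min(rows, shift + col.size)
        matrix[shift:stop, j] += col[: stop - shift]
    return matrix


def correct_cluster(
    raw: RawIsotopicCluster,
    frag: FragmentDef,
    table: IsotopeAbundanceTable | None = None,
    opts: CorrectionOptions = CorrectionOptions(),
) -> CID:
    """Invert a raw isotopic cluster into a backbone-carbon CID.

    Solves ``raw ≈ matrix · x`` with ``x ≥ 0`` (NNLS), normalizes *x* to unit
    sum, and reports the relative fit residual and the mean ¹³C enrichment
    ``Σ i·xᵢ / n``.

    Raises
    ------
    ValueError
        If the cluster is shorter than n+1 shifts, or all areas are zero.
    """
    n = frag.n_backbone
    areas = raw.areas
    if areas.size < n + 1:
        raise ValueError(
            f"{frag.name}: cluster has {areas.size} shifts, needs at least "
            f"{n + 1}"
        )
    if not np.any(areas > 0):
        raise ValueError(f"{frag.name}: all-zero areas in sample {raw.sample!r}")
    warns: list[str] = []
    matrix = build_correction_matrix(frag, table, opts)
    if areas.size > matrix.shape[0]:
        warns.append(
            f"ignoring {areas.size - matrix.shape[0]} areas beyond shift "
            f"{matrix.shape[0] - 1}"
        )
        areas = areas[: matrix.shape[0]]
    rows = areas.size
    x, rnorm = nnls(matrix[:rows], areas)
    total = x.sum()
    if total <= 0:
        raise ValueError(f"{frag.name}: correction produced a zero solution")
    residual = float(rnorm / np.linalg.norm(areas))
    if residual > opts.residual_warn:
        warns.append(f"high correction residual {residual:.3g}")
    fractions = x / total
    return CID(
        fragment=frag.name,
        fractions=fractions,
        mean_enrichment=_mean_enrichment(fractions),
        residual=residual,
        sample=raw.sample,
        warnings=tuple(warns),
    )


def forward_convolve(
    cid: CID | np.ndarray | Sequence[float],
    frag: FragmentDef,
    table: IsotopeAbundanceTable | None = None,
    opts: CorrectionOptions = CorrectionOptions(),
    total_area: float = 1.0,
    sample: str = "",
) -> RawIsotopicCluster:
    """Predict the raw isotopic cluster a CID would produce (inverse of
    :func:`correct_cluster`), scaled to *total_area*.

    Used both as the round-trip oracle for the correction solver and as the
    measurement model of the synthetic-data generators.
    """
    fractions = cid.fractions if isinstance(cid, CID) else np.asarray(cid, float)
    n = frag.n_backbone
    if fractions.size != n + 1:
        raise ValueError(
            f"{frag.name}: CID has {fractions.size} entries, expected {n + 1}"
        )
    matrix = build_correction_matrix(frag, table, opts)
    areas = matrix @ fractions
    s = areas.sum()
    if s > 0:
        areas = areas * (total_area / s)
    return RawIsotopicCluster(fragment=frag.name, areas=areas, sample=sample)
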