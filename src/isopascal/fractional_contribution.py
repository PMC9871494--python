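"""Pathway fractional contributions from U-¹³C-pyruvate labeling.

With U-¹³C-pyruvate as tracer, mitochondrial pyruvate dehydrogenase (PDC)
produces M2 acetyl-CoA and ¹³CO₂ simultaneously.  The ¹³CO₂ (as bicarbonate)
can be reassimilated by phosphoenolpyruvate carboxylase (PEPc) into
oxaloacetate/malate, producing isotopologue signatures distinct from forward
turns of the TCA cycle:

* malate C1–C4: M1 comes from both PEPc and the second TCA "turn"; M2 and M3
  are TCA-only.  The second turn produces M1 and M3 in a fixed ratio set by
  the labeling of the active acetyl-CoA pool, so its M1 share can be inferred
  from M3.
* citrate C1–C6: M1 is PEPc-only, M2 and M4 are TCA-only, M3 carries one unit
  of each pathway.
* serine C1–C2 / C2–C3: photorespiratory serine gains M1 (labeled at C2 only)
  from photosynthetic reassimilation of PDC/TCA-derived ¹³CO₂.

The acetyl-CoA pool M2 fraction *X* is estimated as ``m3/(m1+m3)`` of
succinate C1–C4 or glutamate C2–C5 (both inherit the ratio unchanged).  The
fractional contributions (FC) are then, writing mᵢ for CID fractions:

    FC_malate_PEPc = (m1 − m3·(1−X)/X) / (m1+m2+m3)
    FC_malate_TCA  = (m2 + m3/X)       / (m1+m2+m3)
    FC_citrate_PEPc = (m1+m3)       / (m1+m2+2·m3+m4)
    FC_citrate_TCA  = (m2+m3+m4)    / (m1+m2+2·m3+m4)
    FC_photosynthesis = (m1/2) / X          (serine, n = 2 carbons)

Each PEPc/TCA pair sums to 1 by construction, and all FCs depend only on
isotopologue ratios, so corrected areas and fractions give identical results.
Calculations assume metabolic and isotopic (pseudo) steady state; by default
the 4 h and 6 h timepoints are pooled at the replicate level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from isopascal.correction import CID

__all__ = [
    "LabelingSample", "AcetylPoolRatio", "FCResult",
    "acetyl_ratio_from_cid", "acetyl_pool_ratio",
    "fc_malate", "fc_citrate", "fc_photosynthesis",
    "pool_steady_state", "fc_summary",
    "DEFAULT_X_FRAGMENT", "X_CROSS_CHECK_FRAGMENT",
]

#: Fragment used for the acetyl-CoA pool ratio by default (weak analytical and
#: biological variability); glutamate C2-C5 serves as cross-check.
DEFAULT_X_FRAGMENT = "Succinate_2TMS_C1C4"
X_CROSS_CHECK_FRAGMENT = "Glutamate_3TMS_C2C5"

MALATE_FRAGMENT = "Malate_3TMS_C1C4"
CITRATE_FRAGMENT = "Citrate_4TMS_C1C6"
SERINE_FRAGMENTS = ("Serine_3TMS_C1C2", "Serine_2TMS_C2C3", "Serine_3TMS_C2C3")


@dataclass
class LabelingSample:
    """One labeled sample: condition/time/replicate plus fragment → CID map."""

    condition: str
    time_h: float
    replicate: int | str
    cids: dict[str, CID | np.ndarray]

    def fractions(self, fragment: str) -> np.ndarray:
        c = self.cids[fragment]
        return c.fractions if isinstance(c, CID) else np.asarray(c, float)


@dataclass
class AcetylPoolRatio:
    """M2 fraction X of the active acetyl-CoA pool, m3/(m1+m3)."""

    x: float
    sd: float
    source_fragment: str
    per_replicate: pd.DataFrame
    timepoints: tuple[float, ...]


@dataclass
class FCResult:
    """Fractional contributions of pathways to one target metabolite."""

    target: str
    contributions: dict[str, float]
    warnings: tuple[str, ...] = field(default_factory=tuple)


def _frac(cid: CID | np.ndarray | Sequence[float]) -> np.ndarray:
    return cid.fractions if isinstance(cid, CID) else np.asarray(cid, float)


def acetyl_ratio_from_cid(cid: CID | np.ndarray | Sequence[float]) -> float:
    """X = m3/(m1+m3) for a single succinate C1-C4 or glutamate C2-C5 CID."""
    m = _frac(cid)
    if m.size < 4:
        raise ValueError("fragment must carry at least 3 backbone carbons")
    denom = m[1] + m[3]
    if denom <= 0:
        raise ZeroDivisionError("m1 + m3 = 0: acetyl pool ratio undefined")
    return float(m[3] / denom)


def pool_steady_state(
    samples: Iterable[LabelingSample],
    timepoints: Sequence[float] = (4.0, 6.0),
    condition: str | None = None,
) -> list[LabelingSample]:
    """Pool replicate-level samples across steady-state timepoints.

    Returns the samples at the requested timepoints (optionally restricted to
    one condition) concatenated — 4 replicates × 2 timepoints give 8 pooled
    replicate values.  Downstream FCs are computed per pooled replicate and
    then summarized.
    """
    samples = list(samples)
    available = sorted({s.time_h for s in samples})
    missing = [t for t in timepoints if t not in available]
    if missing:
        raise ValueError(
            f"timepoints {missing} not present; available: {available}"
        )
    pooled = [
        s for s in samples
        if s.time_h in set(timepoints)
        and (condition is None or s.condition == condition)
    ]
    return pooled


def acetyl_pool_ratio(
    samples: Iterable[LabelingSample],
    fragment: str = DEFAULT_X_FRAGMENT,
    timepoints: Sequence[float] = (4.0, 6.0),
    condition: str | None = None,
) -> AcetylPoolRatio:
    """Estimate X = m3/(m1+m3) from pooled steady-state replicates."""
    pooled = pool_steady_state(samples, timepoints, condition)
    rows = []
    for s in pooled:
        if fragment not in s.cids:
            raise KeyError(
                f"fragment {fragment!r} missing from sample "
                f"({s.condition}, t={s.time_h}, rep={s.replicate})"
            )
        rows.append({
            "condition": s.condition,
            "time_h": s.time_h,
            "replicate": s.replicate,
            "x": acetyl_ratio_from_cid(s.cids[fragment]),
        })
    if not rows:
        raise ValueError("no samples at the requested timepoints/condition")
    table = pd.DataFrame(rows)
    return AcetylPoolRatio(
        x=float(table["x"].mean()),
        sd=float(table["x"].std(ddof=1)) if len(table) > 1 else 0.0,
        source_fragment=fragment,
        per_replicate=table,
        timepoints=tuple(timepoints),
    )


def _check_x(x: float) -> None:
    if not (0.0 < x < 1.0) or not math.isfinite(x):
        raise ValueError(f"acetyl pool ratio X must be in (0, 1), got {x}")


def fc_malate(cid: CID | np.ndarray | Sequence[float], x: float) -> FCResult:
    """PEPc vs TCA-cycle contribution to malate from the C1-C4 fragment.

    The TCA second turn produces M1 and M3 in the ratio (1-X):X, so
    ``m3·(1−X)/X`` of M1 is attributed to the TCA cycle and the remainder to
    PEPc.  A slight M1 deficit (noise) clamps FC_PEPc to 0 with a warning
    carrying the raw value.
    """
    _check_x(x)
    m = _frac(cid)
    if m.size < 4:
        raise ValueError("malate C1-C4 fragment must have 4 backbone carbons")
    m1, m2, m3 = m[1], m[2], m[3]
    labeled = m1 + m2 + m3
    if labeled <= 0:
        raise ZeroDivisionError("m1 + m2 + m3 = 0: no labeled malate")
    pepc = (m1 - m3 * (1.0 - x) / x) / labeled
    tca = (m2 + m3 / x) / labeled
    warns: tuple[str, ...] = ()
    if pepc < 0:
        warns = (f"FC_PEPc clamped to 0 (raw value {pepc:.4g})",)
        pepc, tca = 0.0, 1.0
    return FCResult("malate", {"PEPc": float(pepc), "TCA": float(tca)}, warns)


def fc_citrate(cid: CID | np.ndarray | Sequence[float]) -> FCResult:
    """PEPc vs TCA-cycle contribution to citrate from the C1-C6 fragment.

    M1 is PEPc-only, M2/M4 are TCA-only and M3 carries one unit of each, so
    FC_PEPc = (m1+m3)/(m1+m2+2·m3+m4).
    """
    m = _frac(cid)
    if m.size < 5:
        raise ValueError("citrate C1-C6 fragment must have >= 4 isotopologues")
    m1, m2, m3, m4 = m[1], m[2], m[3], m[4]
    denom = m1 + m2 + 2.0 * m3 + m4
    if denom <= 0:
        raise ZeroDivisionError("no labeled citrate isotopologues")
    return FCResult(
        "citrate",
        {"PEPc": float((m1 + m3) / denom), "TCA": float((m2 + m3 + m4) / denom)},
    )


def fc_photosynthesis(cid: CID | np.ndarray | Sequence[float], x: float) -> FCResult:
    """Share of net photosynthesis fed by PDC/TCA-derived CO₂, via serine.

    Serine is labeled only at C2 in the monitored two-carbon fragments, so its
    mean enrichment is recomputed as m1/2 and compared with the enrichment X
    expected if mitochondrial CO₂ were the sole carbon source.
    """
    _check_x(x)
    m = _frac(cid)
    if m.size != 3:
        raise ValueError("serine fragments carry 2 backbone carbons")
    return FCResult(
        "photosynthesis", {"PDC_TCA_CO2": float((m[1] / 2.0) / x)}
    )


def fc_summary(
    samples: Iterable[LabelingSample],
    timepoints: Sequence[float] = (4.0, 6.0),
    x_fragment: str = DEFAULT_X_FRAGMENT,
    serine_fragment: str | None = None,
) -> pd.DataFrame:
    """Per-condition fractional-contribution table.

    For each condition, estimates X from the pooled steady-state replicates,
    computes malate, citrate and (when a serine fragment is present)
    photosynthesis FCs per pooled replicate, and summarizes mean ± SD.

    Returns a frame with columns target, pathway, condition, mean, sd, n,
    x_used, warnings.
    """
    samples = list(samples)
    conditions = sorted({s.condition for s in samples})
    rows = []
    for cond in conditions:
        ratio = acetyl_pool_ratio(samples, x_fragment, timepoints, cond)
        pooled = pool_steady_state(samples, timepoints, cond)
        values: dict[tuple[str, str], list[float]] = {}
        warns: dict[tuple[str, str], list[str]] = {}
        for s in pooled:
            per_rep_x = acetyl_ratio_from_cid(s.cids[x_fragment])
            if MALATE_FRAGMENT in s.cids:
                res = fc_malate(s.fractions(MALATE_FRAGMENT), per_rep_x)
                for pw, v in res.contributions.items():
                    values.setdefault(("malate", pw), []).append(v)
                    warns.setdefault(("malate", pw), []).extend(res.warnings)
            if CITRATE_FRAGMENT in s.cids:
                res = fc_citrate(s.fractions(CITRATE_FRAGMENT))
                for pw, v in res.contributions.items():
                    values.setdefault(("citrate", pw), []).append(v)
            ser = serine_fragment or next(
                (f for f in SERINE_FRAGMENTS if f in s.cids), None
            )
            if ser is not None and ser in s.cids:
                res = fc_photosynthesis(s.fractions(ser), per_rep_x)
                for pw, v in res.contributions.items():
                    values.setdefault(("photosynthesis", pw), []).append(v)
        for (target, pathway), vals in values.items():
            arr = np.asarray(vals)
            rows.append({
                "target": target,
                "pathway": pathway,
                "condition": cond,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                "n": int(arr.size),
                "x_used": ratio.x,
                "warnings": "; ".join(warns.get((target, pathway), [])),
            })
    if not rows:
        warnings.warn("no FC-relevant fragments found in samples", stacklevel=2)
    return pd.DataFrame(rows)
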