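"""Validation of measured CIDs against predictable references.

A ¹³C-PT standard is a biological extract grown on an equimolar mixture of the
four acetate isotopomers, so every metabolite's backbone labeling is an i.i.d.
coin flip per carbon: the CID of an n-carbon fragment is binomial(n, 0.5) —
Pascal's-triangle coefficients divided by 2ⁿ — and the mean ¹³C enrichment is
exactly 50%.  Comparing corrected measurements with these closed-form
references localizes analytical biases (co-eluting contaminations, rearranged
fragments) to individual isotopologues.

The accuracy metric is the mean absolute difference between measured and
predicted isotopologue fractions; replicate comparisons use per-isotopologue
Student-t confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from isopascal.correction import CID

__all__ = [
    "expected_binomial_cid", "rescale_to_pascal", "cid_accuracy",
    "mean_enrichment", "ValidationReport", "validate_replicates",
    "residual_enrichment_check",
]


def _fractions(cid: CID | np.ndarray | Sequence[float]) -> np.ndarray:
    return cid.fractions if isinstance(cid, CID) else np.asarray(cid, float)


def expected_binomial_cid(n: int, p: float) -> np.ndarray:
    """CID of an n-carbon fragment whose carbons are independently ¹³C with
    probability *p*: ``m_i = C(n, i) p^i (1-p)^(n-i)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    return np.array([comb(n, i) * p**i * (1 - p) ** (n - i)
                     for i in range(n + 1)])


def rescale_to_pascal(cid: CID | np.ndarray | Sequence[float]) -> np.ndarray:
    """Multiply the fractions by 2ⁿ so a binomial CID at p = 0.5 reads as a
    row of Pascal's triangle (average isotopomer multiplicity per
    isotopologue)."""
    f = _fractions(cid)
    n = f.size - 1
    return f * 2.0**n


def cid_accuracy(
    measured: CID | np.ndarray | Sequence[float],
    predicted: CID | np.ndarray | Sequence[float],
) -> float:
    """Mean absolute difference between measured and predicted isotopologue
    fractions (lower is better; ±0.05 is the conventional alert level)."""
    m, p = _fractions(measured), _fractions(predicted)
    if m.size != p.size:
        raise ValueError(f"CID length mismatch: {m.size} vs {p.size}")
    return float(np.mean(np.abs(m - p)))


def mean_enrichment(cid: CID | np.ndarray | Sequence[float]) -> float:
    """Mean fractional ¹³C enrichment of the backbone, ``Σ i·mᵢ / n``."""
    f = _fractions(cid)
    n = f.size - 1
    if n == 0:
        return 0.0
    return float(np.arange(n + 1) @ f / n)


@dataclass
class ValidationReport:
    """Replicate comparison of one fragment against a predicted CID.

    ``flagged[i]`` is True when the (1-alpha) confidence interval of
    isotopologue *i* across replicates excludes the prediction.
    """

    fragment: str
    measured_mean: np.ndarray
    measured_sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    predicted: np.ndarray
    flagged: np.ndarray
    cid_accuracy: float
    enrichment_deviation: float
    n_replicates: int
    alpha: float

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    def to_frame(self) -> pd.DataFrame:
        """Per-isotopologue table (one row per M0..Mn)."""
        n = self.predicted.size - 1
        return pd.DataFrame({
            "fragment": self.fragment,
            "isotopologue": np.arange(n + 1),
            "measured_mean": self.measured_mean,
            "measured_sd": self.measured_sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "predicted": self.predicted,
            "flagged": self.flagged,
            "cid_accuracy": self.cid_accuracy,
            "enrichment_deviation": self.enrichment_deviation,
        })


def validate_replicates(
    replicates: Sequence[CID | np.ndarray | Sequence[float]],
    predicted: CID | np.ndarray | Sequence[float],
    alpha: float = 0.05,
    fragment: str = "",
) -> ValidationReport:
    """Compare replicate CIDs against a prediction.

    Builds a per-isotopologue Student-t confidence interval at level
    ``1 - alpha`` and flags isotopologues whose interval excludes the
    predicted value; reports the CID accuracy of the replicate mean and the
    deviation of the replicate-mean enrichment from the predicted enrichment.
    """
    if len(replicates) < 2:
        raise ValueError("at least 2 replicates are required")
    pred = _fractions(predicted)
    if not fragment:
        for r in replicates:
            if isinstance(r, CID):
                fragment = r.fragment
                break
    arr = np.vstack([_fractions(r) for r in replicates])
    if arr.shape[1] != pred.size:
        raise ValueError("replicate/prediction length mismatch")
    k = arr.shape[0]
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    half = stats.t.ppf(1 - alpha / 2, df=k - 1) * sd / np.sqrt(k)
    lo, hi = mean - half, mean + half
    flagged = (pred < lo) | (pred > hi)
    return ValidationReport(
        fragment=fragment,
        measured_mean=mean,
        measured_sd=sd,
        ci_low=lo,
        ci_high=hi,
        predicted=pred,
        flagged=flagged,
        cid_accuracy=cid_accuracy(mean, pred),
        enrichment_deviation=mean_enrichment(mean) - mean_enrichment(pred),
        n_replicates=k,
        alpha=alpha,
    )


def residual_enrichment_check(
    cids_by_fragment: dict[str, Sequence[CID | np.ndarray | Sequence[float]]],
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Residual molecular ¹³C enrichment of unlabeled samples per fragment.

    Inputs must be CIDs corrected with the backbone natural-abundance tier on,
    so a contamination-free fragment gives a residual of 0.  Returns a frame
    with mean/SD residual enrichment per fragment and an alert flag against
    *threshold*.
    """
    rows = []
    for name, cids in cids_by_fragment.items():
        enr = np.array([mean_enrichment(c) for c in cids])
        rows.append({
            "fragment": name,
            "residual_enrichment": float(enr.mean()),
            "sd": float(enr.std(ddof=1)) if enr.size > 1 else 0.0,
            "n": enr.size,
            "flagged": bool(abs(enr.mean()) > threshold),
        })
    return pd.DataFrame(rows)
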