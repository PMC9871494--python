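"""Synthetic GC-MS datasets for exercising the correction, validation and
fractional-contribution stages without instrument data.

Three generators are provided:

* :func:`simulate_pt_extract` — ¹³C-PT-like reference extracts: every
  fragment's true CID is binomial(n, p) (p = 0.5 by default), forward-
  convolved through the derivative isotope model into raw area ladders with
  multiplicative lognormal noise;
* :func:`simulate_natural_abundance` — unlabeled samples whose backbone
  carbons carry natural ¹³C (binomial at p = 0.0107), used to exercise the
  two-tier correction and the residual-enrichment check;
* :func:`simulate_timecourse` — light/dark U-¹³C-pyruvate labeling time
  courses with pathway-specific isotopologue structure: fragment CIDs follow
  first-order saturation toward plateaus constructed so that the acetyl-CoA
  pool ratio equals ``x_true`` and the malate/citrate fractional
  contributions equal the configured pathway splits exactly (before noise).

The noise model is independent lognormal multiplication of raw areas with a
configurable coefficient of variation (GC-MS area noise is scale-dependent);
it is mean-one so expected areas are unbiased.  All generators are
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from isopascal.chem_fragments import FragmentDef, Registry, default_registry
from isopascal.correction import (
    CID,
    CorrectionOptions,
    RawIsotopicCluster,
    correct_cluster,
    forward_convolve,
    load_isotope_table,
)
from isopascal.fractional_contribution import LabelingSample
from isopascal.validation import expected_binomial_cid

__all__ = [
    "PTSimConfig", "TimecourseSimConfig", "TimecourseResult",
    "simulate_pt_extract", "simulate_natural_abundance",
    "simulate_timecourse", "inject_contamination",
    "NATURAL_13C",
]

#: Natural abundance of ¹³C (backbone carbons of unlabeled samples).
NATURAL_13C = 0.0107


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation *cv*."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


@dataclass(frozen=True)
class PTSimConfig:
    """Design of a simulated ¹³C-PT reference extract.

    Defaults mirror the reference-standard study conditions: 50% enrichment,
    four biological replicates, 2% multiplicative area noise.
    """

    seed: int
    enrichment: float = 0.5
    fragments: tuple[str, ...] | None = None  # None = whole registry
    replicates: int = 4
    noise_cv: float = 0.02
    total_area: float = 1e6

    def __post_init__(self) -> None:
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError("enrichment must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def simulate_pt_extract(
    cfg: PTSimConfig,
    registry: Registry | None = None,
    opts: CorrectionOptions = CorrectionOptions(),
) -> list[RawIsotopicCluster]:
    """Raw isotopic clusters of a ¹³C-PT extract.

    For each fragment, the true CID is binomial(n_backbone, enrichment);
    since the backbone pattern is fully controlled, the forward model applies
    natural abundances to derivative/heteroatom positions only (backbone tier
    off).  Sample ids are ``PT_rep{k}``.
    """
    registry = registry or default_registry()
    names = cfg.fragments or tuple(registry.names)
    rng = np.random.default_rng(cfg.seed)
    opts = replace(opts, correct_backbone_natural_abundance=False)
    table = load_isotope_table()
    out = []
    for rep in range(1, cfg.replicates + 1):
        sample = f"PT_rep{rep}"
        for name in names:
            frag = registry[name]
            cid = expected_binomial_cid(frag.n_backbone, cfg.enrichment)
            raw = forward_convolve(cid, frag, table, opts,
                                   total_area=cfg.total_area, sample=sample)
            raw.areas = raw.areas * _lognormal_noise(rng, cfg.noise_cv,
                                                     raw.areas.size)
            out.append(raw)
    return out


def simulate_natural_abundance(
    fragments: Sequence[str] | None = None,
    replicates: int = 4,
    noise_cv: float = 0.0,
    seed: int = 0,
    registry: Registry | None = None,
    total_area: float = 1e6,
) -> list[RawIsotopicCluster]:
    """Raw clusters of unlabeled samples at full natural abundance.

    The backbone carbons carry natural ¹³C as a binomial CID at p = 0.0107;
    after two-tier correction the residual enrichment is ≈ 0.  Sample ids are
    ``NA_rep{k}``.
    """
    registry = registry or default_registry()
    names = fragments or tuple(registry.names)
    rng = np.random.default_rng(seed)
    opts = CorrectionOptions(correct_backbone_natural_abundance=False)
    table = load_isotope_table()
    out = []
    for rep in range(1, replicates + 1):
        sample = f"NA_rep{rep}"
        for name in names:
            frag = registry[name]
            cid = expected_binomial_cid(frag.n_backbone, NATURAL_13C)
            raw = forward_convolve(cid, frag, table, opts,
                                   total_area=total_area, sample=sample)
            raw.areas = raw.areas * _lognormal_noise(rng, noise_cv,
                                                     raw.areas.size)
            out.append(raw)
    return out


def inject_contamination(
    raw: RawIsotopicCluster,
    isotopologue: int,
    relative_area: float,
) -> RawIsotopicCluster:
    """Add a co-eluting contamination peak at one mass shift.

    *relative_area* is the added area as a fraction of the cluster total —
    e.g. 0.1 at shift 4 mimics the proline m/z 146 co-elution class of bias.
    """
    areas = raw.areas.copy()
    areas[isotopologue] += relative_area * areas.sum()
    return RawIsotopicCluster(raw.fragment, areas, raw.sample)


def _plateau_cids(cfg: "TimecourseSimConfig", condition: str,
                  registry: Registry) -> dict[str, np.ndarray]:
    """Plateau CIDs per fragment, constructed so the acetyl ratio equals
    x_true and the FC equations recover the configured splits exactly."""
    x = cfg.x_true
    s = cfg.second_turn_share
    out: dict[str, np.ndarray] = {}

    def finish(name: str, labeled: Mapping[int, float]) -> None:
        n = registry[name].n_backbone
        cid = np.zeros(n + 1)
        for i, v in labeled.items():
            if v < 0:
                raise ValueError(
                    f"{name}: negative isotopologue {i} ({v:.4g}) — "
                    "inconsistent timecourse configuration"
                )
            cid[i] = v
        cid[0] = 1.0 - cid[1:].sum()
        if cid[0] < 0:
            raise ValueError(f"{name}: labeled fractions exceed 1")
        out[name] = cid

    # Acetyl-pool reporters: M2 from the first TCA turn, M1/M3 from the
    # second turn in the ratio (1-x):x.
    for name in ("Succinate_2TMS_C1C4", "Glutamate_3TMS_C2C5"):
        L = cfg.plateau_labeled[name]
        finish(name, {1: (1 - x) * s * L, 2: (1 - s) * L, 3: x * s * L})

    # Malate C1-C4: PEPc adds M1 on top of the TCA structure; the PEPc share
    # of the labeled pool is exactly phi by construction.
    phi = cfg.phi_pepc_malate[condition]
    L = cfg.plateau_labeled["Malate_3TMS_C1C4"]
    finish("Malate_3TMS_C1C4", {
        1: phi * L + (1 - x) * s * (1 - phi) * L,
        2: (1 - s) * (1 - phi) * L,
        3: x * s * (1 - phi) * L,
    })

    # Citrate C1-C6: fix the TCA-associated isotopologues and solve M1 from
    # the FC identity phi = (m1+m3)/(m1+m2+2*m3+m4).
    phi = cfg.phi_pepc_citrate[condition]
    m2, m3, m4 = cfg.citrate_m2_m3_m4
    m1 = (phi * (m2 + 2 * m3 + m4) - m3) / (1 - phi)
    finish("Citrate_4TMS_C1C6", {1: m1, 2: m2, 3: m3, 4: m4})

    # Serine (2 carbons, labeled at C2 only): M1 chosen so the photosynthesis
    # FC equals the configured share.
    m1_ser = 2.0 * x * cfg.phi_photosynthesis[condition]
    for name in ("Serine_3TMS_C1C2", "Serine_2TMS_C2C3"):
        finish(name, {1: m1_ser})

    # Pyruvate: direct tracer uptake, M3-dominated.
    finish("Pyruvate_MEOXTMS_C1C3", {3: cfg.pyruvate_m3})
    return out


@dataclass(frozen=True)
class TimecourseSimConfig:
    """Design of a U-¹³C-pyruvate light/dark labeling time course.

    Ground-truth defaults place the simulation in the regime the leaf-disc
    experiments report: acetyl-CoA pool M2 fraction 0.4; PEPc share of
    labeled malate 23% (light) / 14% (dark) and of citrate 17% (light) /
    26% (dark); mitochondrial CO₂ feeding ~5% of net photosynthesis in the
    light and none in the dark.  Labeling approaches plateau first-order with
    rate ``rate_per_h`` so isotopologue ratios are time-invariant (isotopic
    pseudo steady state for ratios at every sampled time).
    """

    seed: int
    conditions: tuple[str, ...] = ("light", "dark")
    timepoints: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0)
    replicates: int = 4
    x_true: float = 0.4
    phi_pepc_malate: Mapping[str, float] = field(
        default_factory=lambda: {"light": 0.23, "dark": 0.14})
    phi_pepc_citrate: Mapping[str, float] = field(
        default_factory=lambda: {"light": 0.17, "dark": 0.26})
    phi_photosynthesis: Mapping[str, float] = field(
        default_factory=lambda: {"light": 0.05, "dark": 0.0})
    second_turn_share: float = 0.3
    plateau_labeled: Mapping[str, float] = field(default_factory=lambda: {
        "Succinate_2TMS_C1C4": 0.15,
        "Glutamate_3TMS_C2C5": 0.12,
        "Malate_3TMS_C1C4": 0.17,
    })
    citrate_m2_m3_m4: tuple[float, float, float] = (0.10, 0.02, 0.01)
    pyruvate_m3: float = 0.8
    rate_per_h: float = 1.0
    noise_cv: float = 0.02
    total_area: float = 1e6

    def __post_init__(self) -> None:
        if not 0.0 < self.x_true < 1.0:
            raise ValueError("x_true must be in (0, 1)")
        if self.rate_per_h <= 0:
            raise ValueError("rate_per_h must be positive")
        for m in (self.phi_pepc_malate, self.phi_pepc_citrate,
                  self.phi_photosynthesis):
            for cond, phi in m.items():
                if not 0.0 <= phi < 1.0:
                    raise ValueError(f"pathway split {phi} for {cond} "
                                     "outside [0, 1)")


@dataclass
class TimecourseResult:
    """Output of :func:`simulate_timecourse`: corrected-CID samples, the raw
    clusters they were derived from, and the noiseless ground-truth CIDs."""

    samples: list[LabelingSample]
    raw: list[RawIsotopicCluster]
    truth: dict[tuple[str, float], dict[str, np.ndarray]]


def simulate_timecourse(
    cfg: TimecourseSimConfig,
    registry: Registry | None = None,
) -> TimecourseResult:
    """Simulate a labeling time course and run it through the measurement
    model.

    For every condition/time/replicate, the true fragment CIDs (plateau
    structure scaled by ``1 - exp(-k·t)``) are forward-convolved into raw
    areas, perturbed with lognormal noise, and corrected back — so the
    emitted :class:`LabelingSample` CIDs carry realistic correction noise.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(cfg.seed)
    table = load_isotope_table()
    opts = CorrectionOptions(correct_backbone_natural_abundance=False)
    samples: list[LabelingSample] = []
    raws: list[RawIsotopicCluster] = []
    truth: dict[tuple[str, float], dict[str, np.ndarray]] = {}
    for condition in cfg.conditions:
        plateaus = _plateau_cids(cfg, condition, registry)
        for t in cfg.timepoints:
            g = 1.0 - np.exp(-cfg.rate_per_h * t)
            true_cids = {}
            for name, plateau in plateaus.items():
                cid = plateau * g
                cid[0] = 1.0 - cid[1:].sum()
                true_cids[name] = cid
            truth[(condition, t)] = true_cids
            for rep in range(1, cfg.replicates + 1):
                sample_id = f"{condition}_T{t:g}_rep{rep}"
                cids: dict[str, CID] = {}
                for name, cid in true_cids.items():
                    frag = registry[name]
                    raw = forward_convolve(cid, frag, table, opts,
                                           total_area=cfg.total_area,
                                           sample=sample_id)
                    raw.areas = raw.areas * _lognormal_noise(
                        rng, cfg.noise_cv, raw.areas.size)
                    raws.append(raw)
                    cids[name] = correct_cluster(raw, frag, table, opts)
                samples.append(LabelingSample(
                    condition=condition, time_h=t, replicate=rep, cids=cids))
    return TimecourseResult(samples=samples, raw=raws, truth=truth)
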