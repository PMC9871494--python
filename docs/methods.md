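# Methods

## Scope and data model

`isopascal` operates on three representations:

* **RawIsotopicCluster** — integrated areas `a₀…a_m` of one fragment ion at
  nominal m/z, m/z+1, …, for one sample;
* **CID** — the corrected carbon isotopologue distribution `m₀…mₙ` of the
  fragment's n backbone carbons (non-negative, unit sum), with its mean ¹³C
  enrichment `Σ i·mᵢ/n` and the relative fit residual of the correction;
* **LabelingSample** — condition/time/replicate metadata plus a
  fragment → CID map, the input of the fractional-contribution stage.

The packaged fragment registry (`data/fragments.tsv`) lists 36 TMS/MEOX
fragment ions of 25 organic and amino acids with ion formula, nominal m/z and
retained backbone carbon positions.  Every row is re-validated at load time:
the nominal mass recomputed from the formula must equal the stated m/z.  The
ornithine entry monitors the intact derivative ion (no neutral loss is
defined for it) and is annotated `molecular_ion`; one valine entry carries a
`formula_corrected` note where the stored formula follows the
derivative-minus-loss arithmetic.

## Isotope correction

**Model.** The measured cluster is a linear mixture: a molecule with exactly
*j* labeled backbone carbons contributes the isotopic fine structure of all
its *other* atoms shifted *j* mass units up.  Column *j* of the correction
matrix is therefore the convolution of per-atom natural isotope distributions
over every atom of the ion formula except the n backbone carbons, shifted by
*j*.  All isotopes are projected onto one integer mass-shift ladder
(low-resolution semantics: ¹⁸O and ³⁰Si both land at +2); mass-defect
resolution is out of scope.

**Two tiers.** Natural isotopes of derivative atoms and heteroatoms are always
removed.  Natural ¹³C of the backbone carbons themselves is removed only when
`correct_backbone_natural_abundance` is on: each column *j* is additionally
convolved with the natural-¹³C binomial of its n−j unlabeled backbone
carbons.  The tier is appropriate for unlabeled samples — their corrected CID
is then (1, 0, …, 0) and the residual molecular ¹³C enrichment is 0, which is
the validation criterion for matrix/analytical contamination.  Samples whose
backbone labeling is controlled or informative (binomial reference standards,
tracer experiments) must keep the tier off, otherwise genuine backbone signal
would be subtracted.

**Abundance constants.** Pinned in `data/isotopes.yaml` (¹³C 0.0107,
²H 0.000115, ¹⁵N 0.00364, ¹⁷O 0.00038, ¹⁸O 0.00205, ²⁹Si 0.04685,
³⁰Si 0.03092, ³³S 0.0075, ³⁴S 0.0425, ³⁶S 0.0001) and overridable by a
user-supplied file of the same shape, so corrected outputs are reproducible
against a fixed constant set.

**Tracer purity.** Off by default (purity 1.0).  When set below 1, a binomial
purity kernel over the *j* tracer positions is convolved into column *j*.

**Solver.** `raw ≈ M·x` is solved by non-negative least squares
(`scipy.optimize.nnls`) and *x* is renormalized to unit sum — never a plain
matrix inverse, so non-negativity of fractions is structural rather than a
post-hoc clamp.  The relative residual ‖Mx − a‖/‖a‖ is reported and flagged
above 0.05 (configurable), which is how gross co-elution contaminations
surface.

**Numerical choices.** Isotope patterns are truncated where the trailing tail
mass falls below 1e-9; matrices carry 6 mass shifts beyond the last tracer
isotopologue (>99.9% of pattern mass for the Si-richest registry formulas).
Measured areas beyond the matrix span are ignored with a warning; clusters
shorter than n+1 shifts, or all-zero, are errors.  The noiseless
forward-convolve → correct round trip recovers CIDs to <1e-6 (machine
precision in practice) for every packaged fragment.

## Validation against predictable references

* `expected_binomial_cid(n, p)` — closed-form binomial CID; at p = 0.5 its
  rescaling by 2ⁿ (`rescale_to_pascal`) is row n of Pascal's triangle, the
  natural display for reference-standard comparisons.
* `cid_accuracy` — mean absolute measured−predicted difference per
  isotopologue; the conventional alert level ±0.05 is a configurable default,
  not a hard-coded pass/fail.
* `validate_replicates` — per-isotopologue Student-t confidence intervals
  across replicates (t chosen because reference designs run ~4 biological
  replicates; the distributional form of the interval is a documented default,
  not the only defensible choice).  An isotopologue is flagged when its
  interval excludes the prediction; the report also carries the deviation of
  the replicate-mean enrichment from the predicted enrichment.
* `residual_enrichment_check` — per-fragment mean enrichment of unlabeled
  samples after two-tier correction, flagged above a configurable threshold
  (default 0.05).  Known contamination classes (co-eluting peaks, fixed M1
  additions) are surfaced by these generic flags rather than special-cased
  rules.

## Fractional contributions

At metabolic and isotopic (pseudo) steady state, pathway shares follow from
pathway-specific isotopologues.  The acetyl-CoA pool M2 fraction is defined as
`X = m₃/(m₁+m₃)` of succinate C1–C4 (default; low analytical and biological
variability) or glutamate C2–C5 (cross-check): both fragments inherit the
second-turn M1/M3 ratio of the TCA cycle unchanged.  This identification of
the M3/(M1+M3) ratio with the acetyl-pool M2 fraction is a *definition* within
the network model (PEPc does not touch these fragments), documented rather
than biologically verified by the package.

The malate equation attributes `m₃(1−X)/X` of M1 to the TCA second turn and
the remainder to PEPc; the citrate equation counts M1 as PEPc-only, M2/M4 as
TCA-only and M3 once for each pathway.  Both pairs sum to 1 algebraically —
the equations are implemented in the ratio form under which that identity
holds, which fixes their reading unambiguously.  All FCs depend only on
isotopologue ratios, so corrected areas and fractions are interchangeable
inputs.

Noise can push the malate M1 below its TCA-attributed share; the PEPc share is
then clamped to 0 (TCA to 1) with a warning carrying the raw value, keeping
reported FCs inside [0, 1].

Replicate handling: timepoints at steady state (default 4 h and 6 h) are
pooled at the replicate level (4 replicates × 2 timepoints → 8 values); FCs
are computed per pooled replicate — each using its own replicate-level X, so
correlated correction noise partially cancels — and summarized as mean ± SD.
Significance testing across conditions is left to the user.

The serine-based photosynthesis share recomputes serine's mean enrichment from
M1 alone (`m₁/2`; the monitored two-carbon fragments are labeled only at C2
via the photorespiratory glycine→serine route) and divides by X, the proxy for
the ¹³C/¹²C ratio of mitochondrially released CO₂.  Plastidial pyruvate
dehydrogenase is not modeled as a CO₂ source.

## Synthetic data generators

The generators exist to close the loop simulate → forward-convolve → correct
→ validate/FC against known ground truth; they are test harnesses, not
mechanistic models.

* **Reference extracts** (`simulate_pt_extract`): true CID binomial(n, p),
  defaults p = 0.5, 4 replicates, 2% noise — the standard reference design.
* **Unlabeled samples** (`simulate_natural_abundance`): backbone carbons
  binomial at p = 0.0107.
* **Time courses** (`simulate_timecourse`): plateau CIDs constructed so that
  the succinate/glutamate ratio equals `x_true` and the malate/citrate/serine
  FC equations recover the configured splits exactly before noise; labeled
  fractions approach plateau first-order (`1 − e^{−kt}`, k = 1 h⁻¹ default),
  which keeps isotopologue *ratios* time-invariant — the simplest shape
  consistent with a pseudo steady state reached within a few hours.  Default
  ground truth (X = 0.4; PEPc→malate 23%/14% light/dark; PEPc→citrate
  17%/26%; photosynthesis share 5% light, 0 dark; plateau labeled fractions
  0.12–0.17; second-turn share 0.3) places the simulation in the regime the
  leaf-disc application reports.

**Noise model.** Independent mean-one lognormal multiplication of raw areas
(GC-MS area noise is scale-dependent); the CV is configurable, default 2%.
Per-fragment replicate variability of real data is not tabulated anywhere
authoritative, so these CVs are engineering defaults.  Everything is
deterministic under a fixed seed.

**What the simulators do not emulate** — and hence what green tests do not
prove about real data: chromatographic co-elution and peak integration,
retention-time drift, intensity-dependent detector nonlinearity, natural
backbone ¹³C in the time-course truth (labeled-sample correction leaves
backbone ¹³C in place, so real t = 0 samples show ≈1% enrichment where the
simulator shows 0), biological between-replicate variance beyond area noise,
and any kinetic realism of the TCA network beyond saturating label curves.
Contamination injectors reproduce the bias *classes* (co-eluting peak at one
isotopologue, fixed M1 addition), not specific contaminants.

## Problem sizes

The acceptance script and test suite run the full 36-fragment registry with
4 replicates for reference-standard simulations (144 corrected clusters), 100
random round-trip CIDs per fragment for correction closure, and 2 conditions
× 6 timepoints × 4 replicates × 7 fragments for time courses — sizes chosen
to mirror the reference designs while keeping a full run in seconds.

## Known limitations

* Low-resolution correction only; fragments co-eluting at the same nominal
  mass are detected (flags, residuals), not repaired.
* The Student-t CI and the lognormal noise model are defaults, not claims
  about the true error distribution of any instrument.
* The FC equations assume the network structure described above (no malic
  enzyme flux, no glyoxylate cycle, fumarase reversibility invisible to the
  monitored M1); violations bias the shares without warning.
* X must lie strictly in (0, 1); designs with unlabeled or fully labeled
  acetyl-CoA pools are rejected rather than extrapolated.
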