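"""Correction-matrix construction and NNLS inversion of isotopic clusters."""

from itertools import product

import numpy as np
import pytest

from isopascal.correction import (
    CID,
    CorrectionOptions,
    RawIsotopicCluster,
    build_correction_matrix,
    correct_cluster,
    forward_convolve,
    natural_pattern,
)
from isopascal.validation import expected_binomial_cid

# degenerate table: every element monoisotopic
ZERO_TABLE = {el: [(0, 1.0)] for el in ("C", "H", "N", "O", "S", "Si")}


class TestNaturalPattern:
    def test_degenerate_table_is_delta(self):
        np.testing.assert_allclose(
            natural_pattern({"C": 2}, ZERO_TABLE), [1.0]
        )

    def test_single_atom_returns_own_distribution(self, isotope_table):
        si = natural_pattern({"Si": 1}, isotope_table)
        np.testing.assert_allclose(si, [0.92223, 0.04685, 0.03092])

    def test_two_silicons_match_pairwise_enumeration(self, isotope_table):
        """Self-convolution equals brute-force enumeration over isotope pairs."""
        pairs = isotope_table["Si"]
        expected = np.zeros(5)
        for (s1, a1), (s2, a2) in product(pairs, pairs):
            expected[s1 + s2] += a1 * a2
        got = natural_pattern({"Si": 2}, isotope_table)
        np.testing.assert_allclose(got, expected[: got.size], atol=1e-12)
        assert got[0] == pytest.approx(0.92223**2)

    def test_sums_to_one_up_to_truncation(self, registry, isotope_table):
        for frag in registry:
            p = natural_pattern(frag.ion_formula, isotope_table,
                                exclude_backbone_carbons=frag.n_backbone)
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(p >= 0)

    def test_excluding_more_carbons_than_present_fails(self, isotope_table):
        with pytest.raises(ValueError, match="exclude"):
            natural_pattern({"C": 2, "H": 4}, isotope_table,
                            exclude_backbone_carbons=3)


class TestCorrectionMatrix:
    def test_zeroed_abundances_give_identity(self, registry):
        frag = registry["Malate_3TMS_C1C4"]
        m = build_correction_matrix(frag, ZERO_TABLE)
        n = frag.n_backbone
        np.testing.assert_allclose(m[: n + 1], np.eye(n + 1))
        assert np.all(m[n + 1:] == 0)

    def test_column_zero_equals_natural_pattern_flag_off(
            self, registry, isotope_table):
        for name in ("Succinate_2TMS_C1C4", "Citrate_4TMS_C1C6",
                     "Glycine_3TMS_C2"):
            frag = registry[name]
            m = build_correction_matrix(frag, isotope_table)
            pat = natural_pattern(frag.ion_formula, isotope_table,
                                  exclude_backbone_carbons=frag.n_backbone)
            k = min(m.shape[0], pat.size)
            # matrix columns truncate at the options tolerance (1e-9)
            np.testing.assert_allclose(m[:k, 0], pat[:k], atol=1e-9)

    def test_columns_shifted_copies(self, registry, isotope_table):
        frag = registry["Malate_3TMS_C1C4"]
        m = build_correction_matrix(frag, isotope_table)
        for j in range(1, frag.n_backbone + 1):
            np.testing.assert_allclose(m[j:, j], m[: m.shape[0] - j, 0])

    def test_column_sums_near_one(self, registry, isotope_table):
        opts = CorrectionOptions(correct_backbone_natural_abundance=True)
        for frag in registry:
            for o in (CorrectionOptions(), opts):
                m = build_correction_matrix(frag, isotope_table, o)
                sums = m.sum(axis=0)
                assert np.all(sums <= 1.0 + 1e-12)
                assert np.all(sums > 0.9)

    def test_backbone_flag_forward_matches_natural_molecule(
            self, registry, isotope_table):
        """Backbone tier on, applied to an unlabeled CID, reproduces the
        forward pattern of the molecule at full natural abundance."""
        frag = registry["Malate_3TMS_C1C4"]
        n = frag.n_backbone
        opts = CorrectionOptions(correct_backbone_natural_abundance=True)
        m = build_correction_matrix(frag, isotope_table, opts)
        e0 = np.zeros(n + 1)
        e0[0] = 1.0
        full = natural_pattern(frag.ion_formula, isotope_table)
        k = min(m.shape[0], full.size)
        np.testing.assert_allclose((m @ e0)[:k], full[:k], atol=1e-9)


class TestCorrectCluster:
    def test_roundtrip_random_cids(self, registry, isotope_table, rng):
        for frag in registry:
            for _ in range(5):
                cid = rng.dirichlet(np.ones(frag.n_backbone + 1))
                raw = forward_convolve(cid, frag, isotope_table,
                                       total_area=1e6)
                out = correct_cluster(raw, frag, isotope_table)
                np.testing.assert_allclose(out.fractions, cid, atol=1e-6)
                assert out.residual < 1e-9

    def test_invariants(self, registry, isotope_table, rng):
        frag = registry["Glutamate_3TMS_C2C5"]
        cid = rng.dirichlet(np.ones(frag.n_backbone + 1))
        raw = forward_convolve(cid, frag, isotope_table, total_area=1e5)
        raw.areas *= rng.lognormal(0, 0.05, raw.areas.size)
        out = correct_cluster(raw, frag, isotope_table)
        assert np.all(out.fractions >= 0)
        assert out.fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert 0.0 <= out.mean_enrichment <= 1.0

    def test_unlabeled_sample_two_tier_residual_zero(
            self, registry, isotope_table):
        """A natural-abundance sample corrected with the backbone tier gives
        CID (1, 0, ..., 0) and residual enrichment 0."""
        opts = CorrectionOptions(correct_backbone_natural_abundance=True)
        for name in ("Malate_3TMS_C1C4", "Citrate_4TMS_C1C6",
                     "AlphaAlanine_2TMS_C2C3"):
            frag = registry[name]
            na = expected_binomial_cid(frag.n_backbone, 0.0107)
            raw = forward_convolve(na, frag, isotope_table, total_area=1e6)
            out = correct_cluster(raw, frag, isotope_table, opts)
            expected = np.zeros(frag.n_backbone + 1)
            expected[0] = 1.0
            np.testing.assert_allclose(out.fractions, expected, atol=1e-6)
            assert abs(out.mean_enrichment) < 1e-6

    def test_identity_matrix_halves(self, registry):
        """With monoisotopic abundances, correction just normalizes areas."""
        frag = registry["Glycine_3TMS_C2"]  # n = 1
        raw = RawIsotopicCluster(frag.name, np.array([2.0, 2.0]))
        out = correct_cluster(raw, frag, ZERO_TABLE)
        np.testing.assert_allclose(out.fractions, [0.5, 0.5])
        assert out.mean_enrichment == pytest.approx(0.5)

    def test_all_zero_areas_rejected(self, registry):
        frag = registry["Glycine_3TMS_C2"]
        raw = RawIsotopicCluster(frag.name, np.zeros(4))
        with pytest.raises(ValueError, match="all-zero"):
            correct_cluster(raw, frag)

    def test_short_cluster_rejected(self, registry):
        frag = registry["Succinate_2TMS_C1C4"]  # n = 4
        raw = RawIsotopicCluster(frag.name, np.ones(3))
        with pytest.raises(ValueError, match="at least"):
            correct_cluster(raw, frag)

    def test_excess_areas_ignored_with_warning(self, registry, isotope_table):
        frag = registry["Glycine_3TMS_C2"]
        cid = np.array([0.7, 0.3])
        raw = forward_convolve(cid, frag, isotope_table, total_area=1e6)
        padded = RawIsotopicCluster(
            frag.name, np.concatenate([raw.areas, [5.0, 5.0]]))
        out = correct_cluster(padded, frag, isotope_table)
        assert any("ignoring" in w for w in out.warnings)
        np.testing.assert_allclose(out.fractions, cid, atol=1e-6)

    def test_high_residual_flagged(self, registry, isotope_table):
        frag = registry["Glycine_3TMS_C2"]
        cid = np.array([0.8, 0.2])
        raw = forward_convolve(cid, frag, isotope_table, total_area=1e6)
        raw.areas[3] += 0.5 * raw.areas.sum()  # gross contamination
        out = correct_cluster(raw, frag, isotope_table)
        assert any("residual" in w for w in out.warnings)

    def test_noise_degrades_gracefully(self, registry, isotope_table):
        """Mean absolute CID error grows with area noise but stays below 0.05
        at 2% CV across the registry."""
        rng = np.random.default_rng(7)
        mads = {}
        for cv in (0.0, 0.02, 0.10):
            errs = []
            for frag in registry:
                cid = expected_binomial_cid(frag.n_backbone, 0.5)
                raw = forward_convolve(cid, frag, isotope_table,
                                       total_area=1e6)
                raw.areas *= np.exp(
                    rng.normal(0, cv, raw.areas.size)) if cv else 1.0
                out = correct_cluster(raw, frag, isotope_table)
                errs.append(np.abs(out.fractions - cid).mean())
            mads[cv] = np.mean(errs)
        assert mads[0.0] < mads[0.02] < mads[0.10]
        assert mads[0.02] < 0.05


class TestPurityKernel:
    def test_purity_matrix_roundtrip(self, registry, isotope_table, rng):
        frag = registry["Aspartate_2TMS_C2C4"]
        opts = CorrectionOptions(tracer_purity=0.99)
        cid = rng.dirichlet(np.ones(frag.n_backbone + 1))
        raw = forward_convolve(cid, frag, isotope_table, opts, total_area=1e6)
        out = correct_cluster(raw, frag, isotope_table, opts)
        np.testing.assert_allclose(out.fractions, cid, atol=1e-6)

    def test_impure_fully_labeled_leaks_down(self, registry, isotope_table):
        """At purity < 1 a fully labeled molecule shows intensity below the
        top mass shift."""
        frag = registry["Glycine_3TMS_C2"]
        pure = build_correction_matrix(frag, isotope_table,
                                       CorrectionOptions())
        impure = build_correction_matrix(
            frag, isotope_table, CorrectionOptions(tracer_purity=0.9))
        assert impure[0, 1] > pure[0, 1]  # M0 signal from the M1 column

    def test_invalid_options(self):
        with pytest.raises(ValueError):
            CorrectionOptions(tracer_purity=0.0)
        with pytest.raises(ValueError):
            CorrectionOptions(tolerance=-1.0)


def test_cid_invariants_enforced():
    with pytest.raises(ValueError, match="sum"):
        CID("x", np.array([0.5, 0.4]), mean_enrichment=0.4)
    with pytest.raises(ValueError, match="negative"):
        CID("x", np.array([1.1, -0.1]), mean_enrichment=0.0)
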