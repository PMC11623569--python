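"""Transcript-level quantities: strength, TPM, contrasts, correlation."""

import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from psiscan.io_formats import AnnotationSet, Gene
from psiscan.psi_calling import PsiCall
from psiscan.quantification import (
    TranscriptPsiProfile,
    assign_pus,
    differential_stress,
    pairing_class,
    profile_transcripts,
    psi_strength,
    sites_vs_abundance,
    tpm,
)

from conftest import spearman_no_ties_oracle


class TestPsiStrength:
    @pytest.mark.parametrize(
        "fractions,expected", [([0.10, 0.25], 0.35), ([], 0.0), ([0.07], 0.07)]
    )
    def test_definitional_sum(self, fractions, expected):
        assert psi_strength(fractions) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            psi_strength([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), max_size=12))
    @settings(derandomize=True, max_examples=100)
    def test_permutation_invariant_and_additive(self, fractions):
        shuffled = list(fractions)
        random.Random(0).shuffle(shuffled)
        assert psi_strength(shuffled) == pytest.approx(psi_strength(fractions))
        k = len(fractions) // 2
        assert psi_strength(fractions) == pytest.approx(
            psi_strength(fractions[:k]) + psi_strength(fractions[k:])
        )


class TestTpm:
    def test_hand_computed_two_gene_example(self):
        # rates 11/1000 = 0.011 and 21/2000 = 0.0105
        result = tpm({"g1": 10, "g2": 20}, {"g1": 1000, "g2": 2000})
        assert result["g1"] == pytest.approx(0.011 / 0.0215 * 1e6, rel=1e-9)
        assert result["g2"] == pytest.approx(0.0105 / 0.0215 * 1e6, rel=1e-9)

    def test_sums_to_one_million(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(200)]
        counts = pd.DataFrame(
            rng.integers(0, 5000, size=(200, 4)), index=genes,
            columns=["s1", "s2", "s3", "s4"],
        )
        lengths = {g: int(l) for g, l in zip(genes, rng.integers(200, 5000, 200))}
        result = tpm(counts, lengths)
        assert np.allclose(result.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_counts_equal_lengths_give_equal_tpm(self):
        result = tpm({"a": 0, "b": 0, "c": 0}, {"a": 500, "b": 500, "c": 500})
        assert np.allclose(result, 1e6 / 3)

    def test_prefilter_drops_genes_low_in_every_sample(self):
        counts = pd.DataFrame(
            {"s1": [3, 10, 0], "s2": [4, 2, 100]}, index=["low", "mixed", "high"]
        )
        lengths = {"low": 1000, "mixed": 1000, "high": 1000}
        result = tpm(counts, lengths, min_reads_prefilter=5)
        assert list(result.index) == ["mixed", "high"]  # 'mixed' has one sample >= 5
        assert np.allclose(result.sum(axis=0), 1e6)

    def test_missing_length_names_gene(self):
        with pytest.raises(KeyError, match="g2"):
            tpm({"g1": 5, "g2": 5}, {"g1": 100})


def profiles_from_strengths(strengths):
    """One single-site profile per gene with the given strength."""
    return {
        g: TranscriptPsiProfile(gene_id=g, length=1000, sites=[(1, s)] if s else [])
        for g, s in strengths.items()
    }


class TestProfileTranscripts:
    ANN = AnnotationSet(
        [Gene("gPlus", "chr1", 100, 500, "+"), Gene("gMinus", "chr1", 600, 900, "-")]
    )

    def test_calls_assigned_by_interval_and_strand(self):
        calls = [
            PsiCall("chr1", 250, "+", 0.2, 0.0, 0.2),
            PsiCall("chr1", 700, "+", 0.3, 0.0, 0.3),  # antisense to gMinus
            PsiCall("chr1", 50, "+", 0.4, 0.0, 0.4),   # intergenic
        ]
        profiles = profile_transcripts(calls, self.ANN)
        assert profiles["gPlus"].psi_strength == pytest.approx(0.2)
        assert profiles["gMinus"].psi_strength == 0.0  # sense-only by default

    def test_every_gene_gets_a_profile(self):
        profiles = profile_transcripts([], self.ANN)
        assert set(profiles) == {"gPlus", "gMinus"}
        assert all(p.n_sites == 0 for p in profiles.values())

    def test_sites_per_kb(self):
        calls = [PsiCall("chr1", p, "+", 0.1, 0.0, 0.1) for p in (150, 250)]
        profiles = profile_transcripts(calls, self.ANN)
        assert profiles["gPlus"].sites_per_kb == pytest.approx(2 * 1000 / 401)


class TestAssignPus:
    def rep(self, strengths):
        return profiles_from_strengths(strengths)

    def test_assigned_when_delta_meets_cutoff_in_both_replicates(self):
        wt = [self.rep({"g": 0.20}), self.rep({"g": 0.22})]
        mut = [self.rep({"g": 0.05}), self.rep({"g": 0.08})]
        (a,) = assign_pus(wt, mut, "truB")
        assert a.assigned
        assert a.delta_strength_per_replicate == pytest.approx((0.15, 0.14))

    def test_one_replicate_below_cutoff_blocks_assignment(self):
        wt = [self.rep({"g": 0.20}), self.rep({"g": 0.22})]
        mut = [self.rep({"g": 0.17}), self.rep({"g": 0.10})]
        (a,) = assign_pus(wt, mut, "truB")
        assert not a.assigned

    def test_identical_profiles_not_assigned(self):
        wt = [self.rep({"g": 0.2})] * 2
        (a,) = assign_pus(wt, wt, "truB")
        assert not a.assigned

    def test_gene_absent_from_mutant_counts_as_zero_strength(self):
        wt = [self.rep({"g": 0.10}), self.rep({"g": 0.12})]
        mut = [self.rep({}), self.rep({})]
        (a,) = assign_pus(wt, mut, "truB")
        assert a.assigned

    def test_replicate_mismatch_raises(self):
        with pytest.raises(ValueError, match="replicate"):
            assign_pus([self.rep({"g": 0.1})], [self.rep({"g": 0.1})] * 2, "truA")

    def test_raising_min_delta_never_adds_assignments(self):
        rng = random.Random(5)
        wt = [self.rep({f"g{i}": rng.random() * 0.5 for i in range(30)})
              for _ in range(2)]
        mut = [self.rep({f"g{i}": rng.random() * 0.5 for i in range(30)})
               for _ in range(2)]
        assigned = {}
        for delta in (0.01, 0.05, 0.10, 0.20):
            assigned[delta] = {
                a.gene_id for a in assign_pus(wt, mut, "x", min_delta=delta) if a.assigned
            }
        assert assigned[0.20] <= assigned[0.10] <= assigned[0.05] <= assigned[0.01]


class TestDifferentialStress:
    def rep(self, strengths):
        return profiles_from_strengths(strengths)

    def test_increased_in_both_replicates_reported(self):
        df = differential_stress(
            [self.rep({"g": 0.12}), self.rep({"g": 0.09})],
            [self.rep({"g": 0.0}), self.rep({"g": 0.0})],
        )
        assert bool(df.loc["g", "increased"])
        assert not bool(df.loc["g", "review_flag"])

    def test_one_replicate_below_cutoff_not_reported(self):
        df = differential_stress(
            [self.rep({"g": 0.12}), self.rep({"g": 0.03})],
            [self.rep({"g": 0.0}), self.rep({"g": 0.0})],
        )
        assert not bool(df.loc["g", "increased"])

    def test_stress_equal_control_not_reported(self):
        reps = [self.rep({"g": 0.3}), self.rep({"g": 0.3})]
        df = differential_stress(reps, reps)
        assert not bool(df.loc["g", "increased"])

    def test_borderline_control_strength_flagged_for_review(self):
        # control strength 0.04 >= min_delta/2: reported but flagged
        df = differential_stress(
            [self.rep({"g": 0.15}), self.rep({"g": 0.15})],
            [self.rep({"g": 0.04}), self.rep({"g": 0.04})],
        )
        assert bool(df.loc["g", "increased"])
        assert bool(df.loc["g", "review_flag"])


class TestPairingClass:
    @pytest.mark.parametrize(
        "structure,pos,expected",
        [("((...))", 3, "unpaired"), ("((...))", 1, "paired"), ("((...))", 7, "paired")],
    )
    def test_symbol_mapping(self, structure, pos, expected):
        assert pairing_class(structure, pos) == expected

    def test_out_of_bounds_position_raises(self):
        with pytest.raises(IndexError):
            pairing_class("(...)", 6)

    def test_unbalanced_structure_warns_but_classifies(self):
        with pytest.warns(UserWarning, match="unbalanced"):
            assert pairing_class("((..", 3) == "unpaired"


class TestSitesVsAbundance:
    def profile(self, gene, n_sites, frac, tpm_value, length=1000):
        return TranscriptPsiProfile(
            gene_id=gene, length=length,
            sites=[(i + 1, frac) for i in range(n_sites)], tpm=tpm_value,
        )

    def test_monotone_relation_gives_rho_one(self):
        profiles = [self.profile(f"g{i}", i + 1, 0.1 * (i + 1), 100.0 * (i + 1))
                    for i in range(5)]
        result = sites_vs_abundance(profiles)
        assert result["rho_sites"] == pytest.approx(1.0)
        assert result["rho_level"] == pytest.approx(1.0)

    def test_decreasing_relation_gives_rho_minus_one(self):
        profiles = [self.profile(f"g{i}", i + 1, 0.1, 1000.0 / (i + 1))
                    for i in range(5)]
        assert sites_vs_abundance(profiles)["rho_sites"] == pytest.approx(-1.0)

    def test_matches_rank_formula_without_ties(self):
        rng = random.Random(11)
        densities = rng.sample(range(1, 100), 5)
        tpms = rng.sample(range(1, 1000), 5)
        profiles = [
            self.profile(f"g{i}", d, 0.1 * (i + 1), float(t), length=1000)
            for i, (d, t) in enumerate(zip(densities, tpms))
        ]
        expected = spearman_no_ties_oracle(
            [p.sites_per_kb for p in profiles], [p.tpm for p in profiles]
        )
        assert sites_vs_abundance(profiles)["rho_sites"] == pytest.approx(expected)

    def test_constant_vector_reported_missing(self):
        profiles = [self.profile(f"g{i}", 2, 0.1, 50.0 * (i + 1)) for i in range(4)]
        result = sites_vs_abundance(profiles)
        assert result["rho_sites"] is None  # identical density everywhere
        assert result["rho_level"] is None

    def test_fewer_than_three_profiles_rejected(self):
        with pytest.raises(ValueError):
            sites_vs_abundance([self.profile("g", 1, 0.1, 5.0)])
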