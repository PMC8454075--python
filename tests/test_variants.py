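import numpy as np
import pytest

from umscan import (
    ArtifactCategory,
    CohortDesign,
    InfiniumType,
    ProbeDesign,
    Site,
    Strand,
    VariantRecord,
    classify_cpg_sbe_snp,
    classify_multiallelic,
    enumerate_categories,
    estimate_haplotype_freqs,
    estimate_maf,
    hwe_proportions,
    internal_cpg_failure_adjustment,
    predict_probe_body_snp,
)

CPG = 100  # plus-strand C coordinate used throughout


def design(itype=InfiniumType.I_GREEN, strand=Strand.PLUS, n_internal=0):
    return ProbeDesign("cgT", itype, strand, "chr1", CPG, n_internal)


def var(pos, ref, alt):
    return VariantRecord("chr1", pos, ref, alt)


# Frozen mechanistic enumeration: (infinium_type, strand, site, ref, alt) ->
# (category, flags).  Alleles are plus-strand; the classifier is a pure
# function so this table is its complete regression oracle.
FROZEN = {
    ("I_RED", "+", "CPG_C", "C", "A"): ("SNP_EQ_PF", ""),
    ("I_RED", "+", "CPG_C", "C", "G"): ("SNP_EQ_M", ""),
    ("I_RED", "+", "CPG_C", "C", "T"): ("SNP_EQ_U", ""),
    ("I_RED", "+", "CPG_G", "G", "A"): ("SNP_EQ_U", "near_3prime_mismatch"),
    ("I_RED", "+", "CPG_G", "G", "C"): ("SNP_EQ_U", "near_3prime_mismatch"),
    ("I_RED", "+", "CPG_G", "G", "T"): ("SNP_EQ_U", "near_3prime_mismatch"),
    ("I_RED", "+", "SBE", "A", "C"): ("NO_CHANNEL_CHANGE", ""),
    ("I_RED", "+", "SBE", "A", "G"): ("CHANNEL_SWITCH", ""),
    ("I_RED", "+", "SBE", "A", "T"): ("NO_CHANNEL_CHANGE", ""),
    ("I_RED", "+", "SBE", "C", "A"): ("NO_CHANNEL_CHANGE", ""),
    ("I_RED", "+", "SBE", "C", "G"): ("CHANNEL_SWITCH", ""),
    ("I_RED", "+", "SBE", "C", "T"): ("NO_CHANNEL_CHANGE", "bisulfite_indistinguishable"),
    ("I_RED", "+", "SBE", "G", "A"): ("CHANNEL_SWITCH", ""),
    ("I_RED", "+", "SBE", "G", "C"): ("CHANNEL_SWITCH", ""),
    ("I_RED", "+", "SBE", "G", "T"): ("CHANNEL_SWITCH", ""),
    ("I_RED", "+", "SBE", "T", "A"): ("NO_CHANNEL_CHANGE", ""),
    ("I_RED", "+", "SBE", "T", "C"): ("NO_CHANNEL_CHANGE", "bisulfite_indistinguishable"),
    ("I_RED", "+", "SBE", "T", "G"): ("CHANNEL_SWITCH", ""),
    ("I_RED", "-", "CPG_C", "G", "A"): ("SNP_EQ_U", ""),
    ("I_RED", "-", "CPG_C", "G", "C"): ("SNP_EQ_M", ""),
    ("I_RED", "-", "CPG_C", "G", "T"): ("SNP_EQ_PF", ""),
    ("I_RED", "-", "CPG_G", "C", "A"): ("SNP_EQ_U", "near_3prime_mismatch"),
    ("I_RED", "-", "CPG_G", "C", "G"): ("SNP_EQ_U", "near_3prime_mismatch"),
    ("I_RED", "-", "CPG_G", "C", "T"): ("SNP_EQ_U", "near_3prime_mismatch"),
    ("I_RED", "-", "SBE", "A", "C"): ("CHANNEL_SWITCH", ""),
    ("I_RED", "-", "SBE", "A", "G"): ("NO_CHANNEL_CHANGE", "bisulfite_indistinguishable"),
    ("I_RED", "-", "SBE", "A", "T"): ("NO_CHANNEL_CHANGE", ""),
    ("I_RED", "-", "SBE", "C", "A"): ("CHANNEL_SWITCH", ""),
    ("I_RED", "-", "SBE", "C", "G"): ("CHANNEL_SWITCH", ""),
    ("I_RED", "-", "SBE", "C", "T"): ("CHANNEL_SWITCH", ""),
    ("I_RED", "-", "SBE", "G", "A"): ("NO_CHANNEL_CHANGE", "bisulfite_indistinguishable"),
    ("I_RED", "-", "SBE", "G", "C"): ("CHANNEL_SWITCH", ""),
    ("I_RED", "-", "SBE", "G", "T"): ("NO_CHANNEL_CHANGE", ""),
    ("I_RED", "-", "SBE", "T", "A"): ("NO_CHANNEL_CHANGE", ""),
    ("I_RED", "-", "SBE", "T", "C"): ("CHANNEL_SWITCH", ""),
    ("I_RED", "-", "SBE", "T", "G"): ("NO_CHANNEL_CHANGE", ""),
    ("II", "+", "CPG_C", "C", "A"): ("SNP_EQ_U", ""),
    ("II", "+", "CPG_C", "C", "G"): ("SNP_EQ_M", ""),
    ("II", "+", "CPG_C", "C", "T"): ("SNP_EQ_U", ""),
    ("II", "+", "CPG_G", "G", "A"): ("SNP_EQ_PF", ""),
    ("II", "+", "CPG_G", "G", "C"): ("SNP_EQ_PF", ""),
    ("II", "+", "CPG_G", "G", "T"): ("SNP_EQ_PF", ""),
    ("II", "-", "CPG_C", "G", "A"): ("SNP_EQ_U", ""),
    ("II", "-", "CPG_C", "G", "C"): ("SNP_EQ_M", ""),
    ("II", "-", "CPG_C", "G", "T"): ("SNP_EQ_U", ""),
    ("II", "-", "CPG_G", "C", "A"): ("SNP_EQ_PF", ""),
    ("II", "-", "CPG_G", "C", "G"): ("SNP_EQ_PF", ""),
    ("II", "-", "CPG_G", "C", "T"): ("SNP_EQ_PF", ""),
}


class TestClassification:
    def test_type_i_plus_c_to_t_disguises_as_unmethylated(self):
        call = classify_cpg_sbe_snp(design(), var(CPG, "C", "T"))
        assert call.category is ArtifactCategory.SNP_EQ_U and call.site is Site.CPG_C

    def test_type_i_minus_g_to_a_disguises_as_unmethylated(self):
        # the minus-strand probe reads the plus G position as its CpG C
        call = classify_cpg_sbe_snp(
            design(strand=Strand.MINUS), var(CPG + 1, "G", "A")
        )
        assert call.category is ArtifactCategory.SNP_EQ_U and call.site is Site.CPG_C

    def test_sbe_channel_group_swap_switches_channel(self):
        call = classify_cpg_sbe_snp(design(), var(CPG - 1, "G", "A"))
        assert call.category is ArtifactCategory.CHANNEL_SWITCH and call.site is Site.SBE

    def test_sbe_within_red_group_keeps_channel(self):
        call = classify_cpg_sbe_snp(design(), var(CPG - 1, "A", "T"))
        assert call.category is ArtifactCategory.NO_CHANNEL_CHANGE

    def test_type_ii_has_no_sbe_site(self):
        call = classify_cpg_sbe_snp(design(itype=InfiniumType.II), var(CPG - 1, "G", "A"))
        assert call.category is ArtifactCategory.NOT_AFFECTED

    def test_variant_outside_sites_not_affected(self):
        call = classify_cpg_sbe_snp(design(), var(CPG + 30, "A", "G"))
        assert call.category is ArtifactCategory.NOT_AFFECTED and call.site is Site.NONE

    def test_reference_must_match_cpg(self):
        with pytest.raises(ValueError, match="expected as"):
            classify_cpg_sbe_snp(design(), var(CPG, "A", "T"))

    def test_enumeration_matches_frozen_table(self):
        table = enumerate_categories()
        got = {
            (r.infinium_type, r.strand, r.site, r.ref, r.alt): (r.category, r.flags)
            for r in table.itertuples()
        }
        # I_GREEN obeys the same strand/site rules as I_RED: channel identity
        # does not enter the category logic
        for key, value in got.items():
            lookup = ("I_RED" if key[0] == "I_GREEN" else key[0],) + key[1:]
            assert value == FROZEN[lookup], f"rule changed for {key}"
        assert len(got) == len(FROZEN) + 36  # I_GREEN duplicates the I_RED block

    def test_expected_k_context_rule(self):
        u_call = classify_cpg_sbe_snp(design(), var(CPG, "C", "T"))
        assert u_call.expected_k is None
        assert u_call.expected_k_in_context(region_methylated=True) == 3
        assert u_call.expected_k_in_context(region_methylated=False) == 1
        pf_call = classify_cpg_sbe_snp(design(), var(CPG, "C", "A"))
        assert pf_call.expected_k == 2

    def test_cpg_deleting_deletion_is_failure_candidate(self):
        call = classify_cpg_sbe_snp(design(), VariantRecord("chr1", CPG - 1, "ACG", "A"))
        assert call.category is ArtifactCategory.SNP_EQ_PF and "indel" in call.flags

    def test_other_indels_unresolved(self):
        call = classify_cpg_sbe_snp(design(), VariantRecord("chr1", CPG, "C", "CTT"))
        assert call.category is ArtifactCategory.UNRESOLVED_INDEL

    def test_triallelic_indistinguishable_pair_flagged(self):
        # on a type II probe both C>T and C>A read as the unmethylated allele
        calls = classify_multiallelic(
            design(itype=InfiniumType.II), "chr1", CPG, "C", ["T", "A"]
        )
        assert all("triallelic_collapsed" in c.flags for c in calls)
        calls2 = classify_multiallelic(design(), "chr1", CPG, "C", ["T", "G"])
        assert all("triallelic_collapsed" not in c.flags for c in calls2)


class TestProbeBodySnp:
    def test_ct_on_plus_strand_is_bisulfite_masked(self):
        eff = predict_probe_body_snp(design(), var(CPG + 10, "C", "T"), dist_3prime=2)
        assert eff.bisulfite_masked and not eff.failure_risk

    def test_far_snps_carry_no_failure_risk(self):
        eff = predict_probe_body_snp(design(), var(CPG + 25, "G", "A"), dist_3prime=20)
        assert not eff.bisulfite_masked and not eff.failure_risk

    def test_near_unmasked_snp_risks_failure(self):
        eff = predict_probe_body_snp(design(), var(CPG + 5, "G", "A"), dist_3prime=1)
        assert eff.failure_risk

    def test_ga_masked_on_minus_strand_only(self):
        minus = design(strand=Strand.MINUS)
        assert predict_probe_body_snp(minus, var(CPG + 5, "G", "A"), 2).bisulfite_masked
        assert not predict_probe_body_snp(minus, var(CPG + 5, "C", "T"), 2).bisulfite_masked


class TestInternalCpgAdjustment:
    def _u_call(self, itype=InfiniumType.I_GREEN):
        return classify_cpg_sbe_snp(design(itype=itype), var(CPG, "C", "T"))

    def test_methylated_region_with_internal_cpgs_becomes_failure(self):
        adj = internal_cpg_failure_adjustment(
            self._u_call(), design(n_internal=3), region_methylated=True
        )
        assert adj.category is ArtifactCategory.SNP_EQ_PF and adj.expected_k == 2
        assert "internal_cpg_failure" in adj.flags

    def test_unmethylated_region_unchanged(self):
        call = self._u_call()
        assert internal_cpg_failure_adjustment(call, design(n_internal=3), False) is call

    def test_type_ii_unchanged(self):
        call = classify_cpg_sbe_snp(design(itype=InfiniumType.II), var(CPG, "C", "T"))
        assert (
            internal_cpg_failure_adjustment(call, design(itype=InfiniumType.II, n_internal=3), True)
            is call
        )


def _cohort(n_pairs):
    ids, pairs = [], {}
    for p in range(n_pairs):
        for s in "ab":
            sid = f"t{p:04d}{s}"
            ids.append(sid)
            pairs[sid] = f"p{p:04d}"
    return CohortDesign(ids, pairs), ids


class TestMafEstimation:
    GMAP = {0: "BB", 1: "AB", 2: "AA"}

    def _assignments(self, genotype_per_pair, discord=()):
        # label = 2 - alt dose so that AA maps to the most methylated cluster
        labels = np.repeat(2 - np.asarray(genotype_per_pair), 2)
        for i in discord:
            labels[2 * i + 1] = (labels[2 * i + 1] + 1) % 3
        return labels

    def test_plug_in_formula_exact(self):
        counts = [0] * 64 + [1] * 32 + [2] * 4
        cohort, ids = _cohort(100)
        est = estimate_maf(dict(zip(ids, self._assignments(counts))), self.GMAP, cohort)
        assert est.maf == pytest.approx(0.2) and est.n_pairs_used == 100
        assert not est.flipped

    def test_all_reference_homozygotes(self):
        cohort, ids = _cohort(10)
        est = estimate_maf(dict(zip(ids, self._assignments([0] * 10))), self.GMAP, cohort)
        assert est.maf == 0.0

    def test_discordant_pairs_excluded(self):
        counts = [0] * 8 + [2] * 2
        cohort, ids = _cohort(10)
        est = estimate_maf(
            dict(zip(ids, self._assignments(counts, discord=[0]))), self.GMAP, cohort
        )
        assert est.n_pairs_used == 9
        assert est.concordance.to_numpy().sum() == 10

    def test_major_allele_map_gets_flipped_and_flagged(self):
        counts = [2] * 9 + [0] * 1  # alt is actually the major allele
        cohort, ids = _cohort(10)
        est = estimate_maf(dict(zip(ids, self._assignments(counts))), self.GMAP, cohort)
        assert est.flipped and est.maf == pytest.approx(0.1)

    def test_uncovered_cluster_label_rejected(self):
        cohort, ids = _cohort(4)
        with pytest.raises(ValueError, match="cover"):
            estimate_maf(dict(zip(ids, [5] * 8)), self.GMAP, cohort)

    def test_recovery_from_simulated_cohort(self, cohort400):
        from umscan import Pattern, fit_bgmm
        from .conftest import simulate_probe_matrix

        cohort, factors = cohort400
        intens, probes = simulate_probe_matrix(
            Pattern.SNP_EQ_U, cohort, factors, seed=31, maf=0.3
        )
        model = fit_bgmm(intens.points("cg00000"), 3, seed=0)
        assign = dict(zip(cohort.sample_ids, model.assignments))
        est = estimate_maf(assign, self.GMAP, cohort)
        assert est.maf == pytest.approx(0.3, abs=0.05)


@pytest.mark.parametrize(
    "maf,expected",
    [(0.0, (1, 0, 0)), (0.5, (0.25, 0.5, 0.25)), (0.2, (0.64, 0.32, 0.04))],
)
def test_hwe_proportions(maf, expected):
    assert hwe_proportions(maf) == pytest.approx(expected)


IDENTITY_DMAP = {
    pair: idx
    for idx, pair in enumerate(
        (i, j) for i in range(4) for j in range(i, 4)
    )
}


class TestHaplotypeFrequencies:
    def test_point_mass_on_one_diplotype(self):
        counts = np.zeros(10)
        counts[IDENTITY_DMAP[(0, 0)]] = 400
        with pytest.warns(UserWarning, match="not identifiable"):
            est = estimate_haplotype_freqs(counts, IDENTITY_DMAP, seed=0)
        assert est.freqs[0] == pytest.approx(1.0, abs=1e-6)

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, 10).astype(float)
        est = estimate_haplotype_freqs(counts, IDENTITY_DMAP, seed=2)
        assert est.freqs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_recovery_within_three_multinomial_se(self):
        truth = np.array([0.5, 0.3, 0.15, 0.05])
        rng = np.random.default_rng(7)
        dip = rng.choice(4, size=(400, 2), p=truth)
        dip.sort(axis=1)
        counts = np.zeros(10)
        for i, j in dip:
            counts[IDENTITY_DMAP[(i, j)]] += 1
        est = estimate_haplotype_freqs(counts, IDENTITY_DMAP, seed=1)
        se = np.sqrt(truth * (1 - truth) / 800)
        assert (np.abs(est.freqs - truth) <= 3 * se).all()

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 60, 10).astype(float)
        base = estimate_haplotype_freqs(counts, IDENTITY_DMAP, seed=4)
        perm = [2, 0, 3, 1]
        dmap_perm = {
            tuple(sorted((perm[i], perm[j]))): c
            for (i, j), c in IDENTITY_DMAP.items()
        }
        permuted = estimate_haplotype_freqs(counts, dmap_perm, seed=4)
        assert np.allclose(permuted.freqs[perm], base.freqs, atol=1e-4)

    def test_incomplete_dmap_rejected(self):
        bad = dict(IDENTITY_DMAP)
        bad.pop((2, 3))
        with pytest.raises(ValueError, match="10"):
            estimate_haplotype_freqs(np.ones(10), bad)

    def test_unobserved_haplotype_warns_and_goes_flat(self):
        counts = np.zeros(10)
        counts[IDENTITY_DMAP[(0, 0)]] = 300
        counts[IDENTITY_DMAP[(0, 1)]] = 100
        # haplotypes 2 and 3 only appear in empty clusters
        with pytest.warns(UserWarning, match="not identifiable"):
            est = estimate_haplotype_freqs(counts, IDENTITY_DMAP, seed=5)
        assert est.non_identifiable == (2, 3)
        assert est.freqs[2] == pytest.approx(est.freqs[3])
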