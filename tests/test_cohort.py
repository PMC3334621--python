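"""Positional profiles, arm dominance/switching, ac-pre screen, ablation test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from isomirkit import (
    AcPreThresholds,
    AlignerParams,
    Hairpin,
    MatureAnnotation,
    SampleMeta,
    Tag,
    ablation_report,
    arm_dominance_table,
    build_profile,
    chi_square_2x2,
    detect_arm_switching,
    find_acpre_candidates,
    resample_to_depth,
)
from isomirkit.alignment import AlignedTag, Placement
from isomirkit.annotation import canonical_name
from isomirkit.cohort import candidate_set, profiles_by_tissue

from conftest import random_dna


@pytest.fixture(scope="module")
def hairpin_with_arms():
    rng = np.random.default_rng(300)
    hp = Hairpin("syn-mir-t", random_dna(rng, 100))
    a5 = MatureAnnotation("syn-mir-t", "syn-miR-t", "5p", 8, 29, hp.subseq(8, 29))
    a3 = MatureAnnotation("syn-mir-t", "syn-miR-t", "3p", 55, 76, hp.subseq(55, 76))
    return hp, a5, a3


def _aligned(hp, start, end, sample, mult=1, subs=(), nta="", weight_n=1):
    placements = tuple(
        Placement(hp.id, start, end, subs) for _ in range(1)
    ) * weight_n
    return AlignedTag(
        Tag(hp.subseq(start, end) + nta, mult, sample),
        "adaptor_trimmed", end - start + 1, placements[:weight_n] or placements, nta,
    )


class TestBuildProfile:
    def test_canonical_mass_on_every_position(self, hairpin_with_arms):
        hp, a5, a3 = hairpin_with_arms
        at = _aligned(hp, a5.start, a5.end, "s1", mult=4)
        prof = build_profile([at], hp, [a5, a3])
        for pos in range(a5.start, a5.end + 1):
            assert prof.matrix[pos - 1].sum() == pytest.approx(4.0)
        assert prof.start_hist["5p"] == {a5.start: 4.0}
        assert prof.end_hist["5p"] == {a5.end: 4.0}

    def test_mass_conservation_random(self, hairpin_with_arms):
        hp, a5, a3 = hairpin_with_arms
        rng = np.random.default_rng(7)
        tags = []
        total = 0.0
        for _ in range(40):
            start = int(rng.integers(5, 50))
            end = start + int(rng.integers(20, 24))
            mult = int(rng.integers(1, 6))
            tags.append(_aligned(hp, start, end, "s1", mult=mult))
            total += mult
        prof = build_profile(tags, hp, [a5, a3])
        # per-tag positional mass / span length sums back to tag mass
        assert prof.total_mass == pytest.approx(total)
        hist_mass = sum(sum(h.values()) for h in prof.start_hist.values())
        assert hist_mass == pytest.approx(total)

    def test_substitution_deposits_tag_base(self, hairpin_with_arms):
        hp, a5, a3 = hairpin_with_arms
        pos = 15
        ref = hp.sequence[pos - 1]
        alt = "A" if ref != "A" else "C"
        at = AlignedTag(
            Tag("x" * 22, 3, "s1"), "adaptor_trimmed", 22,
            (Placement(hp.id, 8, 29, ((pos, ref, alt),)),), "",
        )
        prof = build_profile([at], hp, [a5, a3])
        assert prof.matrix[pos - 1, "ACGT".index(alt)] == pytest.approx(3.0)
        assert prof.matrix[pos - 1, "ACGT".index(ref)] == 0.0


SAMPLES = [
    SampleMeta("p1", "placenta", "d1", "SREK"),
    SampleMeta("p2", "placenta", "d1", "WTAK"),
    SampleMeta("h1", "heart", "d2", "SREK"),
    SampleMeta("h2", "heart", "d2", "WTAK"),
]


def _tpm_matrix(ann5, ann3, per_sample):
    """per_sample: {sample: (tpm_5p, tpm_3p)} on the canonical features."""
    rows = {
        canonical_name(ann5): [per_sample[s.sample_id][0] for s in SAMPLES],
        canonical_name(ann3): [per_sample[s.sample_id][1] for s in SAMPLES],
    }
    return pd.DataFrame(rows, index=[s.sample_id for s in SAMPLES]).T


class TestArmDominance:
    def test_log2_ratio_and_eligibility(self, hairpin_with_arms):
        _, a5, a3 = hairpin_with_arms
        mat = _tpm_matrix(a5, a3, {s.sample_id: (100.0, 10.0) for s in SAMPLES})
        table = arm_dominance_table(mat, [a5, a3], SAMPLES, noise_floor=10.0)
        row = table.iloc[0]
        assert row.dominant == "5p"
        assert row.log2_ratio == pytest.approx(math.log2(10))
        assert row.eligible

    def test_below_floor_ineligible(self, hairpin_with_arms):
        _, a5, a3 = hairpin_with_arms
        mat = _tpm_matrix(a5, a3, {s.sample_id: (100.0, 5.0) for s in SAMPLES})
        table = arm_dominance_table(mat, [a5, a3], SAMPLES, noise_floor=10.0)
        assert not table.eligible.any()

    def test_totals_match_hand_summation(self, hairpin_with_arms):
        _, a5, a3 = hairpin_with_arms
        per = {"p1": (10.0, 40.0), "p2": (30.0, 60.0), "h1": (5.0, 1.0), "h2": (7.0, 3.0)}
        mat = _tpm_matrix(a5, a3, per)
        table = arm_dominance_table(mat, [a5, a3], SAMPLES).set_index("tissue")
        assert table.at["placenta", "tpm_5p"] == pytest.approx((10 + 30) / 2)
        assert table.at["heart", "tpm_3p"] == pytest.approx((1 + 3) / 2)


class TestArmSwitching:
    def _dominance(self, rows):
        return pd.DataFrame(
            rows, columns=["hairpin_id", "tissue", "tpm_5p", "tpm_3p",
                           "log2_ratio", "dominant", "eligible"]
        )

    def test_switch_detected(self):
        rows = [("h", t, 100, 10, 3.3, "5p", True) for t in "abcdefghi"]
        rows.append(("h", "j", 10, 100, -3.3, "3p", True))
        out = detect_arm_switching(self._dominance(rows))
        assert out.switched.tolist() == [True]
        assert out.minority_tissues.iloc[0] == "j"

    def test_constant_dominance_not_switched(self):
        rows = [("h", t, 100, 10, 3.3, "5p", True) for t in "abc"]
        out = detect_arm_switching(self._dominance(rows))
        assert out.switched.tolist() == [False]

    def test_single_eligible_tissue_unassessable(self):
        rows = [("h", "a", 100, 10, 3.3, "5p", True),
                ("h", "b", 10, 100, -3.3, "3p", False)]
        out = detect_arm_switching(self._dominance(rows))
        assert out.empty

    def test_invariant_to_tissue_order_and_scaling(self):
        rows = [("h", t, 100 * s, 10 * s, 3.3, "5p", True)
                for t, s in zip("abc", (1, 7, 3))]
        rows.append(("h", "d", 20, 200, -3.3, "3p", True))
        fwd = detect_arm_switching(self._dominance(rows))
        rev = detect_arm_switching(self._dominance(rows[::-1]))
        assert fwd.switched.tolist() == rev.switched.tolist() == [True]


class TestAcPre:
    def _setup(self, hairpin_with_arms, modal_split=False, silent_3p=True,
               ext_fraction=0.25, n_ends=4):
        hp, a5, a3 = hairpin_with_arms
        tags = []
        n = 400
        n_ext = int(n * ext_fraction)
        n_can = n - n_ext
        for sid in ("p1", "p2", "h1", "h2"):
            if modal_split:
                tags.append(_aligned(hp, a5.start, a5.end, sid, mult=n_can // 2))
                tags.append(_aligned(hp, a5.start + 1, a5.end, sid, mult=n_can // 2))
            else:
                tags.append(_aligned(hp, a5.start, a5.end, sid, mult=n_can))
            for j in range(n_ext):
                ext = 2 + (j % n_ends)
                tags.append(_aligned(hp, a5.start, a5.end + ext, sid, mult=1))
        per = {
            s.sample_id: (1e5, 0.0 if silent_3p else 50.0) for s in SAMPLES
        }
        mat = _tpm_matrix(a5, a3, per)
        profiles = profiles_by_tissue(tags, {hp.id: hp}, [a5, a3], SAMPLES)
        return profiles, mat, [a5, a3]

    def test_mir451_like_profile_is_candidate(self, hairpin_with_arms):
        profiles, mat, anns = self._setup(hairpin_with_arms)
        out = find_acpre_candidates(profiles, mat, anns, SAMPLES)
        assert candidate_set(out) == {("syn-mir-t", "5p")}

    def test_expressed_opposite_arm_rejected(self, hairpin_with_arms):
        profiles, mat, anns = self._setup(hairpin_with_arms, silent_3p=False)
        out = find_acpre_candidates(profiles, mat, anns, SAMPLES)
        five_p = out[out.dominant_arm == "5p"]
        assert not five_p.pass_opposite.any()
        assert ("syn-mir-t", "5p") not in candidate_set(out)

    def test_split_modal_start_rejected_on_that_flag(self, hairpin_with_arms):
        profiles, mat, anns = self._setup(hairpin_with_arms, modal_split=True)
        out = find_acpre_candidates(profiles, mat, anns, SAMPLES)
        five_p = out[out.dominant_arm == "5p"]
        assert not five_p.pass_modal5.any()
        assert five_p.pass_opposite.all() and five_p.pass_ext.all()

    def test_tightening_thresholds_is_monotone(self, hairpin_with_arms):
        profiles, mat, anns = self._setup(hairpin_with_arms)
        loose = candidate_set(find_acpre_candidates(
            profiles, mat, anns, SAMPLES, AcPreThresholds()))
        tight = candidate_set(find_acpre_candidates(
            profiles, mat, anns, SAMPLES,
            AcPreThresholds(modal5_min=0.99, ext_fraction_min=0.3,
                            n_distinct_ext_min=5)))
        assert tight <= loose


class TestResample:
    def _tags(self):
        return [Tag("A" * 22, 600, "s"), Tag("C" * 22, 300, "s"), Tag("G" * 22, 100, "s")]

    def test_full_depth_identity(self):
        tags = self._tags()
        assert resample_to_depth(tags, 1000, seed=1) == tags

    def test_seeded_determinism(self):
        tags = self._tags()
        assert resample_to_depth(tags, 400, seed=7) == resample_to_depth(tags, 400, seed=7)

    def test_overdraw_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            resample_to_depth(self._tags(), 1001, seed=1)

    def test_proportions_within_three_sd(self):
        tags = self._tags()
        target = 400
        fracs = np.array([0.6, 0.3, 0.1])
        sd = np.sqrt(fracs * (1 - fracs) * target)
        for seed in range(100):
            out = {t.sequence: t.multiplicity for t in resample_to_depth(tags, target, seed)}
            got = np.array([out.get("A" * 22, 0), out.get("C" * 22, 0), out.get("G" * 22, 0)])
            assert (np.abs(got - fracs * target) <= 3.5 * sd).all()


class TestChiSquare:
    def test_uniform_table_is_zero(self):
        stat, df, p = chi_square_2x2(10, 10, 10, 10)
        assert (stat, df, p) == (0.0, 1, 1.0)

    def test_closed_form_example(self):
        stat, _, _ = chi_square_2x2(10, 20, 20, 10)
        assert stat == pytest.approx(20 / 3, abs=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_contingency_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(1, 500, 4)
        stat, df, p = chi_square_2x2(a, b, c, d)
        o_stat, o_p, o_df, _ = chi2_contingency([[a, b], [c, d]], correction=False)
        assert stat == pytest.approx(o_stat, abs=1e-10)
        assert p == pytest.approx(o_p, abs=1e-10)
        assert df == o_df

    def test_p_decreasing_in_statistic(self):
        stats = [chi_square_2x2(10 + k, 10, 10, 10 + k) for k in (0, 5, 20, 80)]
        ps = [p for _, _, p in stats]
        assert ps == sorted(ps, reverse=True)

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_square_2x2(0, 0, 5, 5)


class TestAblation:
    def _annotations(self, n):
        rng = np.random.default_rng(400)
        anns = []
        for i in range(n):
            hp = Hairpin(f"dre-mir-{i}", random_dna(rng, 90))
            anns.append(
                MatureAnnotation(f"dre-mir-{i}", f"dre-miR-{i}", "5p", 10, 31,
                                 hp.subseq(10, 31))
            )
        return anns

    def test_support_classes(self):
        anns = self._annotations(4)
        canon = [canonical_name(a) for a in anns]
        iso = [c.replace("{" + a.mature_name + "}", "{isomiR}").replace("10_31", "11_31")
               for c, a in zip(canon, anns)]
        wt = pd.Series(
            {canon[0]: 1000.0, canon[1]: 1000.0, canon[2]: 1000.0, canon[3]: 1000.0,
             iso[0]: 200.0, iso[1]: 200.0, iso[2]: 200.0, iso[3]: 200.0,
             "other|{x}|1_21|": 5000.0},
        )
        mut = pd.Series(
            {canon[0]: 0.0,      # complete ablation
             canon[1]: 150.0,    # 85% reduction
             canon[2]: 950.0, iso[2]: 40.0,  # isomiR support only
             canon[3]: 990.0, iso[3]: 195.0,  # unsupported
             iso[0]: 10.0, iso[1]: 30.0,
             "other|{x}|1_21|": 5000.0},
        )
        candidates = [(a.hairpin_id, "5p") for a in anns]
        group, detail = ablation_report(wt, mut, candidates, anns)
        classes = detail.set_index("hairpin_id").support_class
        assert classes["dre-mir-0"] == "complete_ablation"
        assert classes["dre-mir-1"] == "strong_reduction"
        assert classes["dre-mir-2"] == "isomiR_support"
        assert classes["dre-mir-3"] == "unsupported"
        assert group.df == 1 and group.p < 0.0001
        assert group.wt_mass == pytest.approx(4 * 1200.0)

    def test_mutant_equal_to_wildtype_unsupported(self):
        anns = self._annotations(2)
        canon = [canonical_name(a) for a in anns]
        wt = pd.Series({canon[0]: 500.0, canon[1]: 500.0, "other|{x}|1_21|": 1000.0})
        group, detail = ablation_report(
            wt, wt.copy(), [(a.hairpin_id, "5p") for a in anns], anns
        )
        assert group.chi2 == pytest.approx(0.0, abs=1e-12)
        assert (detail.support_class == "unsupported").all()
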