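"""Tests for evidence-code parsing, assignment and five-class combination.

The combining logic is checked against an independent brute-force
evaluator that restates every published combining rule verbatim and is
exercised over an exhaustive enumeration of bounded criteria multisets.
"""
import itertools

import pytest
from hypothesis import given, settings, strategies as st

from armc5curate.acmg import (
    AcmgCriterion, Classification, CriteriaSet, EngineConfig,
    EvidenceProfile, Strength, assign_criteria, combine, concordance,
    default_strength, parse_criteria_string,
)
from armc5curate.hgvs import Consequence

STRICT = EngineConfig(conflict_policy="strict")
CURATED = EngineConfig(conflict_policy="as_curated")


class TestParseCriteriaString:
    def test_concatenated_dialect(self):
        cs = parse_criteria_string("PVS1PM2PP4")
        assert sorted(cs.codes()) == ["PM2", "PP4", "PVS1"]

    def test_modified_pvs1(self):
        cs = parse_criteria_string("PVS1_SPM2PS3PP4")
        assert cs["PVS1"].strength is Strength.STRONG
        assert cs["PVS1"].modified
        assert cs["PVS1"].serialize() == "PVS1_S"
        assert sorted(cs.codes()) == ["PM2", "PP4", "PS3", "PVS1"]

    def test_delimited_dialect(self):
        assert parse_criteria_string("PVS1;PM2; PP4") == parse_criteria_string("PVS1PM2PP4")

    def test_empty(self):
        assert len(parse_criteria_string("")) == 0

    def test_untokenizable_residue_named(self):
        with pytest.raises(ValueError, match="PXX"):
            parse_criteria_string("PVS1PXX")

    def test_serialization_round_trip(self):
        text = "PVS1_S;PM2;PP4"
        assert parse_criteria_string(text).serialize() == text

    def test_duplicate_code_conflicting_strength_rejected(self):
        with pytest.raises(ValueError):
            parse_criteria_string("PVS1PVS1_S")

    def test_fixture_criteria_all_tokenize(self, germline_all):
        for r in germline_all:
            assert len(r.printed_criteria) > 0


def _counts_to_set(pvs, strong, mod, supp, ba1, bs, bp) -> CriteriaSet:
    codes = []
    if pvs:
        codes.append(("PVS1", None))
    codes += [(c, None) for c in ["PS1", "PS3", "PS4"][:strong]]
    codes += [(c, None) for c in ["PM1", "PM2", "PM4", "PM5"][:mod]]
    codes += [(c, None) for c in ["PP1", "PP3", "PP4", "PP5"][:supp]]
    if ba1:
        codes.append(("BA1", None))
    codes += [(c, None) for c in ["BS1", "BS2", "BS3"][:bs]]
    codes += [(c, None) for c in ["BP1", "BP4", "BP6"][:bp]]
    return CriteriaSet(AcmgCriterion.of(c, s) for c, s in codes)


def _oracle(pvs, strong, mod, supp, ba1, bs, bp) -> Classification:
    """Literal restatement of the published combining rules, one rule per line."""
    pathogenic = any([
        pvs and strong >= 1,
        pvs and mod >= 2,
        pvs and mod == 1 and supp == 1,
        pvs and supp >= 2,
        strong >= 2,
        strong == 1 and mod >= 3,
        strong == 1 and mod == 2 and supp >= 2,
        strong == 1 and mod == 1 and supp >= 4,
    ])
    likely_pathogenic = any([
        pvs and mod == 1,
        strong == 1 and 1 <= mod <= 2,
        strong == 1 and supp >= 2,
        mod >= 3,
        mod == 2 and supp >= 2,
        mod == 1 and supp >= 4,
    ])
    benign = ba1 or bs >= 2
    likely_benign = (bs == 1 and bp >= 1) or bp >= 2
    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return Classification.VUS
    if pathogenic:
        return Classification.PATHOGENIC
    if likely_pathogenic:
        return Classification.LIKELY_PATHOGENIC
    if benign:
        return Classification.BENIGN
    if likely_benign:
        return Classification.LIKELY_BENIGN
    return Classification.VUS


class TestCombineStrict:
    def test_exhaustive_against_brute_force_oracle(self, strict_cfg):
        """combine(strict) equals the rule-by-rule evaluator on all bounded sets."""
        space = itertools.product(
            (0, 1), (0, 1, 2), (0, 1, 2, 3), (0, 1, 2, 3, 4),
            (0, 1), (0, 1, 2), (0, 1, 2))
        n = 0
        for pvs, strong, mod, supp, ba1, bs, bp in space:
            cs = _counts_to_set(pvs, strong, mod, supp, ba1, bs, bp)
            assert combine(cs, strict_cfg) is _oracle(pvs, strong, mod, supp, ba1, bs, bp), (
                pvs, strong, mod, supp, ba1, bs, bp)
            n += 1
        assert n == 2160

    def test_modified_pvs1_counts_as_strong(self, strict_cfg):
        # PVS1_S + PM2 behaves like one strong + one moderate
        cs = parse_criteria_string("PVS1_SPM2")
        assert combine(cs, strict_cfg) is Classification.LIKELY_PATHOGENIC
        cs = parse_criteria_string("PVS1_SPM2PS3PP4")
        assert combine(cs, strict_cfg) is Classification.PATHOGENIC

    @pytest.mark.parametrize("text,expected", [
        ("PVS1PM2PP4", Classification.PATHOGENIC),
        ("PVS1PM2", Classification.LIKELY_PATHOGENIC),
        ("PM2", Classification.VUS),
        ("PM2PM5PP3PP5PS3PP4", Classification.PATHOGENIC),
        ("", Classification.VUS),
    ])
    def test_table_examples(self, text, expected, strict_cfg):
        assert combine(parse_criteria_string(text), strict_cfg) is expected


_PATH_CODES = ["PVS1", "PS1", "PS3", "PM1", "PM2", "PM4", "PM5",
               "PP1", "PP3", "PP4", "PP5"]


@st.composite
def pathogenic_sets(draw):
    codes = draw(st.sets(st.sampled_from(_PATH_CODES), max_size=8))
    return CriteriaSet(AcmgCriterion.of(c) for c in codes)


class TestCombineProperties:
    @settings(max_examples=300, derandomize=True)
    @given(pathogenic_sets(), st.sampled_from(_PATH_CODES))
    def test_monotonicity_pathogenic_side(self, cs, extra):
        """With no benign evidence, adding pathogenic evidence never lowers the class."""
        before = combine(cs, STRICT)
        augmented = CriteriaSet(list(cs) + [AcmgCriterion.of(extra)])
        assert combine(augmented, STRICT) >= before

    @settings(max_examples=300, derandomize=True)
    @given(st.integers(0, 1), st.integers(0, 2), st.integers(0, 3),
           st.integers(0, 4), st.integers(0, 2), st.integers(0, 2),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, pvs, strong, mod, supp, bs, bp, rnd):
        """Only the multiset of effective strengths matters, not code identity."""
        pools = {
            "strong": ["PS1", "PS2", "PS3", "PS4"],
            "mod": ["PM1", "PM2", "PM3", "PM4", "PM5", "PM6"],
            "supp": ["PP1", "PP2", "PP3", "PP4", "PP5"],
            "bs": ["BS1", "BS2", "BS3", "BS4"],
            "bp": ["BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7"],
        }

        def build():
            codes = ["PVS1"] if pvs else []
            for name, k in (("strong", strong), ("mod", mod), ("supp", supp),
                            ("bs", bs), ("bp", bp)):
                codes += rnd.sample(pools[name], k)
            return CriteriaSet(AcmgCriterion.of(c) for c in codes)

        assert combine(build(), STRICT) is combine(build(), STRICT)
        assert combine(build(), CURATED) is combine(build(), CURATED)


class TestCombineAsCurated:
    @pytest.mark.parametrize("text,expected", [
        ("BS3", Classification.LIKELY_BENIGN),          # single BS suffices
        ("BS2BP6PS3", Classification.LIKELY_BENIGN),    # benign precedence
        ("BS1BP4BP6", Classification.LIKELY_BENIGN),
        ("BA1BP4BP3BP6", Classification.BENIGN),
        ("PVS1PM2PP4", Classification.PATHOGENIC),
        ("PVS1_SPM2PP4", Classification.LIKELY_PATHOGENIC),
        ("PM2", Classification.VUS),
    ])
    def test_precedence_examples(self, text, expected, curated_cfg):
        assert combine(parse_criteria_string(text), curated_cfg) is expected

    def test_polymorphism_override_forces_benign(self, curated_cfg):
        # BS1+BP would only reach likely benign; the frequency flag forces benign
        cs = parse_criteria_string("BS1BP4BP6")
        assert combine(cs, curated_cfg, polymorphism=True) is Classification.BENIGN

    def test_strict_does_not_apply_override(self, strict_cfg):
        cs = parse_criteria_string("BS1BP4BP6")
        assert combine(cs, strict_cfg, polymorphism=True) is Classification.LIKELY_BENIGN


class TestAssignCriteria:
    def test_truncating_with_second_hit(self):
        ev = EvidenceProfile(maf=None, somatic_second_hit=True, phenotype_specific=True)
        cs = assign_criteria(Consequence.NONSENSE, 267, ev)
        assert sorted(cs.codes()) == ["PM2", "PP4", "PS3", "PVS1"]
        assert not cs["PVS1"].modified
        assert cs["PS3"].provenance == "somatic_second_hit"

    def test_late_truncation_downgrades_pvs1(self):
        ev = EvidenceProfile(maf=None, phenotype_specific=True)
        cs = assign_criteria(Consequence.NONSENSE, 730, ev)
        assert cs["PVS1"].strength is Strength.STRONG
        assert cs.serialize().startswith("PVS1_S")
        assert sorted(cs.codes()) == ["PM2", "PP4", "PVS1"]

    def test_polymorphism_frequency_pathway(self):
        ev = EvidenceProfile(maf=0.03, insilico="benign")
        cs = assign_criteria(Consequence.MISSENSE, 507, ev)
        assert "BS1" in cs and "BP4" in cs
        assert "PM2" not in cs and "BA1" not in cs

    def test_ba1_above_five_percent(self):
        cs = assign_criteria(Consequence.MISSENSE, 14, EvidenceProfile(maf=0.06))
        assert "BA1" in cs and "BS1" not in cs

    def test_functional_benign_gives_bs3_not_ps3(self):
        ev = EvidenceProfile(functional_damaging="no", somatic_second_hit=True)
        cs = assign_criteria(Consequence.MISSENSE, 643, ev)
        assert "BS3" in cs and "PS3" not in cs

    def test_inframe_repeat_vs_nonrepeat(self):
        in_repeat = assign_criteria(
            Consequence.INFRAME_INDEL, 23, EvidenceProfile(inframe_in_repeat=True))
        outside = assign_criteria(Consequence.INFRAME_INDEL, 23, EvidenceProfile())
        assert "BP3" in in_repeat and "PM4" not in in_repeat
        assert "PM4" in outside and "BP3" not in outside

    def test_truncating_without_position_errors(self):
        with pytest.raises(ValueError):
            assign_criteria(Consequence.FRAMESHIFT, None, EvidenceProfile())

    def test_splice_and_large_deletion_keep_full_pvs1(self):
        for cons in (Consequence.SPLICE, Consequence.LARGE_DELETION):
            cs = assign_criteria(cons, None, EvidenceProfile(maf=None))
            assert not cs["PVS1"].modified

    @settings(max_examples=200, derandomize=True)
    @given(st.builds(
        EvidenceProfile,
        maf=st.one_of(st.none(), st.floats(0, 0.2, allow_nan=False)),
        insilico=st.sampled_from(["deleterious", "benign", "conflicting", "absent"]),
        segregation=st.booleans(),
        phenotype_specific=st.booleans(),
        somatic_second_hit=st.booleans(),
        functional_damaging=st.sampled_from(["yes", "no", "untested"]),
        reputable_source=st.sampled_from(["pathogenic_report", "benign_report", "none"]),
        same_aa_known_pathogenic=st.booleans(),
        other_missense_at_residue_pathogenic=st.booleans(),
        in_hotspot_domain=st.booleans(),
        inframe_in_repeat=st.booleans(),
        missense_in_truncating_gene=st.booleans(),
        healthy_adult_carrier=st.booleans()),
        st.sampled_from(list(Consequence)))
    def test_never_emits_contradictory_pairs(self, ev, consequence):
        cs = assign_criteria(consequence, 100, ev)
        for a, b in (("PS3", "BS3"), ("PP3", "BP4"), ("PP5", "BP6")):
            assert not (a in cs and b in cs)

    def test_unused_codes_never_assigned(self):
        # codes with no assignment rule are representable but never emitted
        never = {"PS2", "PS4", "PM3", "PM6", "PP2", "BS4", "BP2", "BP5", "BP7"}
        ev = EvidenceProfile(
            maf=0.0005, insilico="deleterious", segregation=True,
            phenotype_specific=True, somatic_second_hit=True,
            functional_damaging="yes", reputable_source="pathogenic_report",
            same_aa_known_pathogenic=True, other_missense_at_residue_pathogenic=True,
            in_hotspot_domain=True, missense_in_truncating_gene=True,
            healthy_adult_carrier=True)
        cs = assign_criteria(Consequence.MISSENSE, 315, ev)
        assert not (set(cs.codes()) & never)


class TestPvs1StrengthSplit:
    def test_fixture_split_at_nmd_boundary(self, germline, strict_cfg):
        """Every truncating table variant carries PVS1_S iff its termination
        codon sits at or beyond the NMD-escape boundary."""
        checked = 0
        for r in germline:
            if r.consequence not in (Consequence.NONSENSE, Consequence.FRAMESHIFT):
                continue
            term = r.protein.termination_residue
            assert term is not None, r.protein.raw_text
            assert "PVS1" in r.printed_criteria
            expect_modified = term >= strict_cfg.nmd_escape_codon
            assert r.printed_criteria["PVS1"].modified == expect_modified, r.protein.raw_text
            checked += 1
        assert checked == 66  # 42 frameshift + 24 nonsense


class TestConcordance:
    def test_empty_input(self, curated_cfg):
        rep = concordance([], curated_cfg)
        assert rep.n_match == 0 and not rep.mismatches

    def test_as_curated_reproduces_table(self, germline, curated_cfg):
        rep = concordance(germline, curated_cfg)
        assert rep.n_match == 142
        assert {r.protein_key for r, _, _ in rep.mismatches} == {
            "Gly143_Glu148dup", "Ala306Thr", "Pro559Leu"}

    def test_strict_mismatches_superset_benign_or_inframe(self, germline,
                                                          strict_cfg, curated_cfg):
        strict_rep = concordance(germline, strict_cfg)
        curated_rep = concordance(germline, curated_cfg)
        strict_keys = {r.protein_key for r, _, _ in strict_rep.mismatches}
        curated_keys = {r.protein_key for r, _, _ in curated_rep.mismatches}
        assert strict_rep.n_match < len(germline)
        assert curated_keys <= strict_keys
        for rec, printed, _ in strict_rep.mismatches:
            benign_side = printed <= Classification.LIKELY_BENIGN or any(
                c.benign_side for c in rec.printed_criteria)
            assert benign_side or rec.consequence is Consequence.INFRAME_INDEL
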