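"""Screening cascade: control subtraction, thresholds, halogen filter,
suspect matching, inclusion lists, feature detection."""

from __future__ import annotations

import random

import pytest

from halomet import chem, screen
from halomet.chem import IsotopePattern, parse_formula
from halomet.screen import (
    AuditLog,
    Feature,
    SampleMeta,
    SuspectEntry,
    apply_thresholds,
    build_inclusion_list,
    detect_features,
    halogen_filter,
    match_suspects,
    subtract_control,
)


def feat(mz, rt=5.0, area=1e6, snr=100.0, cluster=None, label=None):
    return Feature(mz=mz, rt=rt, area=area, snr=snr, isotope_cluster=cluster, label=label)


class TestSampleMeta:
    def test_valid(self):
        m = SampleMeta("T_x_07_r1", "treated", "xylem_sap", 7, 1)
        assert m.concentration_factor == 1.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(group="sprayed"),
            dict(tissue="roots"),
            dict(dat=10),
            dict(replicate=0),
            dict(concentration_factor=0.0),
        ],
    )
    def test_invalid(self, kwargs):
        base = dict(
            sample_id="s", group="control", tissue="fruits", dat=42, replicate=1
        )
        with pytest.raises(ValueError):
            SampleMeta(**{**base, **kwargs})


class TestSubtractControl:
    def test_eliminates_within_tolerance(self):
        out = subtract_control([feat(473.0126)], [feat(473.0127)])
        assert out == []

    def test_retains_unmatched(self):
        out = subtract_control([feat(473.0126)], [feat(460.0)])
        assert len(out) == 1

    def test_rt_discriminates(self):
        out = subtract_control([feat(473.0126, rt=5.0)], [feat(473.0126, rt=8.0)])
        assert len(out) == 1

    def test_eliminated_features_are_audited(self):
        audit = AuditLog()
        subtract_control([feat(473.0126)], [feat(473.0127)], audit=audit)
        assert len(audit.by_stage("control_subtraction")) == 1

    def test_any_control_replicate_semantics(self):
        # presence in a single control replicate suffices for elimination
        controls = [feat(500.0, rt=9.0), feat(473.0126)]
        assert subtract_control([feat(473.0126)], controls) == []


class TestThresholds:
    @pytest.mark.parametrize(
        "area,snr,kept",
        [
            (9_999, 50.0, False),
            (1e6, 10.0, False),  # S/N cutoff is strict
            (1e6, 11.0, True),
            (1e4, 10.1, True),  # area cutoff is inclusive
        ],
    )
    def test_boundaries(self, area, snr, kept):
        out = apply_thresholds([feat(300.0, area=area, snr=snr)])
        assert bool(out) is kept

    def test_rejects_nonpositive_thresholds(self):
        with pytest.raises(ValueError):
            apply_thresholds([], min_area=0)


class TestHalogenFilter:
    def brcl_cluster(self):
        return chem.isotopologue_pattern(parse_formula("C19H14BrClN6O2"))

    def test_keeps_brcl_pattern(self):
        f = feat(473.0123, cluster=self.brcl_cluster())
        assert halogen_filter([f]) == [f]

    @pytest.mark.parametrize(
        "formula", ["C18H11ClN6O", "C18H9BrN6O", "C9H5BrClN3O2"]
    )
    def test_keeps_single_halogen_patterns(self, formula):
        pat = chem.isotopologue_pattern(parse_formula(formula))
        f = feat(pat.clusters[0][0], cluster=pat)
        assert halogen_filter([f]) == [f]

    def test_drops_carbon_only_pattern(self):
        # A+1 carbon satellite only: no halogen spacing companion
        pat = IsotopePattern(((300.100, 100.0), (301.103, 18.0)))
        assert halogen_filter([feat(300.1, cluster=pat)]) == []

    def test_drops_double_13c_companion(self):
        # +2.0067 (two 13C) must not be confused with +1.997 (37Cl/81Br)
        pat = IsotopePattern(((300.100, 100.0), (302.1067, 20.0)))
        assert halogen_filter([feat(300.1, cluster=pat)]) == []

    def test_drops_inconsistent_ratio(self):
        pat = IsotopePattern(((300.100, 100.0), (302.097, 5.0)))
        assert halogen_filter([feat(300.1, cluster=pat)]) == []

    def test_clusterless_features_audited(self):
        audit = AuditLog()
        assert halogen_filter([feat(300.1)], audit=audit) == []
        assert len(audit.by_stage("halogen_filter")) == 1


class TestMatchSuspects:
    @pytest.fixture(scope="class")
    def entries(self):
        return [
            SuspectEntry(
                "IN-J9Z38", parse_formula("C19H12BrClN6O"), 455.0017, 11.04
            ),
            SuspectEntry(
                "IN-MLA84", parse_formula("C18H10BrClN6O"), 440.9861, 10.27
            ),
            SuspectEntry("TP441", parse_formula("C18H10BrClN6O"), 440.9861, 8.42),
        ]

    def test_matches_by_mz_and_rt(self, entries):
        pairs = match_suspects([feat(455.0022, rt=11.04)], entries)
        assert [(f.mz, s.name) for f, s in pairs] == [(455.0022, "IN-J9Z38")]

    def test_rt_resolves_isobaric_suspects(self, entries):
        pairs = match_suspects([feat(440.9865, rt=8.42)], entries)
        assert [s.name for _, s in pairs] == ["TP441"]

    def test_no_match(self, entries):
        assert match_suspects([feat(999.9)], entries) == []

    def test_inconsistent_suspect_rejected(self):
        with pytest.raises(ValueError):
            SuspectEntry("bad", parse_formula("C19H12BrClN6O"), 455.2)


class TestInclusionList:
    def test_merges_close_masses(self):
        assert len(build_inclusion_list([473.0126, 473.0127])) == 1

    def test_catalog_isobars_merge(self, catalog):
        entries = build_inclusion_list([r.calcd_mz for r in catalog])
        # two isobaric pairs (the demethylation isomers at 440.9861 and
        # the glycoside anomers at 651.0600) collapse
        assert len(entries) == 20
        mzs = [mz for mz, _ in entries]
        assert mzs == sorted(mzs)

    def test_empty(self):
        assert build_inclusion_list([]) == []

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            build_inclusion_list([-1.0])


class TestDetectFeatures:
    def test_apex_and_snr(self):
        frames = [
            (1.00, [(473.0123, 2e4), (473.5, 100.0), (472.6, 300.0)]),
            (1.01, [(473.0124, 5e4), (473.4, 200.0)]),
            (1.02, [(473.0123, 1e4), (472.8, 100.0)]),
        ]
        feats = detect_features(frames)
        apex = max(feats, key=lambda f: f.area)
        assert apex.area == 5e4
        assert apex.rt == 1.01
        # noise floor: median of the four non-member peaks within 0.5 Da
        # of the apex (100, 100, 200, 300 -> 150)
        assert apex.snr == pytest.approx(5e4 / 150.0)

    def test_grouping_across_frames(self):
        frames = [(float(i), [(500.0 * (1 + 1e-7 * i), 1000.0 + i)]) for i in range(4)]
        feats = detect_features(frames)
        assert len(feats) == 1


class TestCascadeProperties:
    def make_features(self, rng):
        feats = []
        for _ in range(40):
            feats.append(
                feat(
                    rng.uniform(150, 1100),
                    rt=rng.uniform(0, 12),
                    area=rng.uniform(1e3, 1e7),
                    snr=rng.uniform(1, 100),
                )
            )
        return feats

    def test_order_invariance(self):
        rng = random.Random(7)
        treated = self.make_features(rng)
        control = self.make_features(rng)
        ref = subtract_control(treated, control)
        shuffled_t, shuffled_c = treated[:], control[:]
        rng.shuffle(shuffled_t)
        rng.shuffle(shuffled_c)
        assert subtract_control(shuffled_t, shuffled_c) == ref
        assert apply_thresholds(list(reversed(treated))) == apply_thresholds(treated)

    def test_each_stage_returns_subset(self):
        rng = random.Random(11)
        feats = self.make_features(rng)
        pool = set(map(id, feats))
        s1 = apply_thresholds(feats)
        assert all(id(f) in pool for f in s1)
        s2 = halogen_filter(s1)
        assert set(map(id, s2)) <= set(map(id, s1))
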