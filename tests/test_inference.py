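"""Anchor filtering, mass recalibration, validation rules, grouping, FDR."""

import numpy as np
import pandas as pd
import pytest

from necrodeconv.inference import (
    DEFAULT_THRESHOLDS,
    EngineThresholds,
    ProteinGroupTable,
    calibration_filter,
    estimate_fdr,
    infer_proteins,
    merge_and_group,
    recalibrate,
    validate_proteins,
)
from necrodeconv.simulate import MassErrorModel, PulldownSimConfig, simulate_pulldown

from conftest import make_psms


class TestCalibrationFilter:
    def test_protein_needs_three_peptides(self):
        psms = make_psms([
            ("s1", "PEPAK", "P1", "A", 50), ("s2", "PEPBK", "P1", "A", 50),
            ("s3", "PEPCK", "P2", "A", 50), ("s4", "PEPDK", "P2", "A", 50),
            ("s5", "PEPEK", "P2", "A", 50),
        ])
        anchors = calibration_filter(psms)
        assert set(anchors["peptide"]) == {"PEPCK", "PEPDK", "PEPEK"}

    def test_score_threshold_is_inclusive_at_30(self):
        psms = make_psms([
            ("s1", "PEPAK", "P1", "A", 30), ("s2", "PEPBK", "P1", "A", 31),
            ("s3", "PEPCK", "P1", "A", 32), ("s4", "PEPDK", "P1", "A", 29.9),
        ])
        anchors = calibration_filter(psms)
        assert len(anchors) == 3
        assert "PEPDK" not in set(anchors["peptide"])

    def test_empty_input_is_a_calibration_error(self):
        with pytest.raises(ValueError, match="anchor"):
            calibration_filter(make_psms([("s1", "PEPAK", "P1", "A", 10)]))


def distorted_psms(slope, offset, n=40, seed=0):
    rng = np.random.default_rng(seed)
    theo = rng.uniform(600.0, 2400.0, n)
    rows = []
    for i, t in enumerate(theo):
        ft = [200.0 + 10 * i, 900.0 + 5 * i]
        rows.append(dict(
            spectrum_id=f"s{i}", peptide=f"PEP{i}K", proteins="P0", engine="A",
            score=50.0, decoy=False, condition="non_competed", replicate=0,
            precursor_measured=slope * t + offset, precursor_theoretical=t,
            fragment_pairs=[(slope * m + offset, m) for m in ft], missed_cleavages=0,
        ))
    return pd.DataFrame(rows)


class TestRecalibration:
    def test_identity_data_gives_identity_transform(self):
        psms = distorted_psms(1.0, 0.0)
        cal, corrected = recalibrate(psms, psms)
        assert cal.precursor[0] == pytest.approx(1.0, abs=1e-9)
        assert cal.precursor[1] == pytest.approx(0.0, abs=1e-6)
        assert cal.fragment == (pytest.approx(1.0, abs=1e-9), pytest.approx(0.0, abs=1e-6))
        assert len(corrected) == len(psms)

    def test_noiseless_linear_distortion_is_inverted_exactly(self):
        psms = distorted_psms(1.000005, 0.002)
        cal, corrected = recalibrate(psms, psms)
        np.testing.assert_allclose(corrected["precursor_measured"],
                                   corrected["precursor_theoretical"], rtol=1e-10)
        for pairs in corrected["fragment_pairs"]:
            for m, t in pairs:
                assert m == pytest.approx(t, abs=1e-8)
        assert cal.post_msd_ppm2 <= cal.pre_msd_ppm2
        assert cal.post_msd_da2 <= cal.pre_msd_da2

    @pytest.mark.parametrize("seed", range(5))
    def test_recalibration_never_increases_msd_on_anchors(self, seed):
        """OLS optimality: corrected anchor masses deviate no more than raw ones."""
        rng = np.random.default_rng(seed)
        slope = 1.0 + rng.uniform(-5e-6, 5e-6)
        offset = rng.uniform(-0.01, 0.01)
        psms = distorted_psms(slope, offset, seed=seed)
        jitter = rng.normal(0, 1e-3, len(psms))
        psms["precursor_measured"] = psms["precursor_measured"] + jitter
        cal, _ = recalibrate(psms, psms)
        assert cal.post_msd_ppm2 <= cal.pre_msd_ppm2 + 1e-12
        assert cal.post_msd_da2 <= cal.pre_msd_da2 + 1e-12

    def test_retained_precursors_within_final_tolerance(self):
        cfg = PulldownSimConfig(n_background_proteins=15, n_true_targets=2, n_decoys=5, seed=4)
        psms, _ = simulate_pulldown(cfg)
        anchors = calibration_filter(psms)
        _, corrected = recalibrate(psms, anchors)
        ppm = ((corrected["precursor_measured"] - corrected["precursor_theoretical"]).abs()
               / corrected["precursor_theoretical"] * 1e6)
        assert len(corrected) > 0
        assert (ppm <= 4.0).all()

    def test_equal_anchor_masses_are_rank_deficient(self):
        psms = distorted_psms(1.0, 0.0, n=5)
        psms["precursor_measured"] = 1000.0
        psms["precursor_theoretical"] = 1000.0
        with pytest.raises(ValueError, match="rank-deficient"):
            recalibrate(psms, psms)


class TestValidation:
    def test_two_unique_peptides_above_t1(self):
        psms = make_psms([("s1", "PEPAK", "P1", "A", 15), ("s2", "PEPBK", "P1", "A", 15)])
        assert "P1" in validate_proteins(psms)["A"]

    def test_scores_at_t1_exactly_do_not_count(self):
        psms = make_psms([("s1", "PEPAK", "P1", "A", 14), ("s2", "PEPBK", "P1", "A", 14)])
        assert "P1" not in validate_proteins(psms)["A"]

    def test_single_peptide_needs_t2(self):
        below = make_psms([("s1", "PEPAK", "P1", "A", 39)])
        above = make_psms([("s1", "PEPAK", "P1", "A", 41)])
        assert "P1" not in validate_proteins(below)["A"]
        assert "P1" in validate_proteins(above)["A"]

    def test_t3_additions_attach_only_above_t3(self):
        psms = make_psms([
            ("s1", "PEPAK", "P1", "A", 45),  # validates via T2
            ("s2", "PEPBK", "P1", "A", 11),  # > T3=10: accepted
            ("s3", "PEPCK", "P1", "A", 9),   # <= T3: rejected
        ])
        accepted = validate_proteins(psms)["A"]["P1"]
        assert accepted == {"PEPAK", "PEPBK"}

    def test_shared_peptides_are_not_unique(self):
        """Two shared peptides above T1 do not validate either protein."""
        psms = make_psms([
            ("s1", "PEPAK", "P1;P2", "A", 20), ("s2", "PEPBK", "P1;P2", "A", 20),
        ])
        validated = validate_proteins(psms)["A"]
        assert "P1" not in validated and "P2" not in validated

    def test_engine_b_uses_its_own_thresholds(self):
        psms = make_psms([("s1", "PEPAK", "P1", "B", 4.3), ("s2", "PEPBK", "P1", "B", 4.3)])
        assert "P1" in validate_proteins(psms)["B"]

    def test_unknown_engine_is_an_input_error(self):
        psms = make_psms([("s1", "PEPAK", "P1", "Z", 99)])
        with pytest.raises(ValueError, match="unknown engine"):
            validate_proteins(psms)

    def test_validation_is_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        rows = [(f"s{i}", f"PEP{i}K", f"P{i % 6}", "A", float(rng.uniform(5, 60)))
                for i in range(60)]
        psms = make_psms(rows)
        base = set(validate_proteins(psms, {"A": EngineThresholds("A", 14, 40, 10)})["A"])
        for t1, t2, t3 in [(20, 45, 12), (14, 50, 10), (30, 60, 20)]:
            tighter = set(validate_proteins(
                psms, {"A": EngineThresholds("A", t1, t2, t3)})["A"])
            assert tighter <= base

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError, match="T3 <= T1 <= T2"):
            EngineThresholds("A", t1=5, t2=4, t3=6)


class TestMergeAndGroup:
    def test_agreeing_engines_count_each_spectrum_once(self):
        psms = make_psms([
            ("s1", "PEPAK", "P1", "A", 45), ("s1", "PEPAK", "P1", "B", 6.0),
            ("s2", "PEPBK", "P1", "A", 45), ("s2", "PEPBK", "P1", "B", 6.0),
        ])
        table = merge_and_group(validate_proteins(psms), psms)
        counts = table.profiles.set_index(["condition", "replicate"])["spectral_count"]
        assert counts[("non_competed", 0)] == 2

    def test_conflicting_spectrum_is_discarded_entirely(self):
        psms = make_psms([
            ("s1", "PEPAK", "P1", "A", 45), ("s1", "PEPXK", "P2", "B", 6.0),
            ("s2", "PEPBK", "P1", "A", 45), ("s2", "PEPBK", "P1", "B", 6.0),
        ])
        table = merge_and_group(validate_proteins(psms), psms)
        total = table.profiles["spectral_count"].sum()
        assert total == 1  # only s2 survives

    def test_identical_peptide_sets_collapse_to_one_group(self):
        psms = make_psms([
            ("s1", "PEPAK", "P1;P2", "A", 45), ("s2", "PEPBK", "P1;P2", "A", 45),
            ("s3", "PEPAK", "P1;P2", "A", 50),
        ])
        validated = {"A": {"P1": {"PEPAK", "PEPBK"}, "P2": {"PEPAK", "PEPBK"}}}
        table = merge_and_group(validated, psms)
        assert table.n_groups == 1
        assert table.groups["members"].iloc[0] == "P1;P2"

    @pytest.mark.parametrize("seed", range(4))
    def test_single_linkage_matches_brute_force_components(self, seed):
        """Grouping equals the transitive closure computed by naive set merging."""
        rng = np.random.default_rng(seed)
        n_prot, n_pep = 15, 25
        validated = {"A": {}}
        for i in range(n_prot):
            peps = set(rng.choice(n_pep, size=rng.integers(1, 4), replace=False))
            validated["A"][f"P{i:02d}"] = {f"PEP{j}K" for j in peps}
        psms = make_psms([(f"s{i}", sorted(v)[0], k, "A", 45)
                          for i, (k, v) in enumerate(validated["A"].items())])
        table = merge_and_group(validated, psms)
        # brute-force closure
        sets = [{p} | set() for p in validated["A"]]
        def peps_of(group):
            return set().union(*[validated["A"][m] for m in group])
        changed = True
        while changed:
            changed = False
            for i in range(len(sets)):
                for j in range(i + 1, len(sets)):
                    if sets[i] and sets[j] and peps_of(sets[i]) & peps_of(sets[j]):
                        sets[i] |= sets[j]
                        sets[j] = set()
                        changed = True
        expected = sorted(frozenset(s) for s in sets if s)
        got = sorted(frozenset(m.split(";")) for m in table.groups["members"])
        assert got == expected

    def test_grouping_is_order_independent(self):
        psms = make_psms([
            ("s1", "PEPAK", "P1", "A", 45), ("s2", "PEPBK", "P2", "A", 45),
            ("s3", "PEPAK", "P1", "B", 6.0), ("s4", "PEPBK", "P2", "B", 6.0),
        ])
        shuffled = psms.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = merge_and_group(validate_proteins(psms), psms)
        b = merge_and_group(validate_proteins(shuffled), shuffled)
        pd.testing.assert_frame_equal(
            a.groups.sort_values("group_id").reset_index(drop=True),
            b.groups.sort_values("group_id").reset_index(drop=True),
        )


def stub_table(n_groups, peptides):
    groups = pd.DataFrame({"group_id": [f"G{i}" for i in range(n_groups)]})
    return ProteinGroupTable(groups=groups, profiles=pd.DataFrame(),
                             accepted_peptides=set(peptides))


class TestFdr:
    def test_zero_decoys_means_zero_fdr(self):
        fdr = estimate_fdr(stub_table(100, [f"p{i}" for i in range(300)]), stub_table(0, []))
        assert fdr.protein_fdr == 0.0 and fdr.peptide_fdr == 0.0
        assert fdr.protein_pass and fdr.peptide_pass

    def test_half_percent_protein_fdr_passes(self):
        fdr = estimate_fdr(stub_table(200, [f"p{i}" for i in range(2000)]),
                           stub_table(1, ["d0"]))
        assert fdr.protein_fdr == pytest.approx(0.005)
        assert fdr.protein_pass

    def test_one_and_a_half_percent_protein_fdr_fails(self):
        fdr = estimate_fdr(stub_table(200, [f"p{i}" for i in range(2000)]),
                           stub_table(3, ["d0", "d1", "d2"]))
        assert fdr.protein_fdr == pytest.approx(0.015)
        assert not fdr.protein_pass

    def test_shared_target_decoy_peptides_leave_the_numerator(self):
        fdr = estimate_fdr(stub_table(10, ["p1", "p2", "shared"]),
                           stub_table(1, ["shared", "d1"]))
        assert fdr.n_decoy_peptides == 1

    def test_zero_targets_is_undefined(self):
        with pytest.raises(ValueError, match="zero target"):
            estimate_fdr(stub_table(0, []), stub_table(1, ["d0"]))


class TestEndToEnd:
    def test_planted_targets_survive_the_full_chain(self):
        cfg = PulldownSimConfig(n_background_proteins=30, n_true_targets=4, n_decoys=15, seed=11)
        psms, truth = simulate_pulldown(cfg)
        result = infer_proteins(psms)
        validated = set(result.target.groups["group_id"].str.split(";").explode())
        members = set()
        for m in result.target.groups["members"]:
            members.update(m.split(";"))
        targets = set(truth.loc[truth["kind"] == "target", "accession"])
        # abundant planted targets validate (low-abundance ones may not draw spectra)
        abundant = set(truth.loc[(truth["kind"] == "target") & (truth["mean_count"] > 5),
                                 "accession"])
        assert abundant <= members
        assert result.fdr.protein_fdr < 0.2
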