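"""Three-criteria identification, untargeted screens, sn-isomer labelling
and retention-time prediction."""

import numpy as np
import pytest

from aifquant.annotator import (
    assign_sn_isomers,
    bile_acid_candidate_space,
    confirm_identity,
    predict_rt,
    screen_bile_acids,
    screen_lpl,
)
from aifquant.chemmass import LPL_CLASS_INFO, Adduct, lpl_formula, parse_formula
from aifquant.peakcraft import Peak, detect_peaks, extract_xic
from aifquant.spectra_io import CompoundEntry, Run
from aifquant.synthgen import SimCompound, SimConfig, simulate_run

CFG = dict(rt_start=4.0, run_length=6.5, noise_floor=50.0, proportional_noise=0.02)


def _lpl_entry(name, cls, carbons, db, rt):
    head, adduct = LPL_CLASS_INFO[cls]
    tag = head if cls == "O-LPC" else f"{head}+fatty-acyl({carbons}:{db})"
    return CompoundEntry(name, tag, lpl_formula(cls, carbons, db), adduct, expected_rt=rt)


class TestConfirmIdentity:
    def test_spiked_conjugate_meets_all_three_criteria(self, by_name):
        run, _ = simulate_run(
            [SimCompound(by_name["GCA"], 0.5)], SimConfig(seed=1, **CFG)
        )
        ann = confirm_identity(run, by_name["GCA"])
        assert ann.criterion_ms1 and ann.criterion_ms2_fragment and ann.criterion_rt
        assert ann.confirmed
        assert ann.matched_fragments == ["glycinate"]

    def test_fragment_shifted_breaks_coelution(self, by_name):
        run, _ = simulate_run(
            [SimCompound(by_name["GCA"], 0.5)], SimConfig(seed=1, **CFG)
        )
        shifted = Run(
            spectra=[
                s if s.ms_level == 1 else type(s)(
                    ms_level=2,
                    rt=s.rt + 0.3,
                    mz_array=s.mz_array,
                    intensity_array=s.intensity_array,
                )
                for s in run.spectra
            ],
            metadata=dict(run.metadata),
        )
        ann = confirm_identity(shifted, by_name["GCA"])
        assert ann.criterion_ms1
        assert not ann.criterion_ms2_fragment
        assert not ann.confirmed

    def test_blank_run_fails_ms1_criterion(self, by_name):
        run, _ = simulate_run(
            [SimCompound(by_name["GCA"], 0.0)], SimConfig(seed=1, **CFG)
        )
        ann = confirm_identity(run, by_name["GCA"])
        assert not ann.criterion_ms1 and not ann.confirmed

    def test_rt_mismatch_blocks_confirmation_for_standards(self, by_name):
        entry = by_name["GCA"]
        run, _ = simulate_run(
            [SimCompound(entry, 0.5, apex_rt=entry.expected_rt + 0.5)],
            SimConfig(seed=1, **CFG),
        )
        ann = confirm_identity(run, entry)
        assert ann.criterion_ms1 and not ann.criterion_rt and not ann.confirmed


class TestScreenBileAcids:
    def test_doubly_conjugated_species_matches_both_fragment_sets(self):
        entry = CompoundEntry(
            "S-GLCA-like",
            "glycine-conjugate+sulfate",
            parse_formula("C26H43NO7S"),
            Adduct.DEPROTONATED,
            expected_rt=5.5,
        )
        run, _ = simulate_run([SimCompound(entry, 0.5)], SimConfig(seed=2, **CFG))
        hits = screen_bile_acids(run)
        assert len(hits) == 1
        names = set(hits[0].matched_fragments)
        assert "glycinate" in names and "bisulfate" in names
        assert hits[0].score == 1.0 and not hits[0].mass_only

    def test_unconjugated_peak_reported_mass_only(self, by_name):
        run, _ = simulate_run(
            [SimCompound(by_name["CA"], 0.5)],  # CA elutes at 7.4 min
            SimConfig(seed=3, rt_start=6.5, run_length=9.0, noise_floor=50.0,
                      proportional_noise=0.02),
        )
        hits = screen_bile_acids(run)
        assert len(hits) == 1
        assert hits[0].mass_only and hits[0].score == 0.0

    def test_empty_candidate_space_rejected(self, by_name):
        run, _ = simulate_run(
            [SimCompound(by_name["CA"], 0.5)], SimConfig(seed=3, **CFG)
        )
        with pytest.raises(ValueError):
            screen_bile_acids(run, candidate_space=[])

    def test_candidate_space_covers_cores_and_conjugations(self):
        space = bile_acid_candidate_space()
        assert len(space) == 33  # 3 cores x (1 + 4 single + 6 paired)
        labels = [label for label, _, _ in space]
        assert "BA(3OH)+glycine" in labels and "BA(1OH)+taurine+sulfate" in labels


@pytest.fixture(scope="module")
def lpl_run():
    compounds = [
        SimCompound(_lpl_entry("LPC(16:0)", "LPC", 16, 0, 9.7), 0.5,
                    sn2_fraction=0.09),
        SimCompound(_lpl_entry("LPE(18:2)", "LPE", 18, 2, 9.5), 0.5,
                    sn2_fraction=0.09),
    ]
    run, truth = simulate_run(
        compounds,
        SimConfig(seed=6, rt_start=8.0, run_length=11.0, noise_floor=50.0,
                  proportional_noise=0.02),
    )
    return run, truth


class TestScreenLpl:
    def test_acetate_adduct_lpc_identified_with_both_fragments(self, lpl_run):
        run, _ = lpl_run
        hits = [h for h in screen_lpl(run) if h.class_hypothesis == "LPC(16:0)"]
        assert hits, "16:0 LPC not found"
        major = max(hits, key=lambda h: h.apex_rt)
        assert major.query_mz == pytest.approx(554.3463, abs=5e-3)
        assert set(major.matched_fragments) == {
            "demethylated phosphocholine",
            "FA 16:0 carboxylate",
        }

    def test_head_group_separates_coeluting_classes(self, lpl_run):
        """LPE and LPC both produce acyl carboxylate fragments; the class
        must come from the head group + adduct, never the acyl channel."""
        run, _ = lpl_run
        hits = screen_lpl(run)
        lpe_hits = [h for h in hits if h.class_hypothesis.startswith("LPE")]
        assert lpe_hits and all(
            "glycerophosphoethanolamine" in h.matched_fragments for h in lpe_hits
        )
        for h in hits:
            if h.class_hypothesis.startswith("LPC"):
                assert "demethylated phosphocholine" in h.matched_fragments

    def test_low_abundance_species_reported_mass_only(self):
        entry = _lpl_entry("LPI(18:1)", "LPI", 18, 1, 9.0)
        run, _ = simulate_run(
            [SimCompound(entry, 0.5, fragment_yield=0.0)],
            SimConfig(seed=7, rt_start=8.0, run_length=10.0, noise_floor=50.0),
        )
        hits = [h for h in screen_lpl(run) if h.class_hypothesis == "LPI(18:1)"]
        assert hits and all(h.mass_only for h in hits)


class TestAssignSnIsomers:
    def test_minor_early_pair_labelled_sn2_sn1(self):
        minor = Peak(9.40, 9.3, 9.5, 10.0, 1.0)
        major = Peak(9.70, 9.6, 9.8, 100.0, 10.0)
        out = assign_sn_isomers([minor, major])
        assert out.labels == ["sn2", "sn1"]
        assert out.consistent is True

    def test_single_peak_is_sn1(self):
        out = assign_sn_isomers([Peak(9.5, 9.4, 9.6, 10.0, 1.0)])
        assert out.labels == ["sn1"]

    def test_equal_pair_gets_dominant_only_label(self):
        a = Peak(9.40, 9.3, 9.5, 100.0, 10.1)
        b = Peak(9.70, 9.6, 9.8, 100.0, 10.0)
        out = assign_sn_isomers([a, b])
        assert out.labels == ["sn1", None]  # dominant peak only
        assert out.consistent is False  # the minor peak eluted second

    def test_permutation_invariant(self):
        minor = Peak(9.40, 9.3, 9.5, 10.0, 1.0)
        major = Peak(9.70, 9.6, 9.8, 100.0, 10.0)
        fwd = assign_sn_isomers([minor, major])
        rev = assign_sn_isomers([major, minor])
        assert fwd.labels == ["sn2", "sn1"] and rev.labels == ["sn1", "sn2"]
        assert fwd.consistent == rev.consistent

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            assign_sn_isomers([])

    def test_sn2_first_convention_configurable(self):
        minor = Peak(9.40, 9.3, 9.5, 10.0, 1.0)
        major = Peak(9.70, 9.6, 9.8, 100.0, 10.0)
        out = assign_sn_isomers([minor, major], sn2_first=False)
        assert out.labels == ["sn1", "sn2"]


class TestPredictRt:
    def test_exact_linear_anchors_reproduced(self):
        anchors = [
            (c, d, 2.0 + 0.5 * c - 0.4 * d)
            for c in (14, 16, 18, 20)
            for d in (0, 1, 2)
        ]
        pred = predict_rt("LPC", 22, 3, anchors)
        assert pred == pytest.approx(2.0 + 0.5 * 22 - 0.4 * 3, abs=1e-6)

    def test_leave_one_out_error_small_on_noisy_linear_data(self):
        rng = np.random.default_rng(5)
        pts = [(c, d) for c in (12, 14, 16, 18, 20, 22) for d in (0, 1, 2, 3)]
        rts = {p: 1.5 + 0.45 * p[0] - 0.35 * p[1] + rng.normal(0, 0.01) for p in pts}
        errs = []
        for held in pts:
            anchors = [(c, d, rts[(c, d)]) for c, d in pts if (c, d) != held]
            errs.append(abs(predict_rt("LPC", *held, anchors) - rts[held]))
        assert max(errs) < 0.05

    def test_too_few_anchors_rejected(self):
        with pytest.raises(ValueError):
            predict_rt("LPC", 18, 1, [(16, 0, 9.7), (18, 0, 10.5)])
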