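import numpy as np
import pandas as pd
import pytest

from trnamod import homology
from trnamod.calling import _with_mi
from trnamod.homology import (
    HomologyError,
    comparison_from_pairs,
    compare_species,
    match_orthologs,
    parse_trna_id,
    sequence_identity,
    transfer_annotations,
)
from trnamod.simulate import SimulationConfig, simulate_species_pair


def seq(base="A", n=76):
    return base * n


def make_calls(rows):
    out = []
    for species, trna, position, ref, mi, conf in rows:
        out.append({"species": species, "trna": trna,
                    "position": str(position), "ref_base": ref,
                    "coverage": 500, "mi_frequency": mi,
                    "frac_a": 0.0, "frac_c": 0.0, "frac_g": 1 - mi,
                    "frac_t": mi, "frac_del": 0.0,
                    "p_value": 1e-6, "p_adjusted": 1e-5,
                    "confidence": conf, "inferred_code": np.nan})
    return pd.DataFrame(out)


def make_ann(rows):
    return pd.DataFrame([
        {"species": s, "trna": t, "position": str(p), "code": c,
         "source": "known"} for s, t, p, c in rows])


class TestParseAndIdentity:
    def test_parse_trna_id(self):
        assert parse_trna_id("Lys-UUU-2") == ("Lys", "TTT")
        assert parse_trna_id("iMet-CAU") == ("iMet", "CAT")

    def test_bad_id_raises(self):
        with pytest.raises(HomologyError):
            parse_trna_id("nonsense")

    def test_identity_equal_length(self):
        assert sequence_identity("ACGT", "ACGA") == 0.75

    def test_identity_with_alignment(self):
        assert sequence_identity("ACGTACGT", "ACGTACG") >= 0.8


class TestMatchOrthologs:
    def test_shared_isotype_anticodon_paired(self):
        pairs, us, ut = match_orthologs(
            {"iMet-CAU-1": seq("A")}, {"iMet-CAU-1": seq("A")}, "Pfu", "Tko")
        assert len(pairs) == 1
        assert pairs[0].source_trna == pairs[0].target_trna == "iMet-CAU-1"
        assert us == [] and ut == []

    def test_missing_counterpart_reported(self):
        pairs, unmatched_src, _ = match_orthologs(
            {"Glu-UUG-1": seq("A"), "Ala-AGC-1": seq("C")},
            {"Ala-AGC-1": seq("C")}, "a", "b")
        assert len(pairs) == 1
        assert unmatched_src == ["Glu-UUG-1"]

    def test_duplicate_isodecoder_resolved_by_identity(self):
        # hand-constructed duplicate: the higher-identity copy must win
        source = {"Lys-UUU-1": "ACGT" * 19}
        target = {"Lys-UUU-1": "ACGT" * 19,          # identical
                  "Lys-UUU-2": "ACGA" * 19}          # 75% identical
        pairs, _, unmatched_tgt = match_orthologs(source, target, "a", "b")
        assert len(pairs) == 1
        assert pairs[0].target_trna == "Lys-UUU-1"
        assert pairs[0].identity == 1.0
        assert unmatched_tgt == ["Lys-UUU-2"]

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            pairs, _, _ = match_orthologs({}, {"X-AAA-1": seq()}, "a", "b")
        assert pairs == []


class TestTransferAnnotations:
    def setup_method(self):
        self.pairs, _, _ = match_orthologs(
            {"iMet-CAU-1": seq("G")}, {"iMet-CAU-1": seq("G")}, "Pfu", "Tko")

    def test_conserved_confident_site_transfers(self):
        anns = make_ann([("Pfu", "iMet-CAU-1", 26, "m22G")])
        calls = make_calls([("Tko", "iMet-CAU-1", 26, "G", 0.7, "high")])
        predicted, rejected = transfer_annotations(self.pairs, anns, calls)
        assert len(predicted) == 1 and len(rejected) == 0
        rec = predicted.iloc[0]
        assert rec["source"] == "predicted" and rec["confidence"] == "high"
        assert rec["source_species"] == "Pfu"
        # transfer never changes position or implied base
        assert rec["position"] == "26" and rec["code"] == "m22G"

    def test_base_mismatch_blocks_transfer(self):
        # the target carries C where the source modification needs G
        anns = make_ann([("Pfu", "iMet-CAU-1", 6, "m22G")])
        calls = make_calls([("Tko", "iMet-CAU-1", 6, "C", 0.5, "high")])
        predicted, rejected = transfer_annotations(self.pairs, anns, calls)
        assert len(predicted) == 0
        assert rejected.iloc[0]["reason"] == "base-mismatch"

    def test_no_signal_blocks_transfer(self):
        # 2'-O-methyl with no misincorporation signal in the target
        anns = make_ann([("Pfu", "iMet-CAU-1", 22, "Gm")])
        calls = make_calls([("Tko", "iMet-CAU-1", 22, "G", 0.005, "none")])
        predicted, rejected = transfer_annotations(self.pairs, anns, calls)
        assert len(predicted) == 0
        assert rejected.iloc[0]["reason"] == "no-signal"

    def test_missing_call_reported(self):
        anns = make_ann([("Pfu", "iMet-CAU-1", 58, "m1A")])
        predicted, rejected = transfer_annotations(
            self.pairs, anns, make_calls([]))
        assert len(predicted) == 0
        assert rejected.iloc[0]["reason"] == "no-call"


class TestCompare:
    def pairs_frame(self, known, predicted):
        return pd.DataFrame({
            "trna": [f"t{i}" for i in range(len(known))],
            "position": ["26"] * len(known),
            "code": ["m22G"] * len(known),
            "known_mi": known, "predicted_mi": predicted})

    def test_identical_vectors_give_r_one_no_outliers(self):
        mi = [0.1, 0.4, 0.7, 0.9]
        comp = comparison_from_pairs(self.pairs_frame(mi, mi), "a", "b")
        assert comp.pearson_r == pytest.approx(1.0)
        assert comp.sites["outlier"].sum() == 0

    def test_constructed_outlier_flagged_exactly(self):
        # 20 concordant sites plus one planted residual at 4x the SD the
        # concordant noise would give: only the planted site is flagged
        rng = np.random.default_rng(0)
        known = rng.uniform(0.2, 0.8, size=21)
        predicted = known.copy()
        predicted[:20] += rng.normal(0, 0.004, size=20)
        predicted[20] = known[20] + 0.2
        comp = comparison_from_pairs(
            self.pairs_frame(known, predicted), "a", "b")
        flagged = comp.sites.index[comp.sites["outlier"]].tolist()
        assert flagged == [20]

    def test_equal_residuals_never_outliers(self):
        known = np.array([0.1, 0.3, 0.5, 0.7])
        comp = comparison_from_pairs(
            self.pairs_frame(known, known + 0.05), "a", "b")
        assert comp.sites["outlier"].sum() == 0

    def test_insufficient_pairs_marked(self):
        comp = comparison_from_pairs(
            self.pairs_frame([0.1, 0.2], [0.1, 0.2]), "a", "b")
        assert comp.insufficient

    def test_pearson_r_affine_invariant(self):
        rng = np.random.default_rng(3)
        known = rng.uniform(0.1, 0.9, 30)
        predicted = known + rng.normal(0, 0.05, 30)
        r1 = comparison_from_pairs(
            self.pairs_frame(known, predicted), "a", "b").pearson_r
        r2 = comparison_from_pairs(
            self.pairs_frame(0.5 * known + 0.1, 0.5 * predicted + 0.1),
            "a", "b").pearson_r
        assert r1 == pytest.approx(r2, abs=1e-12)


def observed_mi_pairs(pair):
    """Matched observed MI values at the shared simulated sites."""
    mi_a = _with_mi(pair["coverage_a"]).set_index(["trna", "position"])
    mi_b = _with_mi(pair["coverage_b"]).set_index(["trna", "position"])
    sites = pair["sites"]
    idx = list(zip(sites["trna"], sites["position"]))
    return pd.DataFrame({
        "trna": sites["trna"], "position": sites["position"],
        "code": sites["code"],
        "known_mi": mi_a.loc[idx, "mi_frequency"].to_numpy(),
        "predicted_mi": mi_b.loc[idx, "mi_frequency"].to_numpy()})


class TestSpeciesPairSimulation:
    def test_single_draw_correlation_recovery(self):
        """One 60-site draw at generative rho=0.9 estimates r within a
        single-draw sampling band."""
        pair = simulate_species_pair(SimulationConfig(seed=2), n_sites=60,
                                     rho=0.9)
        comp = comparison_from_pairs(observed_mi_pairs(pair), "a", "b")
        assert 0.82 <= comp.pearson_r <= 0.98

    def test_end_to_end_outlier_detection(self):
        """A planted discordant site is the only +-2 SD outlier when the
        concordant baseline is tight."""
        pair = simulate_species_pair(SimulationConfig(seed=7), n_sites=20,
                                     rho=0.9, noise_sd=0.05, n_outliers=1)
        comp = comparison_from_pairs(observed_mi_pairs(pair), "a", "b")
        flagged = comp.sites[comp.sites["outlier"]]
        planted = pair["sites"][pair["sites"]["is_outlier"]]
        assert len(flagged) == 1
        assert flagged.iloc[0]["trna"] == planted.iloc[0]["trna"]
        assert flagged.iloc[0]["position"] == planted.iloc[0]["position"]


def test_compare_species_full_route(scenario, scenario_calls):
    """transfer_annotations -> compare_species on the coupled synthetic
    clade pair gives a high within-clade correlation."""
    calls = scenario_calls
    pairs, _, _ = match_orthologs(scenario["seqs"]["hyper_A"],
                                  scenario["seqs"]["hyper_B"],
                                  "hyper_A", "hyper_B")
    truth_a = scenario["truth"][scenario["truth"]["species"] == "hyper_A"]
    predicted, _ = transfer_annotations(
        pairs, truth_a, calls[calls["species"] == "hyper_B"])
    comp = compare_species(calls[calls["species"] == "hyper_A"], predicted,
                           calls[calls["species"] == "hyper_B"])
    assert not comp.insufficient
    assert comp.pearson_r > 0.8
    # outlier read-identity compositions are attached for inspection
    assert {"known_frac_del", "predicted_frac_del"} <= set(comp.sites)
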