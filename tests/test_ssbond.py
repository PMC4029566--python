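"""Pattern enumeration, species prediction and elimination-based inference."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from pmfstruct import masscalc as mc
from pmfstruct import scenario, synthetic as syn
from pmfstruct.ssbond import (CysteineFramework, MassObservation,
                              SpeciesPredictor, TreatmentCondition,
                              adjacency_filter, bond, enumerate_patterns,
                              infer_patterns, make_pattern, match_observations,
                              parse_annotation, ppm_error, predict_species)


def brute_force_matchings(n):
    """Independent oracle: dedupe matchings read off all permutations."""
    out = set()
    for perm in itertools.permutations(range(1, n + 1)):
        out.add(frozenset(bond(perm[i], perm[i + 1]) for i in range(0, n, 2)))
    return out


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(2, 1), (4, 3), (6, 15), (8, 105), (10, 945)])
    def test_double_factorial_count(self, n, count):
        pats = enumerate_patterns(n)
        assert len(pats) == count
        assert len(set(pats)) == count

    @pytest.mark.parametrize("n", [2, 4, 6, 8])
    def test_matches_brute_force_enumeration(self, n):
        assert set(enumerate_patterns(n)) == brute_force_matchings(n)

    def test_odd_count_rejected(self):
        with pytest.raises(ValueError):
            enumerate_patterns(7)


class TestAdjacencyFilter:
    def test_no_adjacent_cysteines_is_identity(self):
        fw = CysteineFramework((2, 6, 10, 16))
        pats = enumerate_patterns(4)
        assert adjacency_filter(pats, fw) == pats

    def test_adjacent_doublet_removes_fixed_pair_matchings(self):
        # one adjacent pair (ordinals 6-7); matchings containing a fixed pair
        # number (n-3)!! = 15, so 105 - 15 = 90 survive
        fw = CysteineFramework((2, 6, 10, 16, 20, 24, 25, 30))
        survivors = adjacency_filter(enumerate_patterns(8), fw)
        assert len(survivors) == 90
        assert all(bond(6, 7) not in p for p in survivors)


class TestPredictSpecies:
    SEQ = scenario.SCENARIO_SEQUENCE

    @pytest.fixture()
    def fw(self):
        return CysteineFramework.from_sequence(self.SEQ)

    def test_fully_reduced_alkylated_gives_unlinked_cam_peptides(self, fw):
        pattern = scenario.CANDIDATE_A
        tr = TreatmentCondition("chymotrypsin", dtt=True, iaa=True)
        species = predict_species(self.SEQ, fw, pattern, [], tr)
        assert all(len(sp.spans) == 1 for sp, _ in species)
        for sp, _ in species:
            assert all(st == "cam" for st in sp.mods.statuses.values())

    def test_zero_reduced_joins_by_full_pattern(self, fw):
        pattern = scenario.CANDIDATE_A
        tr = TreatmentCondition("chymotrypsin", dtt=False, iaa=True, n_reduced=0)
        species = predict_species(self.SEQ, fw, pattern, [], tr)
        # 1-2 pair, 4-5 pair, 3 linked to the 6,7,8 peptide, lone SCSAL-free
        multi = [sp for sp, _ in species if len(sp.spans) > 1]
        assert len(multi) == 3
        assert all(st == "bonded" for sp, _ in species
                   for st in sp.mods.statuses.values())

    def test_one_reduced_species_match_hand_construction(self, fw):
        pattern = scenario.CANDIDATE_A
        tr = TreatmentCondition("chymotrypsin", dtt=False, iaa=True, n_reduced=1)
        species = predict_species(self.SEQ, fw, pattern, [bond(3, 6)], tr)
        masses = sorted(m for _, m in species)
        pep = lambda s: mc.peptide_mass(s)
        h, cam = mc.DISULFIDE_H_PER_CYS, mc.CAM_DELTA["mono"]
        expected = sorted([
            pep("ACAL") + pep("GCGF") - 2 * h,        # 1-2 dimer
            pep("GGCAF") + pep("TCTGL") - 2 * h,      # 4-5 dimer
            pep("SCSAL") + cam,                       # freed Cys3 peptide, CAM
            pep("CCAGGACN") + cam - 2 * h,            # 6 CAM, 7-8 intact
        ])
        assert masses == pytest.approx(expected, abs=1e-9)

    def test_reduced_subset_must_belong_to_pattern(self, fw):
        tr = TreatmentCondition("chymotrypsin", n_reduced=1)
        with pytest.raises(ValueError, match="subset"):
            predict_species(self.SEQ, fw, scenario.CANDIDATE_A, [bond(1, 3)], tr)

    def test_non_matching_pattern_rejected(self, fw):
        tr = TreatmentCondition("chymotrypsin")
        with pytest.raises(ValueError, match="perfect matching"):
            predict_species(self.SEQ, fw, make_pattern([(1, 2)]), [], tr)


class TestMatching:
    def _theoretical(self):
        fw = CysteineFramework.from_sequence(scenario.SCENARIO_SEQUENCE)
        tr = TreatmentCondition("chymotrypsin", n_reduced=0)
        return predict_species(scenario.SCENARIO_SEQUENCE, fw,
                               scenario.CANDIDATE_A, [], tr)

    def test_exact_mass_matches_at_zero_ppm(self):
        theo = self._theoretical()
        obs = [MassObservation(theo[0][1], 10.0,
                               TreatmentCondition("chymotrypsin"))]
        matches = match_observations(theo, obs)
        assert matches[0] and matches[0][0].ppm == 0.0

    def test_mass_outside_tolerance_unmatched(self):
        theo = self._theoretical()
        off = theo[0][1] * (1 + 20e-6)   # 2x the 10 ppm tolerance
        obs = [MassObservation(off, 10.0, TreatmentCondition("chymotrypsin"))]
        assert match_observations(theo, obs) == [[]]

    def test_collision_flagged_ambiguous(self):
        sp = self._theoretical()[0][0]
        theo = [(sp, 1000.0), (sp, 1000.001)]    # 1 ppm apart
        obs = [MassObservation(1000.0005, 10.0, TreatmentCondition("chymotrypsin"))]
        matches = match_observations(theo, obs)
        assert len(matches[0]) == 2
        assert all(m.ambiguous for m in matches[0])

    def test_empty_theoretical_list_means_unmatched(self):
        obs = [MassObservation(500.0, 10.0, TreatmentCondition("chymotrypsin"))]
        assert match_observations([], obs) == [[]]


class TestAnnotations:
    def test_parse_positive_and_negative(self):
        assert parse_annotation("Cys8 not alkylated") == (8, False)
        assert parse_annotation("Cys3 alkylated") == (3, True)

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            parse_annotation("Cys8 bonded")


class TestInference:
    def test_study_scenario_yields_exactly_two_candidates(self):
        seq, fw, obs = scenario.scenario_observations()
        result = infer_patterns(seq, fw, obs, use_adjacency_rule=True)
        assert set(result.candidates) == {scenario.CANDIDATE_A, scenario.CANDIDATE_B}
        assert scenario.CANONICAL_TFP not in result.candidates

    def test_annotation_alone_excludes_the_3_8_6_7_pattern(self):
        # even without the adjacency prior, the unalkylated-Cys8 fragment
        # evidence eliminates the {3-8, 6-7} completion
        seq, fw, obs = scenario.scenario_observations()
        result = infer_patterns(seq, fw, obs, use_adjacency_rule=False)
        assert set(result.candidates) == {scenario.CANDIDATE_A, scenario.CANDIDATE_B}

    def test_no_observations_keeps_all_patterns(self):
        seq, fw, _ = scenario.scenario_observations()
        result = infer_patterns(seq, fw, [], use_adjacency_rule=False)
        assert len(result.candidates) == 105

    def test_adding_observations_never_enlarges_candidates(self):
        seq, fw, obs = scenario.scenario_observations()
        previous = None
        for k in range(len(obs) + 1):
            result = infer_patterns(seq, fw, obs[:k], use_adjacency_rule=False)
            current = set(result.candidates)
            if previous is not None:
                assert current <= previous
            previous = current

    def test_noise_free_observations_never_eliminate_truth(self):
        for seed in range(5):
            prot = syn.gen_protein(seed=seed)
            ms = syn.gen_ms_dataset(prot, noise_ppm=0.0, dropout=0.0, seed=seed)
            result = infer_patterns(prot.sequence, prot.framework,
                                    ms.observations, use_adjacency_rule=False)
            assert prot.pattern in result.candidates

    def test_contaminants_do_not_eliminate_in_default_mode(self):
        prot = syn.gen_protein(seed=11)
        ms = syn.gen_ms_dataset(prot, noise_ppm=0.0, dropout=0.0,
                                contaminant_rate=3.0, seed=11)
        result = infer_patterns(prot.sequence, prot.framework, ms.observations,
                                use_adjacency_rule=False)
        assert prot.pattern in result.candidates

    def test_strict_mode_counts_every_unmatched_observation(self):
        seq, fw, obs = scenario.scenario_observations()
        rogue = MassObservation(4321.0, 10.0,
                                TreatmentCondition("chymotrypsin", n_reduced=1))
        loose = infer_patterns(seq, fw, obs + [rogue], use_adjacency_rule=True)
        strict = infer_patterns(seq, fw, obs + [rogue], use_adjacency_rule=True,
                                strict=True)
        assert set(loose.candidates) == {scenario.CANDIDATE_A, scenario.CANDIDATE_B}
        assert strict.candidates == []
        # diagnostics survive a total wipe-out
        assert all(ev.contradictions > 0 for ev in strict.evaluations)
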