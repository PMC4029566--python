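"""A synthetic reconstruction of the partial-reduction evidence that leaves
exactly two candidate disulfide patterns.

The historical deduction for the salamander pheromone ran: a single reduced
disulfide, alkylation, chymotryptic digestion and LC-MS/MS identified peptide
pairs carrying bonds 1-2 and 4-5; the fragment-ion series of the peptide
holding Cys 6, 7 and 8 did not support alkylation of Cys 8; and since
adjacent cysteines essentially never bond each other, no pattern containing
3-8 together with 6-7 is viable.  That evidence pins the connectivity down to
{1-2, 3-6, 4-5, 7-8} or {1-2, 3-7, 4-5, 6-8} — an ambiguity mass
spectrometry alone cannot resolve.

The fixture below is synthetic: a toy 8-cysteine sequence engineered so that
chymotrypsin isolates cysteines 1-5 in separate peptides and the adjacent
6-7 doublet plus 8 in a single C-terminal peptide, mirroring the structure
of the real evidence without the (unpublished) observed masses.
"""

from __future__ import annotations

from . import masscalc
from .ssbond import (CysteineFramework, MassObservation, TreatmentCondition,
                     make_pattern)

#: synthetic stand-in sequence; chymotryptic peptides are
#: ACAL / GCGF / SCSAL / GGCAF / TCTGL / CCAGGACN
SCENARIO_SEQUENCE = "ACALGCGFSCSALGGCAFTCTGLCCAGGACN"

#: the two connectivities the evidence cannot distinguish
CANDIDATE_A = make_pattern([(1, 2), (3, 6), (4, 5), (7, 8)])
CANDIDATE_B = make_pattern([(1, 2), (3, 7), (4, 5), (6, 8)])
#: the canonical three-finger-protein pattern, excluded by the evidence
CANONICAL_TFP = make_pattern([(1, 3), (2, 4), (5, 6), (7, 8)])


def scenario_observations(tol_ppm: float = 10.0
                          ) -> tuple[str, CysteineFramework, list[MassObservation]]:
    """Sequence, framework and the qualitative evidence set.

    Three peaks from the one-bond-reduced, alkylated, chymotrypsin-digested
    species: the 1-2 linked peptide pair, the 4-5 linked pair, and the
    Cys-6,7,8 peptide carrying one CAM and one intact internal bond, whose
    fragment ions rule out alkylation at Cys 8.
    """
    seq = SCENARIO_SEQUENCE
    framework = CysteineFramework.from_sequence(seq)
    treatment = TreatmentCondition(enzyme="chymotrypsin", dtt=False, iaa=True,
                                   n_reduced=1)
    pep = {1: "ACAL", 2: "GCGF", 4: "GGCAF", 5: "TCTGL", 678: "CCAGGACN"}
    m = {k: masscalc.peptide_mass(v) for k, v in pep.items()}
    h = masscalc.DISULFIDE_H_PER_CYS
    cam = masscalc.CAM_DELTA["mono"]
    observations = [
        # peptide pair joined by bond 1-2 (two bonded cysteines)
        MassObservation(m[1] + m[2] - 2 * h, tol_ppm, treatment),
        # peptide pair joined by bond 4-5
        MassObservation(m[4] + m[5] - 2 * h, tol_ppm, treatment),
        # Cys-6,7,8 peptide: one CAM from the reduced bond, one internal bond
        # intact; the ion series shows the CAM is not on Cys 8
        MassObservation(m[678] + cam - 2 * h, tol_ppm, treatment,
                        annotation="Cys8 not alkylated"),
    ]
    return seq, framework, observations
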