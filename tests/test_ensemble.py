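"""Superposition, RMSF/RMSD statistics and geometric screens."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from pmfstruct import synthetic as syn
from pmfstruct.ensemble import (ModelEnsemble, avg_rmsd_to_mean,
                                disulfide_geometry, hbond_candidates,
                                per_residue_rmsf, superpose_ensemble)


def toy_ensemble(n_models=3, n_residues=5, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    atoms = pd.DataFrame(
        [(r + 1, "ALA", name) for r in range(n_residues)
         for name in ("N", "CA", "C", "O")],
        columns=["residue_id", "residue_name", "atom_name"])
    base = rng.uniform(-10, 10, size=(len(atoms), 3))
    coords = np.stack([base + jitter * rng.standard_normal(base.shape)
                       for _ in range(n_models)])
    return ModelEnsemble(atoms, coords)


class TestSuperposition:
    def test_identical_models_converge_immediately(self):
        ens = toy_ensemble(jitter=0.0)
        res = superpose_ensemble(ens)
        assert res.converged
        np.testing.assert_allclose(res.rotations,
                                   np.tile(np.eye(3), (ens.n_models, 1, 1)),
                                   atol=1e-9)

    def test_known_rigid_rotation_recovered(self):
        ens = toy_ensemble(n_models=1)
        rot = Rotation.from_euler("xyz", [30, -40, 75], degrees=True).as_matrix()
        moved = ens.coords[0] @ rot.T + np.array([5.0, -3.0, 9.0])
        pair = ModelEnsemble(ens.atoms, np.stack([ens.coords[0], moved]))
        res = superpose_ensemble(pair)
        rmsd = avg_rmsd_to_mean(res)
        assert rmsd.mean < 1e-6
        assert np.allclose(np.linalg.det(res.rotations), 1.0)

    def test_single_model_is_identity(self):
        ens = toy_ensemble(n_models=1)
        res = superpose_ensemble(ens)
        assert res.converged
        np.testing.assert_allclose(res.mean_coords, ens.coords[0], atol=1e-12)

    def test_rigid_pretransform_invariance(self):
        ens = toy_ensemble(n_models=4, jitter=0.5, seed=3)
        rmsf_a = per_residue_rmsf(superpose_ensemble(ens))
        rng = np.random.default_rng(9)
        moved = []
        for m in range(ens.n_models):
            r = Rotation.random(rng=rng).as_matrix()
            moved.append(ens.coords[m] @ r.T + rng.uniform(-30, 30, 3))
        rmsf_b = per_residue_rmsf(
            superpose_ensemble(ModelEnsemble(ens.atoms, np.stack(moved))))
        np.testing.assert_allclose(rmsf_a.values, rmsf_b.values, atol=1e-6)

    def test_mismatched_roster_rejected(self, tmp_path):
        from pmfstruct.ensemble import read_pdb_ensemble, write_pdb_ensemble
        se = syn.gen_ensemble(n_models=2, n_residues=8, seed=0)
        path = tmp_path / "ens.pdb"
        write_pdb_ensemble(se.ensemble, path)
        text = path.read_text().splitlines()
        # drop one atom from the second model only
        out, dropped, in_second = [], False, False
        for line in text:
            if line.startswith("MODEL") and "2" in line.split():
                in_second = True
            if in_second and not dropped and line.startswith("ATOM"):
                dropped = True
                continue
            out.append(line)
        bad = tmp_path / "bad.pdb"
        bad.write_text("\n".join(out) + "\n")
        with pytest.raises(ValueError, match="roster"):
            read_pdb_ensemble(bad)


class TestEnsembleStatistics:
    def test_identical_models_zero_rmsf_and_rmsd(self):
        ens = toy_ensemble(jitter=0.0)
        res = superpose_ensemble(ens)
        assert per_residue_rmsf(res).max() == pytest.approx(0.0, abs=1e-9)
        rmsd = avg_rmsd_to_mean(res)
        assert rmsd.mean == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_displacement_gives_half_delta_rmsf(self):
        # two models, one atom displaced +/- delta/2 about the mean
        ens = toy_ensemble(n_models=2, n_residues=2, jitter=0.0)
        delta = 0.8
        coords = ens.coords.copy()
        coords[0, 0, 0] += delta / 2
        coords[1, 0, 0] -= delta / 2
        moved = ModelEnsemble(ens.atoms, coords)
        # deviations measured against the fixed mean, no re-fitting
        from pmfstruct.ensemble import SuperpositionResult
        res = SuperpositionResult(
            rotations=np.tile(np.eye(3), (2, 1, 1)),
            translations=np.zeros((2, 3)),
            mean_coords=coords.mean(axis=0),
            transformed=moved, converged=True, n_iterations=0,
            selection_mask=moved.selection_mask("backbone"))
        rmsf = per_residue_rmsf(res)
        # residue 1 has 4 backbone atoms, one displaced by delta/2:
        # RMSF = sqrt((delta/2)^2 / 4) = delta/4
        assert rmsf[1] == pytest.approx(delta / 4, rel=1e-6)
        assert rmsf[2] == pytest.approx(0.0, abs=1e-9)

    def test_heavy_rmsd_at_least_backbone_rmsd(self):
        for seed in range(5):
            se = syn.gen_ensemble(n_models=6, n_residues=20, seed=seed,
                                  base_amplitude=0.4)
            res = superpose_ensemble(se.ensemble, "backbone")
            heavy = avg_rmsd_to_mean(res, "heavy")
            backbone = avg_rmsd_to_mean(res, "backbone")
            assert heavy.mean >= backbone.mean

    def test_flexible_region_has_higher_rmsf(self):
        se = syn.gen_ensemble(n_models=12, n_residues=40,
                              base_amplitude=0.3,
                              region_amplitudes={(25, 34): 0.9}, seed=1)
        res = superpose_ensemble(se.ensemble)
        rmsf = per_residue_rmsf(res)
        flexible = rmsf.loc[27:32].mean()    # interior of the flexible region
        rigid = rmsf.loc[1:20].mean()
        assert flexible > rigid


class TestGeometry:
    def test_disulfide_distances_and_flags(self):
        atoms = pd.DataFrame([
            (1, "CYS", "SG"), (2, "CYS", "SG"),
            (3, "CYS", "SG"), (4, "CYS", "SG")],
            columns=["residue_id", "residue_name", "atom_name"])
        coords = np.array([[[0, 0, 0], [2.05, 0, 0],
                            [10, 0, 0], [14, 0, 0]]], dtype=float)
        model = ModelEnsemble(atoms, coords)
        geo = disulfide_geometry(model, [1, 2, 3, 4], [(1, 2), (3, 4)])
        assert geo[0].distance_A == pytest.approx(2.05)
        assert geo[0].within_range
        assert geo[1].distance_A == pytest.approx(4.0)
        assert not geo[1].within_range

    def test_missing_sg_reported_per_bond(self):
        atoms = pd.DataFrame([(1, "CYS", "SG"), (2, "ALA", "CA")],
                             columns=["residue_id", "residue_name", "atom_name"])
        model = ModelEnsemble(atoms, np.zeros((1, 2, 3)))
        geo = disulfide_geometry(model, [1, 2], [(1, 2)])
        assert geo[0].distance_A is None and "cysteine 2" in geo[0].message

    def test_synthetic_template_bonds_within_range(self):
        pattern = frozenset({(1, 2), (3, 4)})
        se = syn.gen_ensemble(n_models=2, sequence="ACAAACAAAACAAACAAA",
                              pattern=pattern, seed=5)
        geo = disulfide_geometry(se.template, list(se.cys_residue_ids),
                                 [(1, 2), (3, 4)])
        assert all(g.within_range for g in geo)
        assert all(g.distance_A == pytest.approx(2.02, abs=1e-9) for g in geo)


class TestHBondScreen:
    def _model(self, donor_xyz, acceptor_xyz, far_xyz=(50.0, 0, 0)):
        atoms = pd.DataFrame([
            (2, "GLN", "O"), (40, "ALA", "O"), (55, "LEU", "N")],
            columns=["residue_id", "residue_name", "atom_name"])
        coords = np.array([[acceptor_xyz, far_xyz, donor_xyz]], dtype=float)
        return ModelEnsemble(atoms, coords)

    def test_acceptor_within_cutoff_reported(self):
        # a termini-adjacent pairing: late-chain amide donor to the backbone
        # carbonyl of residue 2
        model = self._model((0, 0, 0), (2.0, 0, 0))
        hits = hbond_candidates([55], model)
        assert [(h.donor_residue, h.acceptor_residue) for h in hits] == [(55, 2)]
        assert hits[0].distance_A == pytest.approx(2.0)

    def test_no_acceptor_within_cutoff(self):
        model = self._model((0, 0, 0), (3.1, 0, 0))
        assert hbond_candidates([55], model) == []

    def test_missing_donor_skipped(self):
        model = self._model((0, 0, 0), (2.0, 0, 0))
        assert hbond_candidates([99], model) == []
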