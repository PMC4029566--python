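"""Multi-model coordinate-ensemble statistics.

Superposition onto an iteratively re-estimated mean structure (proper
Kabsch rotations, no reflections), per-residue RMSF, per-model RMSD to the
mean, disulfide Sg-Sg geometry checks and hydrogen-bond candidate screening
for slowly exchanging amides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class ModelEnsemble:
    """M models sharing one atom roster.

    ``atoms`` has one row per roster atom: residue_id (author numbering),
    residue_name, atom_name.  ``coords`` is (M, N, 3) in Angstrom.
    """

    atoms: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords second axis must match the atom roster")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one model")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def selection_mask(self, selection: str | Callable[[pd.Series], bool]) -> np.ndarray:
        """Boolean atom mask; ``"backbone"`` (N, CA, C, O), ``"heavy"`` (all
        non-hydrogen) or an arbitrary per-row predicate."""
        if callable(selection):
            mask = self.atoms.apply(selection, axis=1).to_numpy(dtype=bool)
        elif selection == "backbone":
            mask = self.atoms["atom_name"].isin(BACKBONE_ATOMS).to_numpy()
        elif selection == "heavy":
            mask = ~self.atoms["atom_name"].str.startswith(("H", "D")).to_numpy()
        else:
            raise ValueError(f"unknown selection {selection!r}")
        if not mask.any():
            raise ValueError("selection matches no atoms")
        return mask

    def model(self, index: int) -> "ModelEnsemble":
        return ModelEnsemble(self.atoms, self.coords[index:index + 1].copy())


def read_pdb_ensemble(path) -> ModelEnsemble:
    """Read a multi-model PDB (MODEL/ENDMDL blocks); altloc A preferred.

    All models must share an identical atom roster; a mismatch is rejected
    with a description of the first differing atom.
    """
    st = gemmi.read_pdb(str(path))
    st.remove_alternative_conformations()
    rosters, coord_sets = [], []
    for model in st:
        rows, xyz = [], []
        for chain in model:
            for res in chain:
                for atom in res:
                    rows.append((res.seqid.num, res.name, atom.name))
                    xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
        rosters.append(rows)
        coord_sets.append(xyz)
    if not rosters:
        raise ValueError(f"no models found in {path}")
    first = rosters[0]
    for i, roster in enumerate(rosters[1:], start=2):
        if roster != first:
            diff = next((a, b) for a, b in zip(first, roster) if a != b) \
                if len(roster) == len(first) else (len(first), len(roster))
            raise ValueError(f"model {i} atom roster differs from model 1: {diff}")
    atoms = pd.DataFrame(first, columns=["residue_id", "residue_name", "atom_name"])
    return ModelEnsemble(atoms, np.array(coord_sets))


def write_pdb_ensemble(ens: ModelEnsemble, path, chain_id: str = "A") -> None:
    st = gemmi.Structure()
    st.name = "ensemble"
    for m in range(ens.n_models):
        model = gemmi.Model(m + 1)
        chain = gemmi.Chain(chain_id)
        current = None
        res = None
        for i, row in enumerate(ens.atoms.itertuples(index=False)):
            if row.residue_id != current:
                res = gemmi.Residue()
                res.name = row.residue_name
                res.seqid = gemmi.SeqId(int(row.residue_id), " ")
                chain.add_residue(res)
                current = row.residue_id
                res = chain[-1]
            atom = gemmi.Atom()
            atom.name = row.atom_name
            atom.element = gemmi.Element(row.atom_name[0])
            x, y, z = ens.coords[m, i]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            res.add_atom(atom)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


# --- superposition -----------------------------------------------------------

@dataclass
class SuperpositionResult:
    rotations: np.ndarray          # (M, 3, 3), proper
    translations: np.ndarray       # (M, 3) applied after rotation
    mean_coords: np.ndarray        # (N, 3) over the full roster
    transformed: ModelEnsemble
    converged: bool
    n_iterations: int
    selection_mask: np.ndarray


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper least-squares rotation + translation mapping mobile onto target."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    r = rot.as_matrix()
    t = tc - r @ mc
    return r, t


def superpose_ensemble(ens: ModelEnsemble, selection: str = "backbone",
                       tol: float = 1e-6, max_iter: int = 100) -> SuperpositionResult:
    """Superpose every model onto the iteratively re-estimated mean structure.

    The mean is initialized on model 1, every model is fitted to it over the
    selection, the mean is recomputed, and the cycle repeats until the mean
    shifts by less than ``tol`` Angstrom (RMS over selected atoms).
    """
    mask = ens.selection_mask(selection)
    coords = ens.coords.copy()
    mean_sel = coords[0, mask].copy()
    rotations = np.tile(np.eye(3), (ens.n_models, 1, 1))
    translations = np.zeros((ens.n_models, 3))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for m in range(ens.n_models):
            r, t = _kabsch(coords[m, mask], mean_sel)
            coords[m] = coords[m] @ r.T + t
            rotations[m] = r @ rotations[m]
            translations[m] = r @ translations[m] + t
        new_mean = coords[:, mask].mean(axis=0)
        shift = math.sqrt(float(np.mean(np.sum((new_mean - mean_sel) ** 2, axis=1))))
        mean_sel = new_mean
        if shift < tol:
            converged = True
            break
    for m in range(ens.n_models):
        if np.linalg.det(rotations[m]) < 0:
            raise RuntimeError("improper rotation produced during superposition")
    transformed = ModelEnsemble(ens.atoms, coords)
    return SuperpositionResult(rotations=rotations, translations=translations,
                               mean_coords=coords.mean(axis=0),
                               transformed=transformed, converged=converged,
                               n_iterations=it, selection_mask=mask)


# --- ensemble statistics -----------------------------------------------------

def per_residue_rmsf(result: SuperpositionResult,
                     selection: str = "backbone") -> pd.Series:
    """RMSF_r = sqrt(mean over models and selected atoms of residue r of the
    squared deviation from the mean structure), in Angstrom."""
    ens = result.transformed
    mask = ens.selection_mask(selection)
    dev2 = np.sum((ens.coords - result.mean_coords) ** 2, axis=2)  # (M, N)
    res_ids = ens.atoms["residue_id"].to_numpy()
    out = {}
    for rid in pd.unique(res_ids):
        sel = mask & (res_ids == rid)
        if sel.any():
            out[rid] = float(np.sqrt(dev2[:, sel].mean()))
    return pd.Series(out, name="rmsf_A")


@dataclass(frozen=True)
class RmsdToMean:
    per_model: tuple[float, ...]
    mean: float
    sd: float


def avg_rmsd_to_mean(result: SuperpositionResult,
                     selection: str = "backbone") -> RmsdToMean:
    """Per-model RMSD to the mean structure over a selection, with the
    ensemble average and standard deviation."""
    ens = result.transformed
    mask = ens.selection_mask(selection)
    dev2 = np.sum((ens.coords[:, mask] - result.mean_coords[mask]) ** 2, axis=2)
    per_model = np.sqrt(dev2.mean(axis=1))
    return RmsdToMean(per_model=tuple(float(v) for v in per_model),
                      mean=float(per_model.mean()),
                      sd=float(per_model.std(ddof=1)) if len(per_model) > 1 else 0.0)


# --- disulfide and hydrogen-bond geometry ------------------------------------

@dataclass(frozen=True)
class BondGeometry:
    ordinals: tuple[int, int]
    distance_A: float | None
    within_range: bool
    message: str = ""


def disulfide_geometry(model: ModelEnsemble, cys_residue_ids: Sequence[int],
                       pattern: Iterable[tuple[int, int]],
                       bond_range: tuple[float, float] = (1.8, 2.5)
                       ) -> list[BondGeometry]:
    """Sg-Sg distances for each disulfide of a single model.

    ``cys_residue_ids`` maps cysteine ordinal (1-based index in the list) to
    residue id; bonds outside ``bond_range`` Angstrom are flagged.
    """
    if model.n_models != 1:
        raise ValueError("disulfide_geometry expects a single model")
    atoms = model.atoms
    coords = model.coords[0]

    def sg(ordinal: int) -> np.ndarray | None:
        rid = cys_residue_ids[ordinal - 1]
        hit = atoms.index[(atoms["residue_id"] == rid) & (atoms["atom_name"] == "SG")]
        return coords[hit[0]] if len(hit) else None

    out = []
    for i, j in pattern:
        a, b = sg(i), sg(j)
        if a is None or b is None:
            missing = i if a is None else j
            out.append(BondGeometry((i, j), None, False,
                                    f"missing SG for cysteine {missing}"))
            continue
        d = float(np.linalg.norm(a - b))
        out.append(BondGeometry((i, j), d, bond_range[0] <= d <= bond_range[1]))
    return out


@dataclass(frozen=True)
class HBondCandidate:
    donor_residue: int
    acceptor_residue: int
    distance_A: float


def hbond_candidates(slow_exchangers: Iterable[int], model: ModelEnsemble,
                     cutoff_A: float = 2.5) -> list[HBondCandidate]:
    """Backbone carbonyl acceptors within ``cutoff_A`` of each slow-exchanging
    amide donor (amide H when present, else N as a proxy).

    The donor's own residue and its sequence predecessor are excluded — the
    preceding carbonyl is covalently constrained near the amide regardless of
    hydrogen bonding.  Residues with missing donor atoms are skipped.
    """
    if model.n_models != 1:
        raise ValueError("hbond_candidates expects a single model")
    atoms = model.atoms
    coords = model.coords[0]
    acc_idx = atoms.index[atoms["atom_name"] == "O"]
    out = []
    for res in slow_exchangers:
        donor = atoms.index[(atoms["residue_id"] == res) & (atoms["atom_name"] == "H")]
        if not len(donor):
            donor = atoms.index[(atoms["residue_id"] == res) & (atoms["atom_name"] == "N")]
        if not len(donor):
            continue
        dpos = coords[donor[0]]
        for ai in acc_idx:
            ares = int(atoms.loc[ai, "residue_id"])
            if ares in (res, res - 1):
                continue
            d = float(np.linalg.norm(coords[ai] - dpos))
            if d < cutoff_A:
                out.append(HBondCandidate(res, ares, d))
    return out
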