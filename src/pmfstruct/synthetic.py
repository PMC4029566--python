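"""Seedable generators emulating every input the analysis stages consume.

Each generator draws from its own RNG substream of a master seed
(``SeedSequence([seed, stream_id])``), so fixtures are reproducible per stage
and independent across stages.  Ground truth is always returned alongside the
data so downstream recovery can be tested.

The defaults emulate the study system: a ~60-residue protein with 8 cysteines
in a hidden perfect-matching disulfide pattern, partial-reduction MS
observations with ppm-scale noise and peak dropout, mono-exponential
relaxation/HDX decays driven by a Lipari-Szabo spectral density at 18.8 T,
alignments with a conserved cysteine scaffold and a hypervariable indel-prone
third finger, and coordinate ensembles with region-dependent backbone
dispersion.
"""

from __future__ import annotations

import itertools
import math
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import nmr, seqvar
from .ensemble import ModelEnsemble
from .nmr import (R1_DELAYS_S, R2_DELAYS_S, FieldParams, HDXSeries, HetNOEPair,
                  RelaxationSeries)
from .seqvar import MSA
from .ssbond import (Bond, CysteineFramework, MassObservation, Pattern,
                     SpeciesPredictor, TreatmentCondition, bond,
                     enumerate_patterns)

_STREAMS = {"protein": 1, "ms": 2, "dynamics": 3, "hdx": 4, "msa": 5, "ensemble": 6}

NON_CYS = "ADEFGHIKLMNPQRSTVWY"


def substream(seed: int, name: str) -> np.random.Generator:
    """Per-generator RNG substream of a master seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[name]]))


# --- protein -----------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticProtein:
    sequence: str
    framework: CysteineFramework
    pattern: Pattern


def random_pattern(n_cysteines: int, rng: np.random.Generator) -> Pattern:
    ordinals = list(range(1, n_cysteines + 1))
    rng.shuffle(ordinals)
    return frozenset(bond(ordinals[i], ordinals[i + 1])
                     for i in range(0, n_cysteines, 2))


def gen_protein(length: int = 60, n_cysteines: int = 8,
                pattern: Pattern | None = None,
                adjacent_doublet: bool = False,
                seed: int = 0) -> SyntheticProtein:
    """A random protein with cysteines at non-colliding positions and a
    hidden disulfide pattern.

    With ``adjacent_doublet`` exactly one CC pair is planted (the scaffold
    doublet seen in three-finger proteins); otherwise all cysteines are at
    least two residues apart.
    """
    if n_cysteines % 2 or n_cysteines < 2:
        raise ValueError("cysteine count must be even and >= 2")
    if length < 3 * n_cysteines:
        raise ValueError("sequence too short to place cysteines without collision")
    rng = substream(seed, "protein")
    for _ in range(1000):
        positions = np.sort(rng.choice(np.arange(2, length), size=n_cysteines,
                                       replace=False))
        gaps = np.diff(positions)
        if adjacent_doublet:
            if np.sum(gaps == 1) == 1 and np.all(gaps[gaps != 1] >= 2):
                break
        elif np.all(gaps >= 2):
            break
    else:
        raise RuntimeError("could not place cysteines under the constraints")
    body = rng.choice(list(NON_CYS), size=length)
    for p in positions:
        body[p - 1] = "C"
    sequence = "".join(body)
    framework = CysteineFramework.from_sequence(sequence)
    if pattern is None:
        pattern = random_pattern(n_cysteines, rng)
    if 2 * len(pattern) != n_cysteines:
        raise ValueError("pattern does not match the cysteine count")
    return SyntheticProtein(sequence, framework, pattern)


# --- mass-spectral observations ----------------------------------------------

def default_treatments() -> list[TreatmentCondition]:
    """The informative cells of the treatment grid: both proteases, the
    unreduced control and the one-bond partial-reduction species, alkylated,
    without subsequent full reduction."""
    return [TreatmentCondition(enzyme=e, dtt=False, iaa=True, n_reduced=n)
            for e in ("chymotrypsin", "aspn") for n in (0, 1)]


@dataclass(frozen=True)
class SyntheticMSDataset:
    observations: tuple[MassObservation, ...]
    true_pattern: Pattern
    n_true_peaks: int
    n_contaminants: int


def gen_ms_dataset(protein: SyntheticProtein,
                   treatments: Sequence[TreatmentCondition] | None = None,
                   noise_ppm: float = 5.0,
                   dropout: float = 0.2,
                   contaminant_rate: float = 0.0,
                   tol_ppm: float = 10.0,
                   annotate_cam: bool = True,
                   seed: int = 0) -> SyntheticMSDataset:
    """Observed neutral masses under the true pattern, with Gaussian ppm noise,
    Bernoulli peak dropout and optional uniform-in-log-mass contaminants.

    With ``annotate_cam`` each CAM-carrying species additionally yields
    fragment-level observations annotated ``"Cys<k> alkylated"``, emulating
    confirmation of the alkylation site from the fragment-ion series; each
    emitted peak is subject to dropout and noise independently.
    """
    if treatments is None:
        treatments = default_treatments()
    if not treatments:
        raise ValueError("treatment list must not be empty")
    if not 0.0 <= dropout <= 1.0:
        raise ValueError("dropout must be a probability")
    rng = substream(seed, "ms")
    pos_to_ordinal = {p: o for o, p in enumerate(protein.framework.positions, 1)}
    predictor = SpeciesPredictor(protein.sequence, protein.framework)
    observations: list[MassObservation] = []
    n_true = 0
    n_cont = 0
    for tr in treatments:
        peaks: set[tuple[float, str | None]] = set()
        for species, m in predictor.predict_for_treatment(protein.pattern, tr):
            peaks.add((round(m, 6), None))
            if annotate_cam:
                for p, st in species.mods.statuses.items():
                    if st == "cam":
                        peaks.add((round(m, 6),
                                   f"Cys{pos_to_ordinal[p]} alkylated"))
        for m, annotation in sorted(peaks, key=lambda x: (x[0], x[1] or "")):
            if rng.random() < dropout:
                continue
            noisy = m * (1.0 + noise_ppm * 1e-6 * rng.standard_normal())
            observations.append(MassObservation(noisy, tol_ppm, tr, annotation))
            n_true += 1
        if contaminant_rate > 0 and peaks:
            masses = [m for m, _ in peaks]
            lo, hi = math.log(min(masses)), math.log(max(masses))
            for _ in range(rng.poisson(contaminant_rate)):
                observations.append(MassObservation(
                    math.exp(rng.uniform(lo, hi)), tol_ppm, tr))
                n_cont += 1
    return SyntheticMSDataset(tuple(observations), protein.pattern, n_true, n_cont)


# --- relaxation / NOE --------------------------------------------------------

@dataclass(frozen=True)
class SyntheticDynamics:
    r1_series: tuple[RelaxationSeries, ...]
    r2_series: tuple[RelaxationSeries, ...]
    noe_pairs: tuple[HetNOEPair, ...]
    truth: pd.DataFrame           # residue, s2, r1, r2, noe, j0, jn, jh
    field: FieldParams


def gen_dynamics_dataset(s2: Sequence[float],
                         tau_m: float = 5e-9,
                         tau_e: float = 50e-12,
                         field: FieldParams | None = None,
                         r1_delays: Sequence[float] = R1_DELAYS_S,
                         r2_delays: Sequence[float] = R2_DELAYS_S,
                         snr: float = 50.0,
                         r_ex: Sequence[float] | None = None,
                         seed: int = 0) -> SyntheticDynamics:
    """Forward-simulate R1/R2/NOE from a Lipari-Szabo spectral density.

    The observables are generated with the same reduced-form coefficient
    relations the mapping inverts, evaluated at (0, wN, 0.87wH).  Intensity
    series are unit-amplitude decays with additive Gaussian noise of standard
    deviation 1/snr; NOE peak volumes get the same noise.
    """
    field = field or FieldParams.from_proton_mhz()
    rng = substream(seed, "dynamics")
    sigma = 1.0 / snr if math.isfinite(snr) else 0.0
    rows, r1s, r2s, noes = [], [], [], []
    rex = r_ex if r_ex is not None else [0.0] * len(s2)
    for i, (s2_i, rex_i) in enumerate(zip(s2, rex), start=1):
        j0 = nmr.lipari_szabo_j(0.0, s2_i, tau_m, tau_e)
        jn = nmr.lipari_szabo_j(field.omega_n, s2_i, tau_m, tau_e)
        jh = nmr.lipari_szabo_j(field.omega_high, s2_i, tau_m, tau_e)
        r1, r2, noe = nmr.relaxation_from_j(j0, jn, jh, field, r_ex=rex_i)
        rows.append(dict(residue=i, s2=s2_i, r1=r1, r2=r2, noe=noe,
                         j0=j0, jn=jn, jh=jh))
        r1s.append(RelaxationSeries(
            i, tuple(r1_delays),
            tuple(math.exp(-r1 * t) + sigma * rng.standard_normal()
                  for t in r1_delays), "R1"))
        r2s.append(RelaxationSeries(
            i, tuple(r2_delays),
            tuple(math.exp(-r2 * t) + sigma * rng.standard_normal()
                  for t in r2_delays), "R2"))
        noes.append(HetNOEPair(i,
                               noe + sigma * rng.standard_normal(),
                               1.0 + sigma * rng.standard_normal()))
    return SyntheticDynamics(tuple(r1s), tuple(r2s), tuple(noes),
                             pd.DataFrame(rows), field)


# --- hydrogen/deuterium exchange ---------------------------------------------

@dataclass(frozen=True)
class SyntheticHDX:
    series: tuple[HDXSeries, ...]
    true_k_per_h: Mapping[int, float]
    true_halflife_h: Mapping[int, float]


def gen_hdx_dataset(k_per_h: Mapping[int, float],
                    times_h: Sequence[float] = tuple(range(1, 25)),
                    noise: float = 0.0,
                    detection_floor: float = 0.05,
                    seed: int = 0) -> SyntheticHDX:
    """Peak-integral decay series v = exp(-k t) (+ noise) sampled hourly.

    Points whose noiseless signal falls below ``detection_floor`` are not
    observed, so fast exchangers naturally surface with fewer than three
    points and exercise the undetectable path downstream.
    """
    rng = substream(seed, "hdx")
    series = []
    for res, k in sorted(k_per_h.items()):
        if k <= 0:
            raise ValueError(f"rate for residue {res} must be positive")
        ts, vs = [], []
        for t in times_h:
            v = math.exp(-k * t)
            if v < detection_floor:
                continue
            ts.append(float(t))
            vs.append(v + noise * rng.standard_normal())
        series.append(HDXSeries(res, tuple(ts), tuple(vs)))
    truth_hl = {res: math.log(2.0) / k for res, k in k_per_h.items()}
    return SyntheticHDX(tuple(series), dict(k_per_h), truth_hl)


# --- alignments --------------------------------------------------------------

#: scaffold inter-cysteine gaps before the hypervariable region: the first
#: spacing is the conserved 9-residue gap; after the region comes the CC
#: doublet, 4 residues, the last cysteine and an N.
SCAFFOLD_GAPS = (9, 4, 12, 3)
POST_REGION = ("CC", 4)


@dataclass(frozen=True)
class SyntheticMSA:
    msa: MSA
    region_cols: tuple[int, int]          # 1-based inclusive alignment span
    region_lengths: tuple[int, ...]       # per-row ungapped length
    reference: str                        # ungapped row 0
    mutated_cols: tuple[int, ...]         # 1-based columns carrying >= 1 substitution


def gen_msa(n_sequences: int = 24,
            substitution_prob: float = 0.05,
            region_substitution_prob: float = 0.6,
            region_lengths: Sequence[int] = (13, 14, 15, 16, 17, 18),
            n_term: int = 3,
            seed: int = 0) -> SyntheticMSA:
    """Pre-aligned family with an invariant cysteine scaffold and a
    hypervariable, indel-prone region between the 5th and 6th cysteines.

    Indels are realized directly as gap columns: each row draws its region
    length from ``region_lengths`` and is padded to the longest.
    """
    if n_sequences < 1:
        raise ValueError("need at least one sequence")
    rng = substream(seed, "msa")

    def draw(n: int) -> str:
        return "".join(rng.choice(list(NON_CYS), size=n))

    pre_parts = [draw(n_term)]
    for g in SCAFFOLD_GAPS:
        pre_parts.append("C" + draw(g))
    pre_parts.append("C")
    pre = "".join(pre_parts)                      # ...through the 5th cysteine
    post = POST_REGION[0] + draw(POST_REGION[1]) + "C" + "N"
    lengths = tuple(int(rng.choice(region_lengths)) for _ in range(n_sequences))
    lmax = max(lengths)

    rows: list[str] = []
    base_region = draw(lengths[0])
    for r in range(n_sequences):
        pre_r = "".join(aa if aa == "C" or rng.random() >= substitution_prob
                        else str(rng.choice(list(NON_CYS)))
                        for aa in pre)
        post_r = "".join(aa if aa in "CN" or rng.random() >= substitution_prob
                         else str(rng.choice(list(NON_CYS)))
                         for aa in post)
        if r == 0:
            region = base_region
        else:
            region = "".join(
                base_region[i]
                if i < len(base_region) and rng.random() >= region_substitution_prob
                else str(rng.choice(list(NON_CYS)))
                for i in range(lengths[r]))
        rows.append(pre_r + region + seqvar.GAP * (lmax - lengths[r]) + post_r)
    msa = MSA(tuple(f"seq{i + 1}" for i in range(n_sequences)), tuple(rows))
    region_cols = (len(pre) + 1, len(pre) + lmax)
    mutated = tuple(j + 1 for j in range(msa.n_cols)
                    if len(set(msa.column(j)) - {seqvar.GAP}) > 1)
    return SyntheticMSA(msa, region_cols, lengths, msa.ungapped(0), mutated)


# --- coordinate ensembles ----------------------------------------------------

@dataclass(frozen=True)
class SyntheticEnsemble:
    ensemble: ModelEnsemble
    template: ModelEnsemble
    amplitudes_A: tuple[float, ...]       # per-residue dispersion scale
    cys_residue_ids: tuple[int, ...]
    pattern: Pattern | None


def _template_coords(sequence: str, rng: np.random.Generator,
                     pattern: Pattern | None,
                     ss_bond_length: float = 2.02) -> tuple[pd.DataFrame, np.ndarray]:
    """Backbone trace (N, CA, C, O per residue, SG on cysteines) along a
    smooth random walk; bonded Sg pairs placed at the disulfide distance."""
    n = len(sequence)
    # smooth CA walk: random directions low-pass filtered, 3.8 A steps
    dirs = rng.standard_normal((n, 3))
    kernel = np.ones(7) / 7
    for k in range(3):
        dirs[:, k] = np.convolve(dirs[:, k], kernel, mode="same")
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    ca = np.cumsum(3.8 * dirs, axis=0)
    offsets = {"N": np.array([-0.8, 0.9, 0.0]),
               "CA": np.zeros(3),
               "C": np.array([0.9, -0.8, 0.0]),
               "O": np.array([1.2, -1.6, 0.6])}
    rows, xyz = [], []
    sg_index: dict[int, int] = {}
    for i, aa in enumerate(sequence, start=1):
        resname = "CYS" if aa == "C" else "ALA"
        for name in ("N", "CA", "C", "O"):
            rows.append((i, resname, name))
            xyz.append(ca[i - 1] + offsets[name])
        if aa == "C":
            sg_index[i] = len(rows)
            rows.append((i, "CYS", "SG"))
            xyz.append(ca[i - 1] + np.array([0.0, 1.3, 1.3]))
    coords = np.array(xyz)
    if pattern:
        cys_ids = sorted(sg_index)
        for i, j in pattern:
            pi, pj = cys_ids[i - 1], cys_ids[j - 1]
            mid = 0.5 * (coords[sg_index[pi]] + coords[sg_index[pj]])
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            coords[sg_index[pi]] = mid - 0.5 * ss_bond_length * u
            coords[sg_index[pj]] = mid + 0.5 * ss_bond_length * u
    atoms = pd.DataFrame(rows, columns=["residue_id", "residue_name", "atom_name"])
    return atoms, coords


def gen_ensemble(n_models: int = 20,
                 sequence: str | None = None,
                 n_residues: int = 60,
                 base_amplitude: float = 0.3,
                 region_amplitudes: Mapping[tuple[int, int], float] | None = None,
                 pattern: Pattern | None = None,
                 smoothing: int = 5,
                 seed: int = 0) -> SyntheticEnsemble:
    """Template structure plus correlated per-residue Gaussian backbone
    perturbations, scaled per region, with a random rigid motion per model.

    ``region_amplitudes`` maps 1-based inclusive residue ranges to dispersion
    amplitudes (Angstrom) overriding ``base_amplitude``; the perturbation
    field is smoothed along the chain so neighbouring residues move together.
    """
    rng = substream(seed, "ensemble")
    if sequence is None:
        sequence = "".join(rng.choice(list(NON_CYS), size=n_residues))
    n = len(sequence)
    atoms, template = _template_coords(sequence, rng, pattern)
    amps = np.full(n, base_amplitude)
    for (lo, hi), a in (region_amplitudes or {}).items():
        if not (1 <= lo <= hi <= n):
            raise ValueError(f"region ({lo}, {hi}) outside 1..{n}")
        amps[lo - 1:hi] = a
    res_ids = atoms["residue_id"].to_numpy()
    models = []
    kernel = np.ones(smoothing) / smoothing if smoothing > 1 else np.ones(1)
    sidechain = ~atoms["atom_name"].isin(("N", "CA", "C", "O")).to_numpy()
    for _ in range(n_models):
        disp = rng.standard_normal((n, 3))
        for k in range(3):
            disp[:, k] = np.convolve(disp[:, k], kernel, mode="same")
        disp *= amps[:, None] / max(np.sqrt(1.0 / len(kernel)), 1e-12)
        coords = template + disp[res_ids - 1]
        # side-chain atoms disperse more than the backbone they hang off
        jitter = rng.standard_normal((len(atoms), 3))
        coords = coords + np.where(sidechain[:, None],
                                   0.5 * amps[res_ids - 1][:, None] * jitter, 0.0)
        # random rigid motion so superposition has work to do
        from scipy.spatial.transform import Rotation
        r = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-20, 20, size=3)
        models.append(coords @ r.T + t)
    ens = ModelEnsemble(atoms, np.array(models))
    tmpl = ModelEnsemble(atoms, template[None, :, :].copy())
    cys_ids = tuple(i + 1 for i, aa in enumerate(sequence) if aa == "C")
    return SyntheticEnsemble(ens, tmpl, tuple(amps), cys_ids, pattern)
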