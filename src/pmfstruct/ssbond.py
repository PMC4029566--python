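"""Disulfide-connectivity inference from partial-reduction / alkylation MS data.

The experiment: partially reduce a fully disulfide-bonded protein at low pH so
species with 0-4 cleaved bonds can be separated, alkylate the freed thiols
with iodoacetamide (CAM marks which cysteines were reduced), optionally fully
reduce with DTT, digest, and measure neutral monoisotopic masses.  Which bonds
were cleaved in a partial-reduction species is latent, so every subset of the
stated cardinality is tried.  A candidate connectivity (a perfect matching
over the cysteine ordinals) is eliminated when an observation cannot be
explained by any species it predicts.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Sequence

from . import masscalc
from .masscalc import LinkedSpecies, ModificationState, PeptideSpan

Bond = tuple[int, int]                 # ordinal pair, sorted
Pattern = frozenset[Bond]              # perfect matching over ordinals


def bond(i: int, j: int) -> Bond:
    return (i, j) if i < j else (j, i)


def make_pattern(pairs: Iterable[Sequence[int]]) -> Pattern:
    return frozenset(bond(i, j) for i, j in pairs)


@dataclass(frozen=True)
class CysteineFramework:
    """Cysteine ordinals (1..n, in sequence order) with 1-based positions."""

    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("cysteine positions must be strictly increasing")

    @classmethod
    def from_sequence(cls, sequence: str) -> "CysteineFramework":
        return cls(tuple(i + 1 for i, aa in enumerate(sequence) if aa == "C"))

    @property
    def n(self) -> int:
        return len(self.positions)

    def position(self, ordinal: int) -> int:
        if not 1 <= ordinal <= self.n:
            raise ValueError(f"cysteine ordinal {ordinal} out of range 1..{self.n}")
        return self.positions[ordinal - 1]


@dataclass(frozen=True)
class TreatmentCondition:
    """One cell of the treatment grid: enzyme x reduction x alkylation.

    ``n_reduced`` is the number of disulfides cleaved in the partial-reduction
    species before alkylation; ``dtt`` means full reduction (after any
    alkylation step), ``iaa`` that alkylation was performed.  With the DTT
    flag set, alkylation is taken to reach every cysteine.
    """

    enzyme: str
    dtt: bool = False
    iaa: bool = True
    n_reduced: int = 0
    max_missed: int = 0

    def __post_init__(self) -> None:
        if self.n_reduced < 0:
            raise ValueError("n_reduced must be non-negative")


@dataclass(frozen=True)
class MassObservation:
    """A neutral monoisotopic mass measured under one treatment.

    ``annotation`` carries optional fragment-level evidence from the ion
    series, e.g. ``"Cys8 not alkylated"`` (forbids CAM at ordinal 8 in any
    explaining species) or ``"Cys3 alkylated"``.
    """

    mass: float
    tol_ppm: float
    treatment: TreatmentCondition
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("observed mass must be positive")
        if self.tol_ppm <= 0:
            raise ValueError("tolerance must be positive")


_ANNOT_RE = re.compile(r"^\s*cys\s*(\d+)\s*(not\s+)?alkylated\s*$", re.IGNORECASE)


def parse_annotation(text: str) -> tuple[int, bool]:
    """Parse a fragment-level annotation into (ordinal, cam_required)."""
    m = _ANNOT_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse annotation {text!r}; expected "
                         f"'Cys<k> alkylated' or 'Cys<k> not alkylated'")
    return int(m.group(1)), m.group(2) is None


# --- pattern enumeration -----------------------------------------------------

def enumerate_patterns(n_cysteines: int) -> list[Pattern]:
    """All perfect matchings over ordinals 1..n; count is (n-1)!!."""
    if n_cysteines < 2 or n_cysteines % 2:
        raise ValueError("need an even number (>= 2) of cysteines")

    def rec(ordinals: tuple[int, ...]) -> list[frozenset[Bond]]:
        if not ordinals:
            return [frozenset()]
        first, rest = ordinals[0], ordinals[1:]
        out = []
        for k, partner in enumerate(rest):
            remaining = rest[:k] + rest[k + 1:]
            for sub in rec(remaining):
                out.append(sub | {bond(first, partner)})
        return out

    return rec(tuple(range(1, n_cysteines + 1)))


def adjacency_filter(patterns: Iterable[Pattern], framework: CysteineFramework,
                     min_sequence_gap: int = 1) -> list[Pattern]:
    """Drop patterns bonding cysteines that are (near-)adjacent in sequence.

    Adjacent cysteines essentially never form a disulfide with each other; a
    bond is disallowed when the sequence positions differ by at most
    ``min_sequence_gap``.
    """
    def ok(p: Pattern) -> bool:
        return all(abs(framework.position(j) - framework.position(i)) > min_sequence_gap
                   for i, j in p)

    return [p for p in patterns if ok(p)]


# --- species prediction ------------------------------------------------------

def _tilings(n_fragments: int, max_missed: int) -> list[tuple[tuple[int, int], ...]]:
    """All tilings of fragments 0..n-1 into runs of length <= max_missed + 1."""
    @lru_cache(maxsize=None)
    def rec(i: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        if i == n_fragments:
            return ((),)
        out = []
        for j in range(i, min(i + max_missed + 1, n_fragments)):
            for rest in rec(j + 1):
                out.append(((i, j),) + rest)
        return tuple(out)

    return list(rec(0))


class SpeciesPredictor:
    """Predicts digestion species and their masses for candidate patterns.

    Caches the digest and per-peptide base masses so that sweeping 105
    patterns x latent reduced subsets stays cheap.
    """

    def __init__(self, sequence: str, framework: CysteineFramework,
                 parent_id: str = "seq",
                 table: masscalc.ResidueMassTable | None = None):
        masscalc._validate_sequence(sequence)
        self.sequence = sequence
        self.framework = framework
        self.parent_id = parent_id
        self.table = table or masscalc.default_table()
        self._base: dict[tuple[str, int], list[tuple[PeptideSpan, float]]] = {}

    def _fragments(self, enzyme: str) -> list[tuple[PeptideSpan, float]]:
        key = (enzyme, 0)
        if key not in self._base:
            spans = masscalc.digest(self.sequence, enzyme, 0, self.parent_id)
            self._base[key] = [
                (sp, masscalc.peptide_mass(sp.extract(self.sequence), "mono",
                                           table=self.table))
                for sp in spans
            ]
        return self._base[key]

    def predict(self, pattern: Pattern, reduced: Iterable[Bond],
                treatment: TreatmentCondition) -> list[tuple[LinkedSpecies, float]]:
        """Species (with masses) expected under ``pattern`` when the bonds in
        ``reduced`` were cleaved in the partial-reduction step."""
        reduced = frozenset(bond(i, j) for i, j in reduced)
        if not reduced <= pattern:
            raise ValueError("reduced subset must be part of the pattern")
        if 2 * len(pattern) != self.framework.n:
            raise ValueError("pattern is not a perfect matching over the framework")

        pos = self.framework.position
        reduced_cys = {pos(o) for b in reduced for o in b}
        if treatment.dtt:
            intact: frozenset[Bond] = frozenset()
        else:
            intact = pattern - reduced
        intact_pos = frozenset(frozenset((pos(i), pos(j))) for i, j in intact)
        bonded_cys = {pos(o) for b in intact for o in b}

        def status(p: int) -> str:
            if p in bonded_cys:
                return "bonded"
            if treatment.dtt:
                return "cam" if treatment.iaa else "free"
            if p in reduced_cys:
                return "cam" if treatment.iaa else "free"
            return "free"

        frags = self._fragments(treatment.enzyme)
        out: list[tuple[LinkedSpecies, float]] = []
        for tiling in self._frag_tilings(treatment.enzyme, treatment.max_missed):
            out.extend(self._species_for_tiling(frags, tiling, intact_pos, status))
        # dedupe identical species across tilings
        seen = set()
        uniq = []
        for sp, m in out:
            key = (sp.spans, sp.bonds, tuple(sorted(sp.mods.statuses.items())))
            if key not in seen:
                seen.add(key)
                uniq.append((sp, m))
        return uniq

    def _frag_tilings(self, enzyme: str, max_missed: int):
        frags = self._fragments(enzyme)
        if max_missed == 0:
            return [tuple((i, i) for i in range(len(frags)))]
        return _tilings(len(frags), max_missed)

    def _species_for_tiling(self, frags, tiling, intact_pos, status):
        # tiling entries are (first_fragment, last_fragment) runs
        spans = []
        masses = []
        for i, j in tiling:
            first = frags[i][0]
            last = frags[j][0]
            spans.append(PeptideSpan(self.parent_id, first.start, last.end))
            masses.append(sum(frags[k][1] for k in range(i, j + 1))
                          - (j - i) * self.table.water("mono"))
        return self._link(spans, masses, intact_pos, status)

    def _link(self, spans, masses, intact_pos, status):
        n = len(spans)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def span_index(p):
            for i, sp in enumerate(spans):
                if sp.contains(p):
                    return i
            raise ValueError(f"cysteine position {p} not covered by digest")

        for b in intact_pos:
            a, c = tuple(b)
            ia, ic = span_index(a), span_index(c)
            ra, rc = find(ia), find(ic)
            parent[ra] = rc

        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)

        cys_positions = set(self.framework.positions)
        out = []
        for members in groups.values():
            mspans = tuple(spans[i] for i in members)
            contained = [p for p in cys_positions if any(sp.contains(p) for sp in mspans)]
            mods = ModificationState({p: status(p) for p in contained})
            sbonds = frozenset(b for b in intact_pos
                               if all(any(sp.contains(q) for sp in mspans) for q in b))
            species = LinkedSpecies(spans=mspans, bonds=sbonds, mods=mods)
            mass = (sum(masses[i] for i in members)
                    + masscalc.CAM_DELTA["mono"] * mods.n_cam
                    + masscalc.disulfide_correction(mods.n_bonded, "mono",
                                                    self.table.hydrogen))
            out.append((species, mass))
        return out

    def predict_for_treatment(self, pattern: Pattern,
                              treatment: TreatmentCondition
                              ) -> list[tuple[LinkedSpecies, float]]:
        """Union of predicted species over every latent reduced subset of the
        treatment's cardinality (the experiment does not know which bonds were
        cleaved)."""
        if treatment.dtt:
            subsets = [frozenset()]
        else:
            if treatment.n_reduced > len(pattern):
                raise ValueError("cannot reduce more bonds than the pattern has")
            subsets = [frozenset(c) for c in
                       itertools.combinations(sorted(pattern), treatment.n_reduced)]
        out = []
        for sub in subsets:
            out.extend(self.predict(pattern, sub, treatment))
        return out


def predict_species(sequence: str, framework: CysteineFramework, pattern: Pattern,
                    reduced_bond_subset: Iterable[Bond],
                    treatment: TreatmentCondition,
                    max_missed: int = 0) -> list[tuple[LinkedSpecies, float]]:
    """Convenience wrapper around :class:`SpeciesPredictor` for one subset."""
    predictor = SpeciesPredictor(sequence, framework)
    treatment = replace(treatment, max_missed=max_missed)
    return predictor.predict(pattern, reduced_bond_subset, treatment)


# --- observation matching ----------------------------------------------------

def ppm_error(observed: float, theoretical: float) -> float:
    return abs(observed - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class Match:
    observation_index: int
    species: LinkedSpecies
    theoretical_mass: float
    ppm: float
    ambiguous: bool


def match_observations(theoretical: Sequence[tuple[LinkedSpecies, float]],
                       observations: Sequence[MassObservation],
                       tol_ppm: float | None = None) -> list[list[Match]]:
    """Match each observation to theoretical species within ppm tolerance.

    Returns one (possibly empty) list of :class:`Match` per observation; ties
    within tolerance are all retained and flagged ambiguous.
    """
    out: list[list[Match]] = []
    for idx, obs in enumerate(observations):
        tol = tol_ppm if tol_ppm is not None else obs.tol_ppm
        hits = [(sp, m) for sp, m in theoretical if ppm_error(obs.mass, m) <= tol]
        amb = len(hits) > 1
        out.append([Match(idx, sp, m, ppm_error(obs.mass, m), amb) for sp, m in hits])
    return out


def _explains(species: LinkedSpecies, framework: CysteineFramework,
              annotation: str | None) -> bool:
    if annotation is None:
        return True
    ordinal, cam_required = parse_annotation(annotation)
    p = framework.position(ordinal)
    if not species.contains(p):
        return False
    is_cam = species.mods.statuses.get(p) == "cam"
    return is_cam == cam_required


# --- inference ---------------------------------------------------------------

@dataclass
class CandidateEvaluation:
    """Per-pattern diagnostics from the elimination sweep."""

    pattern: Pattern
    explained: list[bool]
    contradictions: int = 0

    @property
    def n_explained(self) -> int:
        return sum(self.explained)

    @property
    def consistent(self) -> bool:
        return self.contradictions == 0


@dataclass
class InferenceResult:
    candidates: list[Pattern]
    evaluations: list[CandidateEvaluation]

    @property
    def unique(self) -> Pattern | None:
        return self.candidates[0] if len(self.candidates) == 1 else None


def infer_patterns(sequence: str, framework: CysteineFramework,
                   observations: Sequence[MassObservation],
                   tol_ppm: float | None = None,
                   use_adjacency_rule: bool = True,
                   min_sequence_gap: int = 1,
                   strict: bool = False,
                   patterns: Sequence[Pattern] | None = None) -> InferenceResult:
    """Eliminate candidate connectivities inconsistent with the observations.

    Default (non-strict) semantics: an observation contradicts a pattern only
    if no species predicted under that pattern explains it while at least one
    other candidate does explain it — contaminant peaks that nothing explains
    eliminate nobody.  ``strict=True`` makes any unexplained observation
    eliminating.  With no observations every candidate survives.
    """
    if patterns is None:
        patterns = enumerate_patterns(framework.n)
    if use_adjacency_rule:
        patterns = adjacency_filter(patterns, framework, min_sequence_gap)
    patterns = list(patterns)

    predictor = SpeciesPredictor(sequence, framework)
    treatments = {obs.treatment for obs in observations}
    # explained[p][o] — does pattern p explain observation o
    species_cache: dict[tuple[Pattern, TreatmentCondition],
                        list[tuple[LinkedSpecies, float]]] = {}

    def explained(pat: Pattern, obs: MassObservation) -> bool:
        key = (pat, obs.treatment)
        if key not in species_cache:
            species_cache[key] = predictor.predict_for_treatment(pat, obs.treatment)
        tol = tol_ppm if tol_ppm is not None else obs.tol_ppm
        for sp, m in species_cache[key]:
            if ppm_error(obs.mass, m) <= tol and _explains(sp, framework, obs.annotation):
                return True
        return False

    table = [[explained(pat, obs) for obs in observations] for pat in patterns]
    explained_by_any = [any(table[p][o] for p in range(len(patterns)))
                        for o in range(len(observations))]

    evaluations = []
    for p, pat in enumerate(patterns):
        contr = 0
        for o in range(len(observations)):
            if not table[p][o] and (strict or explained_by_any[o]):
                contr += 1
        evaluations.append(CandidateEvaluation(pattern=pat, explained=table[p],
                                               contradictions=contr))
    evaluations.sort(key=lambda ev: (-ev.n_explained, sorted(ev.pattern)))
    candidates = [ev.pattern for ev in evaluations if ev.consistent]
    return InferenceResult(candidates=candidates, evaluations=evaluations)
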