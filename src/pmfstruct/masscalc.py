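"""Residue-level mass arithmetic and in-silico proteolysis for disulfide-linked species.

Monoisotopic masses are used for peptide-level matching and average masses for
intact-protein matching.  Disulfide formation removes one hydrogen per bonded
cysteine; iodoacetamide alkylation of a free thiol adds a carboxyamidomethyl
(CAM) group.  Species that remain covalently joined by intact disulfides after
digestion are summed component-wise (each peptide keeps its own water).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from pyteomics import mass as _ptmass
from pyteomics import parser as _ptparser

MassScale = Literal["mono", "avg"]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: carboxyamidomethyl (CAM) addition from iodoacetamide, Da
CAM_DELTA = {"mono": 57.02146, "avg": 57.0513}

#: hydrogen displaced per cysteine on disulfide formation, Da (applied on both
#: scales, matching how intact and fragment masses are corrected in practice)
DISULFIDE_H_PER_CYS = 1.0078

CYS_STATUS = ("bonded", "free", "cam")


def _water(scale: MassScale) -> float:
    return _ptmass.calculate_mass(formula="H2O", average=(scale == "avg"))


@dataclass(frozen=True)
class ResidueMassTable:
    """Per-residue mass constants for the 20 standard amino acids."""

    mono: Mapping[str, float]
    avg: Mapping[str, float]
    water_mono: float
    water_avg: float
    hydrogen: float = DISULFIDE_H_PER_CYS

    def __post_init__(self) -> None:
        for aa in STANDARD_AA:
            if aa not in self.mono or aa not in self.avg:
                raise ValueError(f"mass table missing residue {aa!r}")
            if self.mono[aa] <= 0 or self.avg[aa] <= 0:
                raise ValueError(f"non-positive mass for residue {aa!r}")
            if self.mono[aa] > self.avg[aa]:
                raise ValueError(f"monoisotopic > average for residue {aa!r}")

    def residue(self, aa: str, scale: MassScale) -> float:
        table = self.mono if scale == "mono" else self.avg
        try:
            return table[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None

    def water(self, scale: MassScale) -> float:
        return self.water_mono if scale == "mono" else self.water_avg

    @classmethod
    def standard(cls) -> "ResidueMassTable":
        mono = {aa: _ptmass.calculate_mass(composition=_ptmass.std_aa_comp[aa])
                for aa in STANDARD_AA}
        avg = {aa: _ptmass.calculate_mass(composition=_ptmass.std_aa_comp[aa], average=True)
               for aa in STANDARD_AA}
        return cls(mono=mono, avg=avg,
                   water_mono=_water("mono"), water_avg=_water("avg"))

    @classmethod
    def from_tsv(cls, path) -> "ResidueMassTable":
        """Load an override table from TSV columns: residue, mono, avg."""
        mono, avg = {}, {}
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("residue"):
                raise ValueError("mass table TSV must have a 'residue\\tmono\\tavg' header")
            for line in fh:
                if not line.strip():
                    continue
                aa, m, a = line.split("\t")
                mono[aa.strip()] = float(m)
                avg[aa.strip()] = float(a)
        return cls(mono=mono, avg=avg, water_mono=_water("mono"), water_avg=_water("avg"))


_DEFAULT_TABLE: ResidueMassTable | None = None


def default_table() -> ResidueMassTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = ResidueMassTable.standard()
    return _DEFAULT_TABLE


@dataclass(frozen=True, order=True)
class PeptideSpan:
    """A contiguous stretch of a parent sequence, 1-based inclusive."""

    parent_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def extract(self, parent_sequence: str) -> str:
        if self.end > len(parent_sequence):
            raise ValueError(f"span [{self.start}, {self.end}] exceeds parent length "
                             f"{len(parent_sequence)}")
        return parent_sequence[self.start - 1:self.end]

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class ModificationState:
    """Cysteine statuses keyed by 1-based sequence position.

    Every cysteine of the species must be assigned exactly one status:
    ``bonded`` (engaged in an intact disulfide), ``free`` (reduced thiol) or
    ``cam`` (reduced and alkylated with iodoacetamide).
    """

    statuses: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, st in self.statuses.items():
            if st not in CYS_STATUS:
                raise ValueError(f"unknown cysteine status {st!r} at position {pos}")

    def count(self, status: str) -> int:
        return sum(1 for st in self.statuses.values() if st == status)

    @property
    def n_bonded(self) -> int:
        return self.count("bonded")

    @property
    def n_cam(self) -> int:
        return self.count("cam")

    @property
    def n_free(self) -> int:
        return self.count("free")


def _validate_sequence(sequence: str) -> None:
    m = re.search(f"[^{STANDARD_AA}]", sequence)
    if m:
        raise ValueError(f"unknown residue {m.group()!r} at position {m.start() + 1}")


def disulfide_correction(n_bonded_cysteines: int, scale: MassScale = "mono",
                         per_cysteine: float = DISULFIDE_H_PER_CYS) -> float:
    """Mass delta for the hydrogens displaced by disulfide formation.

    One hydrogen (1.0078 Da) is lost per bonded cysteine; the same printed
    value is applied on both the monoisotopic and average scales.
    """
    if n_bonded_cysteines < 0:
        raise ValueError("bonded-cysteine count must be non-negative")
    if scale not in ("mono", "avg"):
        raise ValueError(f"unknown mass scale {scale!r}")
    return -per_cysteine * n_bonded_cysteines


def peptide_mass(sequence: str, scale: MassScale = "mono",
                 mods: ModificationState | None = None,
                 table: ResidueMassTable | None = None) -> float:
    """Neutral mass of a single peptide chain with cysteine modifications.

    ``mods`` positions are 1-based within ``sequence`` and must point at
    cysteines.  The empty sequence returns the mass of one water.
    """
    table = table or default_table()
    _validate_sequence(sequence)
    total = table.water(scale) + sum(table.residue(aa, scale) for aa in sequence)
    if mods is not None:
        for pos in mods.statuses:
            if pos < 1 or pos > len(sequence) or sequence[pos - 1] != "C":
                raise ValueError(f"modification at position {pos} does not reference "
                                 f"a cysteine of the peptide")
        total += CAM_DELTA[scale] * mods.n_cam
        total += disulfide_correction(mods.n_bonded, scale, table.hydrogen)
    return total


# --- in-silico digestion -----------------------------------------------------

#: cleavage rules as zero-width regexes (pyteomics convention); trypsin and
#: chymotrypsin do not cleave before proline
ENZYME_RULES = {
    "trypsin": r"(?<=[KR])(?!P)",
    "chymotrypsin": r"(?<=[FYWL])(?!P)",
    "aspn": r"\w(?=D)",
}


def digest(sequence: str, enzyme: str, max_missed_cleavages: int = 0,
           parent_id: str = "seq") -> list[PeptideSpan]:
    """Proteolytic fragments of ``sequence`` as spans, 1-based inclusive.

    At zero missed cleavages the spans tile the sequence; with ``k`` missed
    cleavages every union of at most ``k + 1`` adjacent fragments is included.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    _validate_sequence(sequence)
    if max_missed_cleavages < 0:
        raise ValueError("missed-cleavage count must be non-negative")
    key = enzyme.lower().replace("-", "").replace("_", "")
    if key not in ENZYME_RULES:
        raise ValueError(f"unknown enzyme {enzyme!r}; choose from {sorted(ENZYME_RULES)}")
    spans = []
    for start, pep in _ptparser.icleave(sequence, ENZYME_RULES[key],
                                        missed_cleavages=max_missed_cleavages,
                                        min_length=1, regex=True):
        spans.append(PeptideSpan(parent_id, start + 1, start + len(pep)))
    return sorted(spans)


# --- disulfide-linked species ------------------------------------------------

@dataclass(frozen=True)
class LinkedSpecies:
    """Peptides covalently joined by intact disulfide bonds.

    ``bonds`` are unordered pairs of 1-based cysteine positions in the parent
    sequence; ``mods`` covers every cysteine inside the member spans.  The
    span/bond graph must be connected.
    """

    spans: tuple[PeptideSpan, ...]
    bonds: frozenset[frozenset[int]]
    mods: ModificationState

    def __post_init__(self) -> None:
        object.__setattr__(self, "spans", tuple(sorted(self.spans)))
        for bond in self.bonds:
            if len(bond) != 2:
                raise ValueError(f"a disulfide bond joins exactly two cysteines: {set(bond)}")
            for pos in bond:
                if not any(sp.contains(pos) for sp in self.spans):
                    raise ValueError(f"bond cysteine at {pos} lies outside member spans")
        if not _is_connected(self.spans, self.bonds):
            raise ValueError("span/bond graph is not connected")

    def contains(self, position: int) -> bool:
        return any(sp.contains(position) for sp in self.spans)


def _is_connected(spans: Sequence[PeptideSpan], bonds: Iterable[frozenset[int]]) -> bool:
    n = len(spans)
    if n <= 1:
        return True
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def span_of(pos: int) -> int | None:
        for i, sp in enumerate(spans):
            if sp.contains(pos):
                return i
        return None

    for bond in bonds:
        a, b = tuple(bond)
        ia, ib = span_of(a), span_of(b)
        if ia is None or ib is None:
            return False
        parent[find(ia)] = find(ib)
    return len({find(i) for i in range(n)}) == 1


def species_mass(parent_sequence: str, species: LinkedSpecies,
                 scale: MassScale = "mono",
                 table: ResidueMassTable | None = None) -> float:
    """Neutral mass of a disulfide-linked species.

    Component peptide masses (each with its own water) are summed, then CAM
    additions and per-bonded-cysteine hydrogen losses are applied over the
    whole species.
    """
    table = table or default_table()
    total = 0.0
    for span in species.spans:
        total += peptide_mass(span.extract(parent_sequence), scale, table=table)
    for pos in species.mods.statuses:
        if not species.contains(pos):
            raise ValueError(f"modification at {pos} outside species spans")
        if parent_sequence[pos - 1] != "C":
            raise ValueError(f"modification at {pos} does not reference a cysteine")
    total += CAM_DELTA[scale] * species.mods.n_cam
    total += disulfide_correction(species.mods.n_bonded, scale, table.hydrogen)
    return total
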