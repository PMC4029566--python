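"""Alignment variability, cysteine-framework geometry and motif scanning.

Covers the sequence-level analyses for a hypervariable cysteine-rich protein
family: per-column Shannon entropy of a consumed alignment, inter-cysteine
spacing statistics, ProSite-style scanning for the three-finger-protein
cysteine scaffold, residue-class net charge and per-region cross-tabulation
of conservation against site-selection classes.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

ACIDIC = set("DE")
BASIC = set("KR")       # His contribution configurable

SELECTION_CLASSES = ("purifying", "neutral", "positive p<0.05", "positive p<0.01")


@dataclass(frozen=True)
class MSA:
    """A consumed multiple sequence alignment (equal-length gapped rows)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if not self.rows:
            raise ValueError("alignment is empty")
        width = len(self.rows[0])
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise ValueError(f"ragged alignment: row {self.ids[i]!r} has length "
                                 f"{len(row)}, expected {width}")
            bad = re.search(f"[^{AA20}{GAP}]", row)
            if bad:
                raise ValueError(f"row {self.ids[i]!r}: invalid character "
                                 f"{bad.group()!r} at column {bad.start() + 1}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, index: int) -> str:
        if not 0 <= index < self.n_cols:
            raise IndexError(f"column {index} out of range 0..{self.n_cols - 1}")
        return "".join(row[index] for row in self.rows)

    def ungapped(self, row_index: int) -> str:
        return self.rows[row_index].replace(GAP, "")


@dataclass(frozen=True)
class EntropyProfile:
    entropy_bits: tuple[float, ...]       # NaN where all-gap
    gap_fraction: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.entropy_bits)


def column_entropy(msa: MSA, column: int) -> tuple[float, float]:
    """Shannon entropy (bits) and gap fraction of one alignment column.

    Gaps are excluded from the residue frequencies and reported separately;
    an all-gap column has no defined entropy and returns NaN.
    """
    col = msa.column(column)
    gap_fraction = col.count(GAP) / len(col)
    residues = col.replace(GAP, "")
    if not residues:
        return math.nan, gap_fraction
    counts = Counter(residues)
    n = len(residues)
    h = -sum((c / n) * math.log2(c / n) for c in counts.values())
    return h, gap_fraction


def entropy_profile(msa: MSA) -> EntropyProfile:
    pairs = [column_entropy(msa, j) for j in range(msa.n_cols)]
    return EntropyProfile(tuple(h for h, _ in pairs), tuple(g for _, g in pairs))


# --- cysteine framework geometry ---------------------------------------------

@dataclass(frozen=True)
class CysSpacingProfile:
    """Residue counts strictly between consecutive cysteines, in order."""

    gaps: tuple[int, ...]
    n_cysteines: int


def cysteine_spacings(sequence: str) -> CysSpacingProfile:
    if GAP in sequence:
        raise ValueError("cysteine_spacings expects an ungapped sequence")
    positions = [i for i, aa in enumerate(sequence) if aa == "C"]
    gaps = tuple(b - a - 1 for a, b in zip(positions, positions[1:]))
    return CysSpacingProfile(gaps=gaps, n_cysteines=len(positions))


@dataclass(frozen=True)
class SpacingStats:
    mean: float
    sd: float
    conservation_fraction: float     # fraction sharing the modal gap
    n_used: int
    n_excluded: int


def spacing_stats(sequences: Iterable[str], gap_index: int) -> SpacingStats:
    """Mean/SD of the ``gap_index``-th inter-cysteine gap across sequences.

    ``gap_index`` is 1-based: gap 5 is the stretch between the 5th and 6th
    cysteines.  Sequences lacking enough cysteines are excluded and counted.
    """
    if gap_index < 1:
        raise ValueError("gap_index is 1-based")
    values = []
    excluded = 0
    for seq in sequences:
        prof = cysteine_spacings(seq.replace(GAP, ""))
        if len(prof.gaps) < gap_index:
            excluded += 1
        else:
            values.append(prof.gaps[gap_index - 1])
    if not values:
        raise ValueError("no sequence has the requested cysteine pair")
    arr = np.asarray(values, dtype=float)
    modal = Counter(values).most_common(1)[0]
    return SpacingStats(mean=float(arr.mean()),
                        sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                        conservation_fraction=modal[1] / len(values),
                        n_used=len(values), n_excluded=excluded)


# --- ProSite-style motif scanning --------------------------------------------

@dataclass(frozen=True)
class MotifElement:
    """Literal residue or x(min,max) wildcard."""

    residue: str | None          # None => wildcard
    min_len: int = 1
    max_len: int = 1

    def to_string(self) -> str:
        if self.residue is not None:
            return self.residue
        if self.min_len == self.max_len:
            return "x" if self.min_len == 1 else f"x({self.min_len})"
        return f"x({self.min_len},{self.max_len})"


_ELEM_RE = re.compile(r"^(?:(?P<lit>[A-Z])|x(?:\((?P<a>\d+)(?:,(?P<b>\d+))?\))?)$")


@dataclass(frozen=True)
class MotifPattern:
    """Subset of ProSite syntax: dash-separated literals and x wildcards."""

    elements: tuple[MotifElement, ...]

    @classmethod
    def parse(cls, pattern: str) -> "MotifPattern":
        elements = []
        for pos, tok in enumerate(pattern.strip().rstrip(".").split("-")):
            m = _ELEM_RE.match(tok)
            if not m:
                raise ValueError(f"malformed pattern element {tok!r} at index {pos}")
            if m.group("lit"):
                elements.append(MotifElement(m.group("lit")))
            else:
                a = int(m.group("a")) if m.group("a") else 1
                b = int(m.group("b")) if m.group("b") else a
                if b < a:
                    raise ValueError(f"wildcard max < min in element {tok!r} at index {pos}")
                elements.append(MotifElement(None, a, b))
        return cls(tuple(elements))

    def to_string(self) -> str:
        return "-".join(el.to_string() for el in self.elements)

    def to_regex(self) -> str:
        parts = []
        for i, el in enumerate(self.elements):
            if el.residue is not None:
                parts.append(el.residue)
            else:
                parts.append(f"(?P<x{i}>[A-Z]{{{el.min_len},{el.max_len}}})")
        return "".join(parts)


#: cysteine scaffold query for the three-finger protein superfamily
TFP_MOTIF = "C-x(5,30)-C-x(2,10)-C-x(10,30)-C-x(2,20)-C-x(5,30)-C-C-x(4)-C-N"


@dataclass(frozen=True)
class MotifMatch:
    start: int                    # 1-based
    end: int                      # 1-based inclusive
    wildcard_lengths: tuple[int, ...]


def scan_motif(sequence: str, pattern: MotifPattern | str) -> list[MotifMatch]:
    """All non-overlapping matches with realized wildcard lengths.

    The captured x(min,max) lengths for the scaffold query above are exactly
    the inter-cysteine spacings of the matched protein.
    """
    if isinstance(pattern, str):
        pattern = MotifPattern.parse(pattern)
    rx = re.compile(pattern.to_regex())
    out = []
    for m in rx.finditer(sequence):
        lengths = tuple(len(m.group(f"x{i}"))
                        for i, el in enumerate(pattern.elements)
                        if el.residue is None)
        out.append(MotifMatch(m.start() + 1, m.end(), lengths))
    return out


# --- residue-class charge ----------------------------------------------------

def net_charge(sequence: str, his_charge: int = 1) -> int:
    """Residue-class net charge: basic (K, R, and His per convention) minus
    acidic (D, E).  ``his_charge`` is +1 to count His as basic, 0 to ignore."""
    if GAP in sequence:
        raise ValueError("net_charge expects an ungapped sequence")
    basic = sum(1 for aa in sequence if aa in BASIC)
    basic += his_charge * sequence.count("H")
    acidic = sum(1 for aa in sequence if aa in ACIDIC)
    return basic - acidic


# --- selection / conservation cross-tabulation -------------------------------

@dataclass(frozen=True)
class SelectionAnnotation:
    """Per-site evolutionary-mode classes on reference coordinates (1-based)."""

    classes: Mapping[int, str]

    def __post_init__(self) -> None:
        for site, cls in self.classes.items():
            if cls not in SELECTION_CLASSES:
                raise ValueError(f"unknown selection class {cls!r} at site {site}")


def region_selection_summary(profile: EntropyProfile,
                             annotation: SelectionAnnotation | None,
                             region: tuple[int, int],
                             entropy_threshold: float = 0.0) -> pd.DataFrame:
    """Cross-tabulate conservation with selection classes over a region.

    ``region`` is 1-based inclusive on the profile coordinates (e.g. the
    residues strictly between the 5th and 6th cysteines).  A site is
    non-conserved when its entropy exceeds ``entropy_threshold``.
    """
    lo, hi = region
    if not (1 <= lo <= hi <= len(profile)):
        raise ValueError(f"region {region} outside profile of length {len(profile)}")
    records = []
    for site in range(lo, hi + 1):
        h = profile.entropy_bits[site - 1]
        conserved = (not math.isnan(h)) and h <= entropy_threshold
        cls = annotation.classes.get(site, "unannotated") if annotation else "unannotated"
        records.append({"site": site, "conserved": conserved, "selection": cls})
    df = pd.DataFrame(records)
    table = pd.crosstab(df["conserved"], df["selection"])
    table.attrs["n_sites"] = len(df)
    table.attrs["n_nonconserved"] = int((~df["conserved"]).sum())
    pos = df.loc[~df["conserved"], "selection"].str.startswith("positive")
    table.attrs["n_nonconserved_positive"] = int(pos.sum())
    return table
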