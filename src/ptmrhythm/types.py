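"""Shared domain types for time-course PTM proteomics.

All abundances live in :class:`TimeCourseTable`, a feature x (timepoint,
replicate) matrix with zeitgeber-time metadata.  PTM sites, protein-complex
membership, interplay motifs, and kinase motifs each get a small validated
record type; every downstream stage consumes these types rather than raw
files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = frozenset({"labeled", "unlabeled", "proteome", "phospho", "glyco_site"})
REGIMES = frozenset({"NRF", "DRF", "NA"})
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: residues that can accept O-GlcNAc or phosphate
ACCEPTOR_RESIDUES = frozenset({"S", "T"})


class InputError(ValueError):
    """Malformed or contract-violating input data."""


def _fmt_zt(t: float) -> str:
    """ZT hours rendered as integer when integral: 3.0 -> 'ZT3'."""
    if float(t) == int(t):
        return f"ZT{int(t)}"
    return f"ZT{t:g}"


def sample_label(timepoint: float, replicate: int) -> str:
    return f"{_fmt_zt(timepoint)}_r{replicate}"


_SAMPLE_RE = re.compile(r"^ZT(\d+(?:\.\d+)?)_r(\d+)$")


def parse_sample_label(label: str) -> tuple[float, int]:
    m = _SAMPLE_RE.match(label)
    if m is None:
        raise InputError(f"malformed sample column {label!r}; expected ZT<t>_r<k>")
    return float(m.group(1)), int(m.group(2))


@dataclass
class TimeCourseTable:
    """Feature-by-sample abundance matrix on a 24-h ZT clock.

    ``data`` is indexed by feature_id with a (timepoint, replicate)
    MultiIndex on the columns.  Missing values are explicit NaNs and are
    never imputed; negative abundances are rejected.
    """

    data: pd.DataFrame
    condition: str = "labeled"
    regime: str = "NA"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise InputError(f"unknown condition {self.condition!r}")
        if self.regime not in REGIMES:
            raise InputError(f"unknown regime {self.regime!r}")
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise InputError("data columns must be a (timepoint, replicate) MultiIndex")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise InputError(f"duplicate feature_id {dup!r}")
        for t, r in self.data.columns:
            if not (0.0 <= float(t) < 24.0):
                raise InputError(f"timepoint {t} outside [0, 24)")
            if int(r) < 1:
                raise InputError(f"replicate index {r} < 1")
        neg = self.data.lt(0)
        if neg.any().any():
            col = neg.any().idxmax()
            row = neg[col].idxmax()
            raise InputError(
                f"negative abundance at feature {row!r}, sample {sample_label(*col)}"
            )

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def timepoints(self) -> list[float]:
        return sorted({float(t) for t, _ in self.data.columns})

    @property
    def n_replicates(self) -> int:
        return max(int(r) for _, r in self.data.columns)

    @property
    def sample_timepoints(self) -> np.ndarray:
        """Timepoint of every sample column, in column order."""
        return np.asarray([float(t) for t, _ in self.data.columns])

    def values_for(self, feature_id: str) -> np.ndarray:
        return self.data.loc[feature_id].to_numpy(dtype=float)

    def subset(self, feature_ids) -> "TimeCourseTable":
        keep = [f for f in self.data.index if f in set(feature_ids)]
        return TimeCourseTable(self.data.loc[keep], self.condition, self.regime)

    def with_data(self, data: pd.DataFrame) -> "TimeCourseTable":
        return TimeCourseTable(data, self.condition, self.regime)

    def equals(self, other: "TimeCourseTable") -> bool:
        return (
            self.condition == other.condition
            and self.regime == other.regime
            and self.data.equals(other.data)
        )


@dataclass(frozen=True)
class SiteRecord:
    """One PTM site: 1-based residue position on a protein accession."""

    accession: str
    position: int
    residue: str
    ptm: str  # "O-GlcNAc" | "phospho"
    feature_id: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise InputError(f"site position {self.position} must be >= 1 (1-based)")
        if len(self.residue) != 1 or self.residue not in AMINO_ACIDS:
            raise InputError(f"invalid residue {self.residue!r}")
        if self.ptm not in ("O-GlcNAc", "phospho"):
            raise InputError(f"unknown ptm kind {self.ptm!r}")

    def validate_against(self, sequences: dict[str, str]) -> None:
        seq = sequences.get(self.accession)
        if seq is None:
            raise InputError(f"accession {self.accession!r} not in sequence set")
        if self.position > len(seq):
            raise InputError(
                f"{self.accession} position {self.position} beyond sequence "
                f"length {len(seq)}"
            )
        if seq[self.position - 1] != self.residue:
            raise InputError(
                f"{self.accession} position {self.position}: sequence has "
                f"{seq[self.position - 1]!r}, site record says {self.residue!r}"
            )


@dataclass(frozen=True)
class ComplexRecord:
    """One protein complex (CORUM-style membership row)."""

    complex_id: str
    complex_name: str
    members: frozenset[str]
    function_label: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise InputError(f"complex {self.complex_id!r} has no members")


# --- motif pattern language -------------------------------------------------
#
# A pattern is a fixed-length string of tokens: an exact residue ("S"), a
# residue class ("[ST]"), or a wildcard ("."), each optionally followed by a
# fixed repeat ("{3}").  "S.{3}S" matches an S, any three residues, then S.

_TOKEN_RE = re.compile(r"(\[[A-Z]+\]|[A-Z]|\.)(\{(\d+)\})?")


def parse_pattern(pattern: str) -> list[frozenset[str] | None]:
    """Expand a pattern into per-position residue sets (None = wildcard)."""
    positions: list[frozenset[str] | None] = []
    pos = 0
    while pos < len(pattern):
        m = _TOKEN_RE.match(pattern, pos)
        if m is None:
            raise InputError(f"cannot parse motif pattern {pattern!r} at offset {pos}")
        tok = m.group(1)
        repeat = int(m.group(3)) if m.group(3) else 1
        if tok == ".":
            slot = None
        elif tok.startswith("["):
            slot = frozenset(tok[1:-1])
        else:
            slot = frozenset(tok)
        if slot is not None and not slot <= set(AMINO_ACIDS):
            raise InputError(f"non-amino-acid residue in pattern {pattern!r}")
        positions.extend([slot] * repeat)
        pos = m.end()
    if not positions:
        raise InputError("empty motif pattern")
    return positions


@dataclass(frozen=True)
class MotifPattern:
    """A glycosylation-phosphorylation interplay motif.

    ``phospho_offset`` / ``glyco_offset`` are 0-based indices of the two
    acceptor positions within the pattern; they coincide for same-site
    competition motifs.
    """

    pattern: str
    phospho_offset: int
    glyco_offset: int
    mode: str = "proximal"  # "same-site" | "proximal"

    def __post_init__(self) -> None:
        slots = parse_pattern(self.pattern)
        n = len(slots)
        for name, off in (("phospho", self.phospho_offset), ("glyco", self.glyco_offset)):
            if not 0 <= off < n:
                raise InputError(
                    f"{name}_offset {off} outside pattern {self.pattern!r} (length {n})"
                )
            slot = slots[off]
            if slot is not None and not slot & ACCEPTOR_RESIDUES:
                raise InputError(
                    f"{name}_offset {off} of {self.pattern!r} is not S/T-compatible"
                )
        if self.mode not in ("same-site", "proximal"):
            raise InputError(f"unknown motif mode {self.mode!r}")
        if self.mode == "same-site" and self.phospho_offset != self.glyco_offset:
            raise InputError("same-site motif must have equal acceptor offsets")

    @property
    def slots(self) -> list[frozenset[str] | None]:
        return parse_pattern(self.pattern)

    @property
    def length(self) -> int:
        return len(self.slots)

    def matches(self, sequence: str) -> list[int]:
        """All (overlapping) 1-based match start positions in ``sequence``."""
        slots = self.slots
        n = len(slots)
        hits = []
        for start in range(len(sequence) - n + 1):
            window = sequence[start : start + n]
            if all(s is None or window[k] in s for k, s in enumerate(slots)):
                hits.append(start + 1)
        return hits

    def hit_probability(self) -> float:
        """Per-position match probability on a uniform random sequence."""
        p = 1.0
        for slot in self.slots:
            if slot is not None:
                p *= len(slot) / len(AMINO_ACIDS)
        return p


@dataclass(frozen=True)
class KinaseMotifEntry:
    """A kinase recognition motif centered on the phospho-acceptor."""

    kinase: str
    pattern: str
    source_feature: str | None = None

    def __post_init__(self) -> None:
        slots = parse_pattern(self.pattern)
        if len(slots) % 2 == 0:
            raise InputError(
                f"kinase motif {self.pattern!r} must be centered (odd length)"
            )
        center = slots[len(slots) // 2]
        if center is not None and not center & ACCEPTOR_RESIDUES:
            raise InputError(f"kinase motif {self.pattern!r} center is not S/T")

    @property
    def half_window(self) -> int:
        return len(parse_pattern(self.pattern)) // 2

    def matches_flank(self, flank: str) -> bool:
        """Match against a '-'-padded flank centered on the acceptor.

        The motif is aligned at the flank center; wildcards also match the
        '-' padding (unknown context), residue classes do not.
        """
        slots = parse_pattern(self.pattern)
        h = len(slots) // 2
        fc = len(flank) // 2
        if h > fc:
            return False
        window = flank[fc - h : fc + h + 1]
        return all(s is None or window[k] in s for k, s in enumerate(slots))
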