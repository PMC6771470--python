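"""Canonical in-memory model for SWATH/DIA spectral libraries.

A spectral library is a table of peptide precursors, each carrying the
fragment-ion coordinates (m/z, relative intensity) and the chromatographic
retention time used to score DIA/SWATH signal. One *entry* is one precursor
(a stripped sequence, its modified form, and a charge state); one
:class:`FragmentIon` is one transition row of a PeakView/OpenSWATH file.

The entry key is ``(stripped_sequence, modified_sequence, precursor_charge)``.
The protein accession is an attribute of the entry, not part of the key: a
peptide that maps to more than one protein stays a single entry with
``shared=True``, which is what the proteotypic ("unique to individual
proteins") filter acts on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

EntryKey = Tuple[str, str, int]


@dataclass
class FragmentIon:
    """One transition: a fragment ion of a peptide precursor.

    Parameters
    ----------
    mz : float
        Fragment mass-to-charge in Thomson, > 0.
    relative_intensity : float
        Unitless library intensity, >= 0 (only ratios matter downstream).
    series : str
        Ion series, ``"b"`` or ``"y"`` (other series accepted but not
        generated here).
    ordinal : int
        Fragment ordinal within the series; must be strictly less than the
        peptide length.
    charge : int
        Fragment charge state, >= 1.
    """

    mz: float
    relative_intensity: float
    series: str
    ordinal: int
    charge: int

    def validate(self, peptide_length: Optional[int] = None) -> None:
        if not (self.mz > 0):
            raise ValueError(f"fragment mz must be > 0, got {self.mz}")
        if self.relative_intensity < 0:
            raise ValueError("relative_intensity must be >= 0")
        if self.ordinal < 1:
            raise ValueError("fragment ordinal must be >= 1")
        if self.charge < 1:
            raise ValueError("fragment charge must be >= 1")
        if peptide_length is not None and self.ordinal >= peptide_length:
            raise ValueError(
                f"fragment ordinal {self.ordinal} not < peptide length "
                f"{peptide_length}"
            )


@dataclass
class PrecursorEntry:
    """One peptide precursor with its fragment list and provenance.

    ``confidence`` is the search-engine identification confidence mapped to
    [0, 1]; ``is_decoy`` marks reversed-sequence entries used for FDR
    estimation; ``shared`` marks peptides mapping to more than one protein;
    ``sources`` accumulates tissue/batch labels across merges.
    """

    stripped_sequence: str
    modified_sequence: str
    precursor_charge: int
    precursor_mz: float
    rt: float
    protein: str
    confidence: float
    is_decoy: bool = False
    shared: bool = False
    sources: Set[str] = field(default_factory=set)
    fragments: List[FragmentIon] = field(default_factory=list)
    extras: Dict[str, str] = field(default_factory=dict)

    @property
    def key(self) -> EntryKey:
        return (self.stripped_sequence, self.modified_sequence,
                self.precursor_charge)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def validate(self) -> None:
        if not self.fragments:
            raise ValueError(f"entry {self.key} has no fragments")
        if not math.isfinite(self.rt):
            raise ValueError(f"entry {self.key} has non-finite rt")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(
                f"entry {self.key} confidence {self.confidence} not in [0, 1]"
            )
        if self.precursor_charge < 1:
            raise ValueError(f"entry {self.key} has charge < 1")
        n = len(self.stripped_sequence)
        for frag in self.fragments:
            frag.validate(peptide_length=n)

    def copy(self) -> "PrecursorEntry":
        return PrecursorEntry(
            stripped_sequence=self.stripped_sequence,
            modified_sequence=self.modified_sequence,
            precursor_charge=self.precursor_charge,
            precursor_mz=self.precursor_mz,
            rt=self.rt,
            protein=self.protein,
            confidence=self.confidence,
            is_decoy=self.is_decoy,
            shared=self.shared,
            sources=set(self.sources),
            fragments=[FragmentIon(f.mz, f.relative_intensity, f.series,
                                   f.ordinal, f.charge)
                       for f in self.fragments],
            extras=dict(self.extras),
        )


class SpectralLibrary:
    """Ordered, keyed collection of :class:`PrecursorEntry`.

    Entries are kept in insertion order (the row order of the source file);
    keys are unique. ``label`` is a provenance string (tissue or batch);
    ``dialect_meta`` records the source file dialect and column mapping.
    """

    def __init__(self, entries: Iterable[PrecursorEntry] = (),
                 label: str = "", dialect_meta: Optional[dict] = None):
        self.label = label
        self.dialect_meta: dict = dialect_meta or {}
        self._entries: Dict[EntryKey, PrecursorEntry] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: PrecursorEntry) -> None:
        if entry.key in self._entries:
            raise ValueError(f"duplicate entry key {entry.key}")
        self._entries[entry.key] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[PrecursorEntry]:
        return iter(self._entries.values())

    def __contains__(self, key: EntryKey) -> bool:
        return key in self._entries

    def __getitem__(self, key: EntryKey) -> PrecursorEntry:
        return self._entries[key]

    def keys(self) -> Iterable[EntryKey]:
        return self._entries.keys()

    @property
    def entries(self) -> List[PrecursorEntry]:
        return list(self._entries.values())

    def targets(self) -> List[PrecursorEntry]:
        """Entries that are not decoys."""
        return [e for e in self if not e.is_decoy]

    def decoys(self) -> List[PrecursorEntry]:
        return [e for e in self if e.is_decoy]

    @property
    def n_fragments(self) -> int:
        return sum(e.n_fragments for e in self)

    def validate(self) -> None:
        for entry in self:
            entry.validate()

    def copy(self, label: Optional[str] = None) -> "SpectralLibrary":
        return SpectralLibrary(
            (e.copy() for e in self),
            label=self.label if label is None else label,
            dialect_meta=dict(self.dialect_meta),
        )

    def __repr__(self) -> str:
        lbl = f" label={self.label!r}" if self.label else ""
        return (f"<SpectralLibrary{lbl} entries={len(self)} "
                f"fragments={self.n_fragments}>")
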