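"""Library composition summaries, inter-library overlap and cross-library
quantification consistency.

For counting, a *peptide* is a distinct (stripped sequence, modified
sequence) pair — charge states collapse, since published library sizes
describe peptides rather than precursors (``count_precursors=True`` gives
the alternative). Proteins are distinct accession strings, treated as
opaque.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import asdict, dataclass
from typing import Dict, List, Mapping, Tuple

import numpy as np

from .model import SpectralLibrary


@dataclass
class LibraryStats:
    """Composition summary of one library.

    ``peptides_per_protein`` and ``fragments_per_precursor`` are integer
    histograms (value -> count); ``pct_multi_peptide`` is the percentage
    of proteins identified with more than one peptide.
    """

    n_peptides: int
    n_proteins: int
    peptides_per_protein: Dict[int, int]
    fragments_per_precursor: Dict[int, int]
    pct_multi_peptide: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["peptides_per_protein"] = {str(k): v for k, v in
                                     sorted(self.peptides_per_protein.items())}
        d["fragments_per_precursor"] = {
            str(k): v for k, v in sorted(self.fragments_per_precursor.items())}
        return d


@dataclass
class SharingRow:
    """Per-tissue contribution: how many of its peptides are unique to it,
    shared with one other tissue, or found in three or more."""

    label: str
    n_peptides_total: int
    n_unique_to_label: int
    n_in_two: int
    n_in_three_plus: int


def library_stats(lib: SpectralLibrary,
                  count_precursors: bool = False) -> LibraryStats:
    """Peptide/protein counts and composition histograms (targets only)."""
    targets = lib.targets()
    if count_precursors:
        peptides = {e.key for e in targets}
        pep_of = lambda e: e.key  # noqa: E731
    else:
        peptides = {(e.stripped_sequence, e.modified_sequence)
                    for e in targets}
        pep_of = lambda e: (e.stripped_sequence, e.modified_sequence)  # noqa

    proteins: Dict[str, set] = defaultdict(set)
    for e in targets:
        proteins[e.protein].add(pep_of(e))

    pep_hist = Counter(len(peps) for peps in proteins.values())
    frag_hist = Counter(e.n_fragments for e in targets)

    n_proteins = len(proteins)
    if n_proteins == 0:
        warnings.warn("empty library: percentage of multi-peptide proteins "
                      "is undefined, reporting 0")
        pct_multi = 0.0
    else:
        n_multi = sum(1 for peps in proteins.values() if len(peps) >= 2)
        pct_multi = 100.0 * n_multi / n_proteins

    return LibraryStats(
        n_peptides=len(peptides),
        n_proteins=n_proteins,
        peptides_per_protein=dict(pep_hist),
        fragments_per_precursor=dict(frag_hist),
        pct_multi_peptide=pct_multi,
    )


def sharing_table(lib: SpectralLibrary) -> List[SharingRow]:
    """Tissue-sharing breakdown of a consensus library.

    For each provenance label, partitions its peptides by how many
    tissues contain them: exactly 1 (unique), exactly 2, or 3+.
    Requires every entry to carry at least one source label.
    """
    per_pep_sources: Dict[Tuple[str, str], set] = defaultdict(set)
    for e in lib.targets():
        if not e.sources:
            raise ValueError(f"entry {e.key} has no source labels")
        per_pep_sources[(e.stripped_sequence, e.modified_sequence)] |= \
            e.sources

    labels = sorted({lbl for srcs in per_pep_sources.values()
                     for lbl in srcs})
    rows = []
    for label in labels:
        total = unique = in_two = in_three = 0
        for srcs in per_pep_sources.values():
            if label not in srcs:
                continue
            total += 1
            if len(srcs) == 1:
                unique += 1
            elif len(srcs) == 2:
                in_two += 1
            else:
                in_three += 1
        rows.append(SharingRow(label, total, unique, in_two, in_three))
    return rows


def library_overlap(a: SpectralLibrary, b: SpectralLibrary
                    ) -> Tuple[float, float]:
    """Percentage of ``b``'s peptides / proteins also present in ``a``.

    The denominator is the SECOND argument — by convention the external
    or tissue-specific library being compared against the (larger)
    consensus. Peptides compared as (stripped, modified) pairs, proteins
    as accession strings; targets only.
    """
    if len(b.targets()) == 0:
        raise ValueError("second library has no target entries")
    peps_a = {(e.stripped_sequence, e.modified_sequence) for e in a.targets()}
    peps_b = {(e.stripped_sequence, e.modified_sequence) for e in b.targets()}
    prot_a = {e.protein for e in a.targets()}
    prot_b = {e.protein for e in b.targets()}
    pep_pct = 100.0 * len(peps_a & peps_b) / len(peps_b)
    prot_pct = 100.0 * len(prot_a & prot_b) / len(prot_b)
    return pep_pct, prot_pct


def quant_consistency(qa: Mapping[str, float], qb: Mapping[str, float]
                      ) -> Tuple[float, int]:
    """Quantification agreement between two peptide-intensity tables.

    Returns the squared Pearson correlation of log10 intensities over
    peptides present in both tables with positive intensity in both, and
    the number of such peptides. Invariant to global multiplicative
    scaling of either table. Requires >= 3 usable shared peptides.
    """
    shared = [p for p in qa if p in qb]
    usable = [(qa[p], qb[p]) for p in shared if qa[p] > 0 and qb[p] > 0]
    if len(usable) < 3:
        raise ValueError(
            f"need >= 3 shared peptides with positive intensities, "
            f"have {len(usable)}")
    la = np.log10([u[0] for u in usable])
    lb = np.log10([u[1] for u in usable])
    if np.ptp(la) == 0 or np.ptp(lb) == 0:
        raise ValueError("degenerate intensities: zero variance on log scale")
    r = float(np.corrcoef(la, lb)[0, 1])
    return r * r, len(usable)
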