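"""Library cleaning: the filters applied to every search-result library
before it may take part in a merge.

A cleaned library contains only target (non-decoy) precursors that are

* unmodified — the modified sequence equals the stripped sequence once
  fixed-modification tags (carbamidomethyl-C by default, since cysteine
  alkylation is part of standard sample preparation) and terminal markers
  are removed;
* identified at FDR < 1% — either via an explicit per-file confidence
  cutoff, or a cutoff derived from the library's own target/decoy
  confidence distribution;
* supported by at least five fragment ions;
* proteotypic — mapping to a single protein accession.

Filters are applied in a fixed order (decoys, modified, confidence,
fragment count, shared) so that report attribution is deterministic;
entry survival itself is order-independent.
"""

from __future__ import annotations

import re
from dataclasses import asdict, dataclass
from typing import Optional, Tuple, Union

from .model import SpectralLibrary

#: Matches bracketed/parenthesised modification tags, e.g. ``[CAM]``.
_TAG_RE = re.compile(r"\[([^\]]*)\]|\(([^)]*)\)")
#: Terminal markers some exports prepend/append (n/c-term underscores etc.).
_TERMINAL_RE = re.compile(r"^_+|_+$|^n(?=[A-Z])|c$")


@dataclass
class CleanConfig:
    """Parameters of :func:`clean_library`.

    ``confidence_cutoff="derive"`` estimates the cutoff matching
    ``fdr_threshold`` from the library's decoys; a float supplies the
    upstream per-file cutoff directly.
    """

    fdr_threshold: float = 0.01
    confidence_cutoff: Union[float, str] = "derive"
    min_fragments: int = 5
    require_unmodified: bool = True
    require_proteotypic: bool = True
    fixed_modification_tags: Tuple[str, ...] = ("CAM",)

    def __post_init__(self):
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.min_fragments < 1:
            raise ValueError("min_fragments must be >= 1")


@dataclass
class CleanReport:
    """Per-filter accounting for one cleaning pass.

    ``output_entries = input_entries - (removed_decoys + removed_modified +
    removed_low_confidence + removed_few_fragments + removed_shared)``;
    each entry is counted once, at the first filter that removes it.
    """

    input_entries: int = 0
    removed_decoys: int = 0
    removed_modified: int = 0
    removed_low_confidence: int = 0
    removed_few_fragments: int = 0
    removed_shared: int = 0
    output_entries: int = 0
    cutoff_used: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def is_unmodified(modified_sequence: str, stripped_sequence: str,
                  fixed_tags: Tuple[str, ...] = ("CAM",)) -> bool:
    """True if the entry carries no variable modification.

    Tags whose text is in ``fixed_tags`` (carbamidomethyl by default) are
    removed before comparison, as are dialect terminal markers, so
    alkylated cysteines do not count as modified.
    """
    def _keep(match: re.Match) -> str:
        tag = match.group(1) if match.group(1) is not None else match.group(2)
        return "" if tag in fixed_tags else match.group(0)

    reduced = _TAG_RE.sub(_keep, modified_sequence)
    reduced = _TERMINAL_RE.sub("", reduced)
    return reduced == stripped_sequence


def derive_confidence_cutoff(lib: SpectralLibrary,
                             fdr_threshold: float = 0.01) -> float:
    """Smallest confidence ``c`` with estimated FDR <= ``fdr_threshold``.

    The FDR at ``c`` is estimated as (#decoys with confidence >= c) /
    (#targets with confidence >= c), the plain target-decoy ratio without
    pi0 correction. Candidates are the observed confidence values; if no
    candidate satisfies the threshold, a cutoff just above the maximum
    observed confidence is returned (the filter then removes everything).
    """
    targets = sorted(e.confidence for e in lib.targets())
    decoys = sorted(e.confidence for e in lib.decoys())
    if not targets:
        raise ValueError("cannot derive cutoff: library has no target entries")
    if not decoys:
        raise ValueError(
            "cannot derive cutoff without decoys; supply explicit cutoff")

    import bisect
    candidates = sorted(set(targets) | set(decoys))
    for c in candidates:
        n_targets = len(targets) - bisect.bisect_left(targets, c)
        n_decoys = len(decoys) - bisect.bisect_left(decoys, c)
        if n_targets == 0:
            continue
        if n_decoys / n_targets <= fdr_threshold:
            return c
    return max(candidates) + 1e-9


def clean_library(lib: SpectralLibrary, cfg: Optional[CleanConfig] = None
                  ) -> Tuple[SpectralLibrary, CleanReport]:
    """Apply the cleaning filters; returns the cleaned library and report.

    The output library contains copies of the surviving entries; the
    input is not modified. Decoys never survive.
    """
    cfg = cfg or CleanConfig()
    if cfg.confidence_cutoff == "derive":
        cutoff = derive_confidence_cutoff(lib, cfg.fdr_threshold)
    else:
        cutoff = float(cfg.confidence_cutoff)

    report = CleanReport(input_entries=len(lib), cutoff_used=cutoff)
    kept = []
    for entry in lib:
        if entry.is_decoy:
            report.removed_decoys += 1
        elif cfg.require_unmodified and not is_unmodified(
                entry.modified_sequence, entry.stripped_sequence,
                cfg.fixed_modification_tags):
            report.removed_modified += 1
        elif entry.confidence < cutoff:
            report.removed_low_confidence += 1
        elif entry.n_fragments < cfg.min_fragments:
            report.removed_few_fragments += 1
        elif cfg.require_proteotypic and entry.shared:
            report.removed_shared += 1
        else:
            kept.append(entry.copy())
    report.output_entries = len(kept)
    out = SpectralLibrary(kept, label=lib.label,
                          dialect_meta=dict(lib.dialect_meta))
    return out, report
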