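"""Sequential merging of cleaned, RT-aligned spectral libraries.

The consensus library grows one add-on at a time: the first (cleaned)
library seeds the base and defines the consensus RT coordinate system;
each subsequent library is cleaned, RT-aligned against the current base,
checked against the linearity gate, transformed into base RT space, and
unioned in. An add-on whose alignment fails the gate is skipped with its
verdict recorded — a rejection, not an error.

Duplicate peptides (same entry key in base and add-on) are resolved by
policy: ``keep_base`` (default — first-seen wins, mirroring the
base/add-on asymmetry of sequential workflows) or ``best_confidence``.
Either way the retained entry's ``sources`` becomes the union of both
entries' provenance labels, which is what the tissue-sharing statistics
are computed from. A retained base entry's RT is never modified by later
merges.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import List, Optional, Sequence, Tuple, Union

from .clean import CleanConfig, CleanReport, clean_library
from .model import SpectralLibrary
from .rt_align import (DEFAULT_GATE, PiecewiseRTAligner, RTAlignmentModel,
                       alignment_gate, pair_shared_peptides, transform_rt)

_POLICIES = ("keep_base", "best_confidence")


@dataclass
class MergePolicy:
    """How duplicate entry keys are resolved and which gate applies."""

    conflict: str = "keep_base"
    gate: float = DEFAULT_GATE

    def __post_init__(self):
        if self.conflict not in _POLICIES:
            raise ValueError(
                f"conflict must be one of {_POLICIES}, got {self.conflict!r}")


@dataclass
class MergeReport:
    """Accounting for one merge step."""

    base_entries: int
    addon_entries: int
    overlapping: int = 0
    added: int = 0
    dropped_by_alignment: int = 0
    gate_r_squared: float = float("nan")
    verdict: str = "merged"
    addon_label: str = ""
    message: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def merge_pair(base: SpectralLibrary, addon: SpectralLibrary,
               policy: Optional[MergePolicy] = None,
               model: Optional[RTAlignmentModel] = None,
               extrapolate: str = "drop"
               ) -> Tuple[SpectralLibrary, MergeReport]:
    """Merge one aligned add-on library into the base.

    ``model`` is the RT alignment from add-on to base space; it must have
    passed :func:`~swathlib.rt_align.alignment_gate`, otherwise the
    verdict is ``rejected`` and the base is returned unchanged. With
    ``model=None`` the add-on is taken as already in base RT space
    (identity alignment, gate trivially satisfied).
    """
    policy = policy or MergePolicy()
    report = MergeReport(base_entries=len(base), addon_entries=len(addon),
                         addon_label=addon.label)

    if model is not None:
        verdict, message = alignment_gate(model, policy.gate)
        report.gate_r_squared = model.global_r_squared
        if verdict == "fail":
            report.verdict = "rejected"
            report.message = message
            return base, report
        aligned, dropped = transform_rt(addon, model, extrapolate=extrapolate)
        report.dropped_by_alignment = dropped
    else:
        aligned = addon
        report.gate_r_squared = 1.0

    merged = base.copy()
    for entry in aligned:
        if entry.key in merged:
            report.overlapping += 1
            kept = merged[entry.key]
            if (policy.conflict == "best_confidence"
                    and entry.confidence > kept.confidence):
                new = entry.copy()
                new.sources |= kept.sources
                merged._entries[entry.key] = new
            else:
                kept.sources |= entry.sources
        else:
            merged.add(entry.copy())
            report.added += 1
    report.verdict = "merged"
    return merged, report


def build_consensus(
    plan: Sequence[Tuple[Union[str, SpectralLibrary], str]],
    clean_cfg: Optional[CleanConfig] = None,
    policy: Optional[MergePolicy] = None,
    aligner: Optional[PiecewiseRTAligner] = None,
    min_pairs: Optional[int] = None,
    extrapolate: str = "drop",
) -> Tuple[SpectralLibrary, List[MergeReport], List[CleanReport]]:
    """Sequentially assemble a consensus library from an ordered plan.

    ``plan`` lists (library or TSV path, label) in merge order. Each
    library is cleaned; the first seeds the base, every later one is
    aligned (piecewise fit + gate), transformed and merged. Add-ons that
    cannot be aligned — too few shared peptides, no segment passing the
    gate, or global R^2 at or below the gate — are skipped with verdict
    ``rejected``.

    Returns (consensus, merge reports, clean reports).
    """
    if not plan:
        raise ValueError("merge plan is empty")
    policy = policy or MergePolicy()
    aligner = aligner or PiecewiseRTAligner(segment_r2_gate=policy.gate)
    if min_pairs is None:
        min_pairs = aligner.min_segment_pairs

    merge_reports: List[MergeReport] = []
    clean_reports: List[CleanReport] = []

    def load(item, label) -> SpectralLibrary:
        if isinstance(item, SpectralLibrary):
            lib = item.copy(label=label)
        else:
            from .io import read_library
            lib = read_library(item, label=label)
        for entry in lib:
            entry.sources.add(label)
        return lib

    first_item, first_label = plan[0]
    base, rep = clean_library(load(first_item, first_label), clean_cfg)
    clean_reports.append(rep)

    for item, label in plan[1:]:
        addon, rep = clean_library(load(item, label), clean_cfg)
        clean_reports.append(rep)
        try:
            pairs = pair_shared_peptides(base, addon, min_pairs=min_pairs)
            model = aligner.fit(pairs)
        except ValueError as exc:
            merge_reports.append(MergeReport(
                base_entries=len(base), addon_entries=len(addon),
                verdict="rejected", addon_label=label, message=str(exc)))
            continue
        base, report = merge_pair(base, addon, policy=policy, model=model,
                                  extrapolate=extrapolate)
        merge_reports.append(report)

    base.label = "consensus"
    return base, merge_reports, clean_reports
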