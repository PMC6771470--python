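"""Retention-time alignment between a base and an add-on spectral library.

Before two libraries can be merged, the add-on library's chromatographic
retention times must be mapped into the base library's time coordinate.
The map is estimated from peptides present in both libraries. When the RT
correlation is linear a single ordinary-least-squares fit suffices; when
the gradient differs in shape, the correlation is piecewise-linear and the
add-on RT axis is divided into linear fragments, each aligned separately
and reassembled. Portions of the add-on library whose local fit does not
reach the linearity gate (R^2, strictly greater than 0.90 by default) are
not alignable and are discarded rather than force-fitted.

Division into linear fragments is automated as recursive binary
splitting: a segment that fails the R^2 gate and holds at least
``2 * min_segment_pairs`` points is split at the breakpoint minimising
the total residual sum of squares of the two sub-fits (ties broken to
the earliest breakpoint); recursion stops when the gate is met, the
segment is too small, or ``max_segments`` is reached. Terminal segments
still failing the gate are moved to the discarded ranges.

The fitted map is an :class:`RTAlignmentModel` results object carrying
per-segment fits with standard errors, the discarded ranges, and the
global R^2 on the retained, transformed pairs; ``summary()`` renders a
text table and :func:`plot_alignment` draws the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats as _stats

from .model import EntryKey, SpectralLibrary

DEFAULT_GATE = 0.90
DEFAULT_MIN_PAIRS = 20


@dataclass
class RTPairs:
    """Shared-peptide retention-time pairs (add-on RT, base RT, key)."""

    pairs: List[Tuple[float, float, EntryKey]]

    @property
    def n(self) -> int:
        return len(self.pairs)

    def arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        addon = np.array([p[0] for p in self.pairs], dtype=float)
        base = np.array([p[1] for p in self.pairs], dtype=float)
        return addon, base


@dataclass
class LinearFit:
    """OLS fit of base RT on add-on RT over one segment."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    slope_se: float = float("nan")
    intercept_se: float = float("nan")

    def predict(self, addon_rt: float) -> float:
        return self.slope * addon_rt + self.intercept


@dataclass
class Segment:
    """One retained linear fragment: half-open add-on RT range and fit."""

    lo: float
    hi: float
    fit: LinearFit
    closed_top: bool = False

    def contains(self, rt: float) -> bool:
        if self.closed_top:
            return self.lo <= rt <= self.hi
        return self.lo <= rt < self.hi


@dataclass
class RTAlignmentModel:
    """Piecewise-linear map from add-on RT space to base RT space.

    ``segments`` are the retained linear fragments (sorted, disjoint
    half-open intervals; the last retained interval is closed at the
    top); ``discarded_ranges`` are add-on RT intervals where no linear
    fit reached the gate; ``global_r_squared`` is computed on the
    retained pairs after per-segment transformation.
    """

    segments: List[Segment]
    discarded_ranges: List[Tuple[float, float]]
    global_r_squared: float
    n_used: int
    n_discarded: int
    segment_gate: float = DEFAULT_GATE

    def segment_for(self, addon_rt: float) -> Optional[Segment]:
        for seg in self.segments:
            if seg.contains(addon_rt):
                return seg
        return None

    def in_discarded(self, addon_rt: float) -> bool:
        for lo, hi in self.discarded_ranges:
            if lo <= addon_rt < hi or (hi == self._span_hi and addon_rt == hi):
                return True
        return False

    @property
    def _span_hi(self) -> float:
        tops = [s.hi for s in self.segments] + [h for _, h in
                                                self.discarded_ranges]
        return max(tops) if tops else float("nan")

    def summary(self) -> str:
        lines = [
            "Piecewise-linear RT alignment",
            f"  pairs used: {self.n_used}   discarded: {self.n_discarded}",
            f"  global R^2 (retained): {self.global_r_squared:.4f}",
            f"  {'segment':>8} {'range (min)':>18} {'slope':>8} "
            f"{'intercept':>10} {'R^2':>7} {'n':>6}",
        ]
        for i, seg in enumerate(self.segments, 1):
            lines.append(
                f"  {i:>8} {seg.lo:>8.2f}-{seg.hi:<9.2f} "
                f"{seg.fit.slope:>8.4f} {seg.fit.intercept:>10.4f} "
                f"{seg.fit.r_squared:>7.4f} {seg.fit.n:>6}")
        for lo, hi in self.discarded_ranges:
            lines.append(f"  discarded {lo:>7.2f}-{hi:<9.2f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "segments": [
                {"lo": s.lo, "hi": s.hi, "closed_top": s.closed_top,
                 "slope": s.fit.slope, "intercept": s.fit.intercept,
                 "r_squared": s.fit.r_squared, "n": s.fit.n}
                for s in self.segments
            ],
            "discarded_ranges": [list(r) for r in self.discarded_ranges],
            "global_r_squared": self.global_r_squared,
            "n_used": self.n_used,
            "n_discarded": self.n_discarded,
            "segment_gate": self.segment_gate,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RTAlignmentModel":
        segments = [
            Segment(d["lo"], d["hi"],
                    LinearFit(d["slope"], d["intercept"], d["r_squared"],
                              d["n"]),
                    closed_top=d.get("closed_top", False))
            for d in data["segments"]
        ]
        return cls(segments=segments,
                   discarded_ranges=[tuple(r) for r in
                                     data["discarded_ranges"]],
                   global_r_squared=data["global_r_squared"],
                   n_used=data["n_used"], n_discarded=data["n_discarded"],
                   segment_gate=data.get("segment_gate", DEFAULT_GATE))


def pair_shared_peptides(base: SpectralLibrary, addon: SpectralLibrary,
                         min_pairs: int = DEFAULT_MIN_PAIRS) -> RTPairs:
    """RT pairs for entry keys present in both libraries.

    Raises if the intersection is smaller than ``min_pairs`` — too few
    anchors to estimate an alignment.
    """
    shared = [k for k in addon.keys() if k in base]
    if len(shared) < min_pairs:
        raise ValueError(
            f"insufficient shared peptides for alignment: "
            f"{len(shared)} < {min_pairs}")
    return RTPairs([(addon[k].rt, base[k].rt, k) for k in shared])


def fit_linear(pairs: RTPairs) -> LinearFit:
    """OLS regression of base RT on add-on RT over all pairs."""
    if pairs.n < 2:
        raise ValueError("need at least 2 pairs for a linear fit")
    x, y = pairs.arrays()
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: all add-on RTs identical")
    order = np.argsort(x, kind="stable")  # fixed summation order
    res = _stats.linregress(x[order], y[order])
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue) ** 2, n=pairs.n,
                     slope_se=float(res.stderr),
                     intercept_se=float(res.intercept_stderr))


# ---------------------------------------------------------------------------
# Piecewise fitting via recursive binary splitting

def _prefix_sums(x: np.ndarray, y: np.ndarray):
    z = np.zeros(1)
    return (np.concatenate([z, np.cumsum(x)]),
            np.concatenate([z, np.cumsum(y)]),
            np.concatenate([z, np.cumsum(x * x)]),
            np.concatenate([z, np.cumsum(y * y)]),
            np.concatenate([z, np.cumsum(x * y)]))


def _range_rss(sums, i: np.ndarray, j: np.ndarray):
    """Vectorised OLS residual sum of squares on index ranges [i, j)."""
    sx, sy, sxx, syy, sxy = sums
    n = (j - i).astype(float)
    dx = sx[j] - sx[i]
    dy = sy[j] - sy[i]
    dxx = sxx[j] - sxx[i]
    dyy = syy[j] - syy[i]
    dxy = sxy[j] - sxy[i]
    var_x = dxx - dx * dx / n
    sst = dyy - dy * dy / n
    cov = dxy - dx * dy / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = np.where(var_x > 0, sst - cov * cov / np.where(var_x > 0,
                                                             var_x, 1.0),
                       sst)
    return np.maximum(rss, 0.0), np.maximum(sst, 0.0)


def _segment_r2(sums, i: int, j: int) -> float:
    rss, sst = _range_rss(sums, np.array([i]), np.array([j]))
    if sst[0] <= 0:
        return 1.0  # constant response: nothing left to explain
    return float(1.0 - rss[0] / sst[0])


def _best_split(sums, i: int, j: int, min_pairs: int) -> Optional[int]:
    """Breakpoint k in (i, j) minimising RSS[i,k) + RSS[k,j)."""
    ks = np.arange(i + min_pairs, j - min_pairs + 1)
    if ks.size == 0:
        return None
    left_rss, _ = _range_rss(sums, np.full_like(ks, i), ks)
    right_rss, _ = _range_rss(sums, ks, np.full_like(ks, j))
    total = left_rss + right_rss
    return int(ks[int(np.argmin(total))])  # argmin ties -> earliest


@dataclass
class PiecewiseRTAligner:
    """Segmented-regression aligner for add-on → base RT maps.

    Parameters
    ----------
    max_segments : int
        Ceiling on the number of terminal segments (retained plus
        discarded); with 1 the aligner reduces to a single OLS fit.
    min_segment_pairs : int
        Minimum shared-peptide pairs per segment; a segment is only
        split while both halves can keep this many.
    segment_r2_gate : float
        A terminal segment is retained iff its local R^2 >= this gate.
    """

    max_segments: int = 6
    min_segment_pairs: int = DEFAULT_MIN_PAIRS
    segment_r2_gate: float = DEFAULT_GATE

    def fit(self, pairs: RTPairs) -> RTAlignmentModel:
        return fit_piecewise(pairs, max_segments=self.max_segments,
                             min_segment_pairs=self.min_segment_pairs,
                             segment_r2_gate=self.segment_r2_gate)


def fit_piecewise(pairs: RTPairs, max_segments: int = 6,
                  min_segment_pairs: int = DEFAULT_MIN_PAIRS,
                  segment_r2_gate: float = DEFAULT_GATE) -> RTAlignmentModel:
    """Fit a quality-gated piecewise-linear RT map.

    Pairs sorted by add-on RT are recursively partitioned into at most
    ``max_segments`` contiguous segments (see module docstring for the
    splitting rule). Terminal segments failing the gate become discarded
    ranges. Raises ``ValueError("library not alignable")`` when every
    segment is discarded.
    """
    if pairs.n < min_segment_pairs:
        raise ValueError(
            f"insufficient pairs for piecewise fit: {pairs.n} < "
            f"{min_segment_pairs}")
    x, y = pairs.arrays()
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: all add-on RTs identical")
    sums = _prefix_sums(x, y)
    n = len(x)

    # Depth-first recursive binary splitting under a shared segment budget.
    leaves: List[Tuple[int, int]] = []
    budget = [1]  # current number of terminal segments

    def split(i: int, j: int) -> None:
        r2 = _segment_r2(sums, i, j)
        if r2 >= segment_r2_gate:
            leaves.append((i, j))
            return
        can_split = (j - i >= 2 * min_segment_pairs
                     and budget[0] < max_segments)
        if not can_split:
            leaves.append((i, j))
            return
        k = _best_split(sums, i, j, min_segment_pairs)
        if k is None:
            leaves.append((i, j))
            return
        budget[0] += 1
        split(i, k)
        split(k, j)

    split(0, n)
    leaves.sort()

    # Index ranges -> contiguous add-on RT intervals covering the span.
    boundaries = [float(x[0])]
    for (_, j) in leaves[:-1]:
        boundaries.append(float((x[j - 1] + x[j]) / 2.0))
    boundaries.append(float(x[-1]))

    segments: List[Segment] = []
    discarded: List[Tuple[float, float]] = []
    n_used = 0
    n_discarded = 0
    retained_leaves = []
    for idx, (i, j) in enumerate(leaves):
        lo, hi = boundaries[idx], boundaries[idx + 1]
        r2 = _segment_r2(sums, i, j)
        if r2 >= segment_r2_gate and np.ptp(x[i:j]) > 0:
            fit = fit_linear(RTPairs(
                [(float(x[t]), float(y[t]), None) for t in range(i, j)]))
            segments.append(Segment(lo, hi, fit))
            retained_leaves.append((i, j, fit))
            n_used += j - i
        else:
            discarded.append((lo, hi))
            n_discarded += j - i
    if not segments:
        raise ValueError("library not alignable")
    segments[-1].closed_top = True  # last retained interval closed at top

    # Global R^2 on retained pairs after per-segment transformation.
    preds = []
    obs = []
    for i, j, fit in retained_leaves:
        preds.append(fit.slope * x[i:j] + fit.intercept)
        obs.append(y[i:j])
    pred = np.concatenate(preds)
    ob = np.concatenate(obs)
    sst = float(np.sum((ob - ob.mean()) ** 2))
    ssr = float(np.sum((ob - pred) ** 2))
    global_r2 = 1.0 if sst == 0 else 1.0 - ssr / sst

    return RTAlignmentModel(segments=segments, discarded_ranges=discarded,
                            global_r_squared=global_r2, n_used=n_used,
                            n_discarded=n_discarded,
                            segment_gate=segment_r2_gate)


def transform_rt(addon: SpectralLibrary, model: RTAlignmentModel,
                 extrapolate: str = "drop"
                 ) -> Tuple[SpectralLibrary, int]:
    """Map an add-on library's RTs into base space; returns (library,
    dropped count).

    Entries whose RT falls in a retained segment are transformed by that
    segment's fit; entries in discarded ranges are removed. Entries
    outside all ranges (beyond the shared-peptide span) are dropped by
    default; ``extrapolate="nearest"`` extends the nearest retained
    segment instead.
    """
    if extrapolate not in ("drop", "nearest"):
        raise ValueError(f"unknown extrapolation mode {extrapolate!r}")
    kept = []
    dropped = 0
    for entry in addon:
        seg = model.segment_for(entry.rt)
        if seg is None:
            if model.in_discarded(entry.rt) or extrapolate == "drop":
                dropped += 1
                continue
            seg = _nearest_segment(model, entry.rt)
            if seg is None:
                dropped += 1
                continue
        new = entry.copy()
        new.rt = seg.fit.predict(entry.rt)
        kept.append(new)
    out = SpectralLibrary(kept, label=addon.label,
                          dialect_meta=dict(addon.dialect_meta))
    return out, dropped


def _nearest_segment(model: RTAlignmentModel, rt: float) -> Optional[Segment]:
    best, best_dist = None, float("inf")
    for seg in model.segments:
        dist = max(seg.lo - rt, rt - seg.hi, 0.0)
        if dist < best_dist:
            best, best_dist = seg, dist
    return best


def alignment_gate(model: RTAlignmentModel, gate: float = DEFAULT_GATE
                   ) -> Tuple[str, str]:
    """Linearity gate on the assembled alignment: pass iff global
    R^2 strictly exceeds ``gate``."""
    r2 = model.global_r_squared
    if r2 > gate:
        return "pass", f"global R^2 {r2:.4f} > {gate:.2f}"
    return "fail", f"global R^2 {r2:.4f} <= {gate:.2f}"


def plot_alignment(pairs: RTPairs, model: Optional[RTAlignmentModel] = None,
                   ax=None):
    """Scatter of base vs add-on RT with the fitted piecewise map."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    x, y = pairs.arrays()
    ax.plot(x, y, ".", ms=2, alpha=0.5, color="0.3")
    if model is not None:
        for seg in model.segments:
            xs = np.linspace(seg.lo, seg.hi, 20)
            ax.plot(xs, seg.fit.slope * xs + seg.fit.intercept, "-",
                    color="tab:red", lw=1.5)
        for lo, hi in model.discarded_ranges:
            ax.axvspan(lo, hi, color="tab:orange", alpha=0.2)
    ax.set_xlabel("add-on RT (min)")
    ax.set_ylabel("base RT (min)")
    return ax
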