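"""Shared-peptide pairing, OLS and piecewise RT fitting, segmentation
oracle checks, transformation and the linearity gate."""

import numpy as np
import pytest

from swathlib import (LinearFit, RTAlignmentModel, RTPairs,
                      Segment, SimConfig, alignment_gate, distort_library,
                      fit_linear, fit_piecewise, pair_shared_peptides,
                      simulate_library, transform_rt)
from swathlib.rt_align import _best_split, _prefix_sums
from swathlib.simulate import nonlinear_distortion_spec

from conftest import make_entry, make_library


def pairs_of(xy):
    return RTPairs([(x, y, None) for x, y in xy])


# -- pairing ---------------------------------------------------------------

def test_pairing_is_key_intersection():
    base = make_library([make_entry(seq=s, rt=r) for s, r in
                         [("AAK", 1.0), ("BBK", 2.0), ("CCK", 3.0)]])
    addon = make_library([make_entry(seq=s, rt=r) for s, r in
                          [("BBK", 2.5), ("CCK", 3.5), ("DDK", 4.0)]])
    pairs = pair_shared_peptides(base, addon, min_pairs=2)
    assert pairs.n == 2
    assert sorted(pairs.pairs) == [(2.5, 2.0, ("BBK", "BBK", 2)),
                                   (3.5, 3.0, ("CCK", "CCK", 2))]


def test_pairing_insufficient_overlap_errors():
    base = make_library([make_entry(seq="AAK")])
    addon = make_library([make_entry(seq="BBK")])
    with pytest.raises(ValueError, match="insufficient shared peptides"):
        pair_shared_peptides(base, addon)


def test_pairing_identical_libraries_on_diagonal(sim_lib):
    pairs = pair_shared_peptides(sim_lib, sim_lib)
    assert pairs.n == len(sim_lib)
    x, y = pairs.arrays()
    assert np.array_equal(x, y)


# -- linear fit ------------------------------------------------------------

def test_fit_linear_identity_line():
    fit = fit_linear(pairs_of([(1, 1), (2, 2), (3, 3)]))
    assert fit.slope == pytest.approx(1.0)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)


def test_fit_linear_two_points_exact():
    fit = fit_linear(pairs_of([(0, 5), (10, 25)]))
    assert fit.slope == pytest.approx(2.0)
    assert fit.intercept == pytest.approx(5.0)
    assert fit.r_squared == pytest.approx(1.0)


def test_fit_linear_recovers_noisy_parameters():
    rng = np.random.default_rng(7)
    x = rng.uniform(0, 60, 200)
    y = 1.5 * x + 3 + rng.normal(0, 0.3, 200)
    fit = fit_linear(pairs_of(zip(x, y)))
    # closed-form OLS oracle on the same sample
    vx = x - x.mean()
    slope = float(vx @ (y - y.mean()) / (vx @ vx))
    intercept = float(y.mean() - slope * x.mean())
    assert fit.slope == pytest.approx(slope)
    assert fit.intercept == pytest.approx(intercept)
    assert abs(fit.slope - 1.5) < 3 * fit.slope_se
    assert abs(fit.intercept - 3.0) < 3 * fit.intercept_se


def test_fit_linear_degenerate_regressor():
    with pytest.raises(ValueError, match="degenerate regressor"):
        fit_linear(pairs_of([(1, 1), (1, 2), (1, 3)]))


# -- piecewise fit ---------------------------------------------------------

def test_piecewise_linear_input_yields_single_segment():
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 60, 300)
    y = 1.1 * x + 2 + rng.normal(0, 0.05, 300)
    p = pairs_of(zip(x, y))
    model = fit_piecewise(p)
    assert len(model.segments) == 1
    assert model.discarded_ranges == []
    ref = fit_linear(p)
    seg = model.segments[0]
    assert seg.fit.slope == pytest.approx(ref.slope)
    assert seg.fit.intercept == pytest.approx(ref.intercept)
    assert model.global_r_squared == pytest.approx(ref.r_squared)
    assert (seg.lo, seg.hi) == (x.min(), x.max())


@pytest.mark.parametrize("seed", range(5))
def test_best_split_matches_exhaustive_search(seed):
    """The RSS-minimising breakpoint equals a brute-force scan."""
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(0, 10, 120))
    bp = rng.uniform(3, 7)
    y = np.where(x < bp, 2 * x, 0.5 * x + 20) + rng.normal(0, 0.2, 120)
    sums = _prefix_sums(x, y)

    def rss(i, j):
        xi, yi = x[i:j], y[i:j]
        vx = xi - xi.mean()
        if vx @ vx == 0:
            return float(((yi - yi.mean()) ** 2).sum())
        slope = vx @ (yi - yi.mean()) / (vx @ vx)
        resid = yi - yi.mean() - slope * vx
        return float(resid @ resid)

    min_pairs = 10
    candidates = range(min_pairs, 120 - min_pairs + 1)
    brute = min(candidates, key=lambda k: (round(rss(0, k) + rss(k, 120), 9),
                                           k))
    assert _best_split(sums, 0, 120, min_pairs) == brute


def test_piecewise_recovers_three_pieces_and_discards_noise_block():
    lib, _ = simulate_library(SimConfig(n_proteins=300, seed=21))
    spec = nonlinear_distortion_spec()
    addon, truth = distort_library(lib, spec, seed=22)
    pairs = pair_shared_peptides(lib, addon)
    model = fit_piecewise(pairs)
    assert len(model.segments) == 3
    for ts in truth.segments:
        fs = max(model.segments,
                 key=lambda s: min(ts.hi, s.hi) - max(ts.lo, s.lo))
        assert abs(fs.fit.slope - ts.fit.slope) < 3 * fs.fit.slope_se
        assert abs(fs.fit.intercept - ts.fit.intercept) < \
            3 * fs.fit.intercept_se
    w_lo, w_hi = truth.discarded_ranges[0]
    covered = sum(max(0.0, min(hi, w_hi) - max(lo, w_lo))
                  for lo, hi in model.discarded_ranges)
    assert covered > 0.8 * (w_hi - w_lo)


def test_max_segments_one_reduces_to_linear_fit():
    rng = np.random.default_rng(9)
    x = rng.uniform(0, 60, 200)
    y = 0.9 * x + 1 + rng.normal(0, 0.05, 200)
    p = pairs_of(zip(x, y))
    model = fit_piecewise(p, max_segments=1)
    ref = fit_linear(p)
    assert len(model.segments) == 1
    assert model.segments[0].fit.slope == ref.slope
    assert model.segments[0].fit.intercept == ref.intercept


def test_max_segments_one_unalignable_when_gate_fails():
    # noise-free two-piece input whose single fit is far from linear
    x = np.linspace(0, 10, 100)
    y = np.where(x < 5, 30 - 5 * x, 2 * x)
    with pytest.raises(ValueError, match="library not alignable"):
        fit_piecewise(pairs_of(zip(x, y)), max_segments=1)


def test_partition_covers_span_and_assigns_each_pair_once():
    lib, _ = simulate_library(SimConfig(n_proteins=200, seed=31))
    addon, _ = distort_library(lib, nonlinear_distortion_spec(), seed=32)
    pairs = pair_shared_peptides(lib, addon)
    model = fit_piecewise(pairs)
    x, _ = pairs.arrays()
    intervals = sorted([(s.lo, s.hi) for s in model.segments] +
                       list(model.discarded_ranges))
    assert intervals[0][0] == pytest.approx(x.min())
    assert intervals[-1][1] == pytest.approx(x.max())
    for (_, hi), (lo, _) in zip(intervals, intervals[1:]):
        assert hi == pytest.approx(lo)  # contiguous, non-overlapping
    for rt in x:
        in_seg = sum(s.contains(rt) for s in model.segments)
        in_disc = model.in_discarded(rt)
        assert in_seg + in_disc == 1
    assert model.n_used + model.n_discarded == pairs.n


# -- transform -------------------------------------------------------------

def identity_model(lo=0.0, hi=100.0):
    return RTAlignmentModel(
        segments=[Segment(lo, hi, LinearFit(1.0, 0.0, 1.0, 2),
                          closed_top=True)],
        discarded_ranges=[], global_r_squared=1.0, n_used=2, n_discarded=0)


def test_transform_identity_keeps_rts_and_drops_out_of_range():
    lib = make_library([make_entry(seq="AAK", rt=5.0),
                        make_entry(seq="BBK", rt=50.0),
                        make_entry(seq="CCK", rt=150.0)])
    out, dropped = transform_rt(lib, identity_model(0, 100))
    assert dropped == 1
    assert [e.rt for e in out] == [5.0, 50.0]


def test_transform_drops_discarded_range_entries():
    model = RTAlignmentModel(
        segments=[Segment(0.0, 10.0, LinearFit(2.0, 1.0, 1.0, 2),
                          closed_top=True)],
        discarded_ranges=[(10.0, 20.0)],
        global_r_squared=1.0, n_used=2, n_discarded=0)
    lib = make_library([make_entry(seq="AAK", rt=4.0),
                        make_entry(seq="BBK", rt=15.0)])
    out, dropped = transform_rt(lib, model)
    assert dropped == 1
    assert [e.rt for e in out] == [9.0]  # 2 * 4 + 1


def test_transform_nearest_extrapolation_keeps_out_of_range():
    lib = make_library([make_entry(seq="AAK", rt=150.0)])
    out, dropped = transform_rt(lib, identity_model(0, 100),
                                extrapolate="nearest")
    assert dropped == 0
    assert out.entries[0].rt == 150.0


def test_transform_recovers_base_rts_within_noise():
    noise_sd = 0.05
    lib, _ = simulate_library(SimConfig(n_proteins=300, seed=41))
    addon, _ = distort_library(lib, nonlinear_distortion_spec(noise_sd),
                               seed=43)
    pairs = pair_shared_peptides(lib, addon)
    model = fit_piecewise(pairs)
    out, dropped = transform_rt(addon, model)
    hits = sum(abs(e.rt - lib[e.key].rt) <= 4 * noise_sd for e in out)
    assert hits / len(out) >= 0.95


def test_transform_monotone_within_segment():
    model = RTAlignmentModel(
        segments=[Segment(0.0, 50.0, LinearFit(1.3, -2.0, 1.0, 2),
                          closed_top=True)],
        discarded_ranges=[], global_r_squared=1.0, n_used=2, n_discarded=0)
    lib = make_library([make_entry(seq=f"PEP{i}K", rt=float(i))
                        for i in range(1, 50, 3)])
    out, _ = transform_rt(lib, model)
    rts = [e.rt for e in out]
    assert rts == sorted(rts)


# -- gate ------------------------------------------------------------------

@pytest.mark.parametrize("r2,expected", [
    (0.97, "pass"),
    (0.90, "fail"),  # strict inequality at the gate
    (0.50, "fail"),
])
def test_alignment_gate_semantics(r2, expected):
    model = identity_model()
    model.global_r_squared = r2
    verdict, _ = alignment_gate(model, gate=0.90)
    assert verdict == expected
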