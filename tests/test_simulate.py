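"""Mass arithmetic against an independent oracle, generator determinism,
composition fractions and RT distortion ground truth."""

import re

import pytest
from scipy import stats as sps

from swathlib import (DistortionSpec, SimConfig, clean_library,
                      distort_library, fragment_mz, peptide_mz,
                      simulate_library, write_library)

# Independent oracle: hand-typed monoisotopic residue masses (Da).
AA = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.010565
PROTON = 1.0072765
MODS = {"CAM": 57.021464, "Oxi": 15.994915}


def oracle_peptide_mz(seq, charge, deltas=()):
    return (sum(AA[a] for a in seq) + sum(deltas) + WATER
            + charge * PROTON) / charge


def oracle_fragment_mz(seq, series, ordinal, charge, deltas=None):
    deltas = deltas or {}
    if series == "b":
        part = seq[:ordinal]
        extra = sum(d for p, d in deltas.items() if p < ordinal)
        neutral = sum(AA[a] for a in part) + extra
    else:
        part = seq[len(seq) - ordinal:]
        extra = sum(d for p, d in deltas.items()
                    if p >= len(seq) - ordinal)
        neutral = sum(AA[a] for a in part) + extra + WATER
    return (neutral + charge * PROTON) / charge


def test_peptide_mz_reference_values():
    assert peptide_mz("PEPTIDE", 2) == pytest.approx(400.6872, abs=0.001)
    assert peptide_mz("G", 1) == pytest.approx(76.0393, abs=0.001)
    assert peptide_mz("PEPTIDE", 2) == \
        pytest.approx(oracle_peptide_mz("PEPTIDE", 2), abs=0.001)


def test_peptide_mz_charge_state_identity():
    for seq in ("ALSPEVK", "PEPTIDER", "MCWYK"):
        mz1 = peptide_mz(seq, 1)
        mz2 = peptide_mz(seq, 2)
        assert mz2 == pytest.approx((mz1 + PROTON) / 2, abs=1e-4)


def test_fragment_mz_against_oracle():
    assert fragment_mz("AG", "y", 1, 1) == \
        pytest.approx(oracle_fragment_mz("AG", "y", 1, 1), abs=0.001)
    assert fragment_mz("AG", "y", 1, 1) == \
        pytest.approx(peptide_mz("G", 1), abs=0.001)
    for seq in ("ALSPEVK", "TESTPEPTIDEK"):
        for series in "by":
            for ordinal in range(1, len(seq)):
                assert fragment_mz(seq, series, ordinal, 1) == \
                    pytest.approx(
                        oracle_fragment_mz(seq, series, ordinal, 1),
                        abs=0.001)


def test_fragment_complementarity_and_charge_identity():
    seq = "ALSPEVTIDK"
    n = len(seq)
    mh = peptide_mz(seq, 1)
    for k in range(1, n):
        b = fragment_mz(seq, "b", k, 1)
        y = fragment_mz(seq, "y", n - k, 1)
        # neutral(b_k) + neutral(y_{n-k}) = neutral peptide
        assert (b - PROTON) + (y - PROTON) == pytest.approx(mh - PROTON,
                                                            abs=1e-6)
    f1 = fragment_mz(seq, "y", 4, 1)
    f2 = fragment_mz(seq, "y", 4, 2)
    assert f2 == pytest.approx((f1 + PROTON) / 2, abs=1e-4)


def test_fragment_ordinal_and_residue_errors():
    with pytest.raises(ValueError, match="ordinal"):
        fragment_mz("ALSK", "y", 4, 1)
    with pytest.raises(ValueError, match="unknown residue"):
        peptide_mz("ALXZK", 2)


def test_simulation_is_deterministic_from_seed(tmp_path):
    cfg = SimConfig(n_proteins=100, seed=7)
    lib1, _ = simulate_library(cfg)
    lib2, _ = simulate_library(SimConfig(n_proteins=100, seed=7))
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_library(lib1, p1, "peakview")
    write_library(lib2, p2, "peakview")
    assert p1.read_bytes() == p2.read_bytes()
    lib3, _ = simulate_library(SimConfig(n_proteins=100, seed=8))
    p3 = tmp_path / "c.tsv"
    write_library(lib3, p3, "peakview")
    assert p1.read_bytes() != p3.read_bytes()


def test_decoy_fraction_within_binomial_bounds():
    cfg = SimConfig(n_proteins=600, fraction_decoy=0.5, seed=13)
    lib, _ = simulate_library(cfg)
    n = len(lib)
    k = len(lib.decoys())
    lo, hi = sps.binom.interval(0.99, n, 0.5)
    assert lo <= k <= hi


def test_truth_record_predicts_cleaning_survivors_exactly(sim_pair):
    lib, truth = sim_pair
    cleaned, report = clean_library(lib)
    predicted = truth.predicted_survivors(report.cutoff_used)
    assert set(cleaned.keys()) == predicted


def _parse_mod_deltas(modified_sequence):
    """Recover 0-based residue positions of modification tags."""
    deltas = {}
    pos = -1
    for token in re.findall(r"\[([A-Za-z]+)\]|([A-Z])", modified_sequence):
        tag, residue = token
        if residue:
            pos += 1
        else:
            deltas[pos] = deltas.get(pos, 0.0) + MODS[tag]
    return deltas


def test_simulated_mz_reverifies_by_independent_summation(sim_lib):
    """Every Q1/Q3 in a simulated library re-derives within 0.001 Th."""
    worst = 0.0
    for e in sim_lib.entries[:300]:
        deltas = _parse_mod_deltas(e.modified_sequence)
        q1 = oracle_peptide_mz(e.stripped_sequence, e.precursor_charge,
                               deltas.values())
        worst = max(worst, abs(q1 - e.precursor_mz))
        for f in e.fragments:
            q3 = oracle_fragment_mz(e.stripped_sequence, f.series,
                                    f.ordinal, f.charge, deltas)
            worst = max(worst, abs(q3 - f.mz))
    assert worst < 0.001


def test_distort_identity_and_affine():
    lib, _ = simulate_library(SimConfig(n_proteins=30, seed=3))
    same, model = distort_library(lib, DistortionSpec(), seed=1)
    assert [e.rt for e in same] == [e.rt for e in lib]
    assert len(model.segments) == 1
    doubled, model = distort_library(
        lib, DistortionSpec(slopes=(2.0,), intercepts=(3.0,)), seed=1)
    for a, b in zip(lib, doubled):
        assert b.rt == pytest.approx(2 * a.rt + 3, abs=1e-12)
    # ground-truth inverse map
    seg = model.segments[0]
    assert seg.fit.slope == pytest.approx(0.5)
    assert seg.fit.intercept == pytest.approx(-1.5)


def test_distortion_spec_validation():
    with pytest.raises(ValueError, match="slopes"):
        DistortionSpec(breakpoints=(5.0,), slopes=(1.0,),
                       intercepts=(0.0,))
    with pytest.raises(ValueError, match="sorted"):
        DistortionSpec(breakpoints=(5.0, 2.0), slopes=(1.0, 1.0, 1.0),
                       intercepts=(0.0, 0.0, 0.0))
    with pytest.raises(ValueError):
        SimConfig(sharing_probs=(0.5, 0.5, 0.5))


def test_generated_fractions_roughly_match_config(sim_pair):
    lib, truth = sim_pair
    cfg = truth.config
    n = len(lib)
    frac_mod = sum(t.is_modified for t in truth.entries.values()) / n
    assert abs(frac_mod - cfg.fraction_modified) < 0.05
    # every entry has >= fragments_min fragments and a valid tissue count
    for t in truth.entries.values():
        assert t.n_fragments >= min(cfg.fragments_min,
                                    len(t.key[0]) * 2 - 2)
        assert 1 <= len(t.tissues) <= len(cfg.tissue_labels)
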