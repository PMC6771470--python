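"""Monoisotopic peptide and b/y fragment m/z calculation.

Residue masses and physical constants come from :mod:`pyteomics.mass`. The
simulator uses these to emit physically consistent Q1/Q3 columns; variable
modifications are handled as per-residue mass offsets.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from pyteomics import mass as _pmass

PROTON = _pmass.nist_mass["H+"][0][0]  # 1.00727646677
WATER = _pmass.calculate_mass(formula="H2O")  # 18.0105646837

#: Monoisotopic residue masses for the 20 standard amino acids.
RESIDUE_MASSES = {aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}

#: Mass deltas of the modification tags the simulator writes.
MOD_MASSES = {
    "CAM": 57.021464,   # carbamidomethyl (fixed, iodoacetamide alkylation)
    "Oxi": 15.994915,   # oxidation (variable)
}


def _residue_mass_array(sequence: str,
                        mod_deltas: Optional[Mapping[int, float]] = None
                        ) -> Sequence[float]:
    try:
        masses = [RESIDUE_MASSES[aa] for aa in sequence]
    except KeyError as exc:
        raise ValueError(
            f"unknown residue {exc.args[0]!r} in sequence {sequence!r}"
        ) from None
    if mod_deltas:
        for pos, delta in mod_deltas.items():
            if not 0 <= pos < len(masses):
                raise ValueError(f"modification position {pos} out of range")
            masses[pos] += delta
    return masses


def peptide_mz(sequence: str, charge: int,
               mod_deltas: Optional[Mapping[int, float]] = None) -> float:
    """Monoisotopic precursor m/z of ``sequence`` at ``charge``.

    ``mod_deltas`` maps 0-based residue positions to modification mass
    deltas (Da). m/z = (sum of residue masses + water + charge protons)
    / charge.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    masses = _residue_mass_array(sequence, mod_deltas)
    return (sum(masses) + WATER + charge * PROTON) / charge


def fragment_mz(sequence: str, series: str, ordinal: int, charge: int,
                mod_deltas: Optional[Mapping[int, float]] = None) -> float:
    """Monoisotopic m/z of the b- or y-ion ``series``/``ordinal``.

    b_k covers the first k residues (neutral mass = sum of residues);
    y_k covers the last k residues (neutral mass = sum + water). Requires
    1 <= ordinal < len(sequence).
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    n = len(sequence)
    if not 1 <= ordinal < n:
        raise ValueError(
            f"fragment ordinal {ordinal} out of range for length-{n} peptide"
        )
    masses = _residue_mass_array(sequence, mod_deltas)
    if series == "b":
        neutral = sum(masses[:ordinal])
    elif series == "y":
        neutral = sum(masses[n - ordinal:]) + WATER
    else:
        raise ValueError(f"unsupported ion series {series!r}")
    return (neutral + charge * PROTON) / charge
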