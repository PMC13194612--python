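"""Protein physicochemical property calculators.

Native implementations of the five ProtParam-style descriptors used for
druggable-target triage: average molecular weight, theoretical isoelectric
point, GRAVY (grand average of hydropathicity), the Guruprasad instability
index, and Ikai's aliphatic index.  All calculators operate on sequences
over the 20 canonical amino-acid letters; non-canonical letters are rejected
by default (``ignore_unknown=True`` drops them instead).

Conventions follow ProtParam: average (not monoisotopic) isotopic masses,
Kyte–Doolittle hydropathy, and the Bjellqvist pKa set for charge/pI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.SeqUtils import ProtParamData  # published Guruprasad DIWV table

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL)

#: Average residue masses in Da (monomer minus water), ProtParam convention.
RESIDUE_MASS_AVG = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS_AVG = 18.01524

#: Kyte–Doolittle hydropathy values.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: Bjellqvist pKa set as used by ProtParam.  Positive groups gain charge
#: below their pKa, negative groups lose it.
PKA_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}

#: Relative side-chain volume weights for the aliphatic index (Ikai 1980).
_ALIPHATIC_WEIGHTS = {"A": 1.0, "V": 2.9, "I": 3.9, "L": 3.9}


class SequenceError(ValueError):
    """Raised for empty sequences or non-canonical residues."""


def _clean(sequence: str, ignore_unknown: bool = False) -> str:
    seq = sequence.upper()
    if not seq:
        raise SequenceError("empty sequence")
    bad = [c for c in seq if c not in _CANONICAL_SET]
    if bad:
        if not ignore_unknown:
            raise SequenceError(f"non-canonical residue(s): {sorted(set(bad))}")
        seq = "".join(c for c in seq if c in _CANONICAL_SET)
        if not seq:
            raise SequenceError("no canonical residues left after filtering")
    return seq


def molecular_weight(sequence: str, ignore_unknown: bool = False) -> float:
    """Average molecular weight in Da: sum of residue masses plus one water."""
    seq = _clean(sequence, ignore_unknown)
    return sum(RESIDUE_MASS_AVG[c] for c in seq) + WATER_MASS_AVG


def gravy(sequence: str, ignore_unknown: bool = False) -> float:
    """Grand average of hydropathicity (mean Kyte–Doolittle value)."""
    seq = _clean(sequence, ignore_unknown)
    return sum(KYTE_DOOLITTLE[c] for c in seq) / len(seq)


def instability_index(sequence: str, ignore_unknown: bool = False) -> float:
    """Guruprasad instability index: II = (10/L) * sum of DIWV over pairs.

    The dipeptide weight matrix DIWV is order-dependent, so the index is not
    permutation-invariant.  Values < 40 conventionally indicate a stable
    protein.  Requires length >= 2.
    """
    seq = _clean(sequence, ignore_unknown)
    if len(seq) < 2:
        raise SequenceError("instability index requires length >= 2")
    total = sum(ProtParamData.DIWV[a][b] for a, b in zip(seq, seq[1:]))
    return 10.0 / len(seq) * total


def aliphatic_index(sequence: str, ignore_unknown: bool = False) -> float:
    """Ikai aliphatic index: X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu).

    X are mole percentages; higher values indicate larger relative volume of
    aliphatic side chains (a thermostability proxy).  Maximum is 390
    (poly-Ile/Leu).
    """
    seq = _clean(sequence, ignore_unknown)
    n = len(seq)
    return sum(100.0 * _ALIPHATIC_WEIGHTS.get(c, 0.0) for c in seq) / n


def net_charge(sequence: str, ph: float, ignore_unknown: bool = False) -> float:
    """Henderson–Hasselbalch net charge at a given pH (termini + ionizable
    side chains, Bjellqvist pKa set).  Monotone decreasing in pH."""
    seq = _clean(sequence, ignore_unknown)
    counts = {c: seq.count(c) for c in "KRHDECY"}
    pos = sum(
        n / (1.0 + 10.0 ** (ph - PKA_POSITIVE[aa]))
        for aa, n in ((a, counts[a]) for a in "KRH")
    )
    pos += 1.0 / (1.0 + 10.0 ** (ph - PKA_POSITIVE["Nterm"]))
    neg = sum(
        n / (1.0 + 10.0 ** (PKA_NEGATIVE[aa] - ph))
        for aa, n in ((a, counts[a]) for a in "DECY")
    )
    neg += 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE["Cterm"] - ph))
    return pos - neg


def isoelectric_point(
    sequence: str,
    ignore_unknown: bool = False,
    charge_tol: float = 1e-4,
    ph_tol: float = 1e-4,
) -> float:
    """Theoretical pI: the pH at which the net charge crosses zero.

    Found by bisection on [0, 14]; the charge function is strictly monotone
    in pH, so the root is unique.  Stops when |charge| < charge_tol or the
    bracketing interval is narrower than ph_tol.
    """
    seq = _clean(sequence, ignore_unknown)
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid)
        if abs(q) < charge_tol or (hi - lo) < ph_tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class PropertyProfile:
    """The five scored physicochemical descriptors of one protein."""

    mw: float
    pi: float
    gravy: float
    instability_index: float
    aliphatic_index: float

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        if not 0.0 < self.pi < 14.0:
            raise ValueError("pi must lie in (0, 14)")
        if self.aliphatic_index < 0:
            raise ValueError("aliphatic_index must be >= 0")


def property_profile(sequence: str, ignore_unknown: bool = False) -> PropertyProfile:
    """Compute all five descriptors for one sequence."""
    return PropertyProfile(
        mw=molecular_weight(sequence, ignore_unknown),
        pi=isoelectric_point(sequence, ignore_unknown),
        gravy=gravy(sequence, ignore_unknown),
        instability_index=instability_index(sequence, ignore_unknown),
        aliphatic_index=aliphatic_index(sequence, ignore_unknown),
    )
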