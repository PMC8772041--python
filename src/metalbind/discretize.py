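"""Categorical class schemes for residues and predicted structural values.

Every feature in this package is built on a small set of fixed partitions:
four relative-solvent-accessibility (RSA) intervals, two phi and three psi
dihedral intervals, three charge classes and six hydropathy classes of the
twenty standard amino acids.  The interval boundaries are hard-coded
literature values, not refit from data.  Each mapper is total on its declared
domain: every legal input falls in exactly one class.

The pad/unknown symbol ``X`` (used both for pseudo-residues appended at chain
ends and for non-standard residues) is a first-class 21st alphabet symbol.
Structure tracks carry an analogous ``PAD`` class.  Charge and hydropathy map
``X`` to ``PAD``, which downstream entropy features exclude.
"""

from __future__ import annotations

AA20 = "ACDEFGHIKLMNPQRSTVWY"
PAD_RESIDUE = "X"
#: Closed 21-symbol residue alphabet: 20 standard amino acids + pad/unknown.
ALPHABET = AA20 + PAD_RESIDUE

PAD = "PAD"
SS_CLASSES = ("H", "E", "C", PAD)
RSA_CLASSES = ("I", "II", "III", "IV", PAD)
PHI_CLASSES = ("I", "II", PAD)
PSI_CLASSES = ("I", "II", "III", PAD)

CHARGE_CLASSES = ("positive", "negative", "neutral")
HYDROPATHY_CLASSES = ("strong_philic", "strong_phobic", "weak_philic", "P", "G", "C")

_CHARGE = {}
for _aa in AA20:
    _CHARGE[_aa] = "neutral"
for _aa in "KRH":
    _CHARGE[_aa] = "positive"
for _aa in "DE":
    _CHARGE[_aa] = "negative"
_CHARGE[PAD_RESIDUE] = PAD

_HYDROPATHY = {}
for _aa in "RDENQKH":
    _HYDROPATHY[_aa] = "strong_philic"
for _aa in "LIVAMF":
    _HYDROPATHY[_aa] = "strong_phobic"
for _aa in "STYW":
    _HYDROPATHY[_aa] = "weak_philic"
_HYDROPATHY["P"] = "P"
_HYDROPATHY["G"] = "G"
_HYDROPATHY["C"] = "C"
_HYDROPATHY[PAD_RESIDUE] = PAD


def classify_rsa(x: float) -> str:
    """Map relative solvent accessibility in [0, 1] to one of four intervals.

    The printed intervals are (0, 0.2], (0.2, 0.45], (0.45, 0.6], (0.6, 0.85];
    the boundary mass they miss is clamped (x = 0 -> I, x > 0.85 -> IV) so the
    mapper stays total on [0, 1].
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"RSA value {x!r} outside [0, 1]")
    if x <= 0.2:
        return "I"
    if x <= 0.45:
        return "II"
    if x <= 0.6:
        return "III"
    return "IV"


def classify_phi(x: float) -> str:
    """Map a phi dihedral in degrees to class I ([-180, -75]) or II ((-75, 180])."""
    if not -180.0 <= x <= 180.0:
        raise ValueError(f"phi angle {x!r} outside [-180, 180]")
    return "I" if x <= -75.0 else "II"


def classify_psi(x: float) -> str:
    """Map a psi dihedral in degrees to I ([-180, 15]), II ((15, 135]) or III ((135, 180])."""
    if not -180.0 <= x <= 180.0:
        raise ValueError(f"psi angle {x!r} outside [-180, 180]")
    if x <= 15.0:
        return "I"
    if x <= 135.0:
        return "II"
    return "III"


def charge_class(aa: str) -> str:
    """Charge class of a residue token: K/R/H positive, D/E negative, rest neutral, X -> PAD."""
    try:
        return _CHARGE[aa]
    except KeyError:
        raise ValueError(f"unknown residue token {aa!r}") from None


def hydropathy_class(aa: str) -> str:
    """Hydropathy class of a residue token.

    R/D/E/N/Q/K/H strongly hydrophilic, L/I/V/A/M/F strongly hydrophobic,
    S/T/Y/W weakly hydrophilic; P, G and C are singleton classes; X -> PAD.
    """
    try:
        return _HYDROPATHY[aa]
    except KeyError:
        raise ValueError(f"unknown residue token {aa!r}") from None
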