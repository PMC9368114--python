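"""Frozen physical constants and controlled vocabularies.

Atomic monoisotopic masses are pinned (IUPAC/CODATA values truncated to the
precision used throughout) rather than looked up at runtime, so that every
m/z printed by this package is bit-reproducible across installations.
"""

from __future__ import annotations

#: Monoisotopic atomic masses in Da. Carbon is exactly 12 by definition.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.0030740,
    "O": 15.99491462,
    "S": 31.97207117,
    "P": 30.97376200,
}

#: Proton mass in Da used for (de)protonation; the electron mass is already
#: folded in, so [M+H]+ = M + PROTON_MASS and [M-H]- = M - PROTON_MASS.
PROTON_MASS = 1.007276

#: Mass added by ammonium adduction, NH4+ (includes the charge correction).
AMMONIUM_MASS = 18.033823

#: Neutral water loss.
WATER_MASS = 18.010565

#: 13C - 12C mass difference; spacing of the M+1 isotopologue.
C13_C12_DELTA = 1.00336

#: Supported singly-charged adducts: name -> (mass delta in Da, charge sign).
ADDUCTS: dict[str, tuple[float, int]] = {
    "[M+H]+": (PROTON_MASS, +1),
    "[M-H]-": (-PROTON_MASS, -1),
    "[M+NH4]+": (AMMONIUM_MASS, +1),
    "[M-H2O+H]+": (-WATER_MASS + PROTON_MASS, +1),
}

#: Acquisition m/z range of the instrument method emulated here.
MZ_MIN = 75.0
MZ_MAX = 1125.0

#: The four insect species of the study cohort (closed set).
SPECIES = (
    "Acheta domesticus",
    "Bombyx mori",
    "Hermetia illucens",
    "Tenebrio molitor",
)

#: Block identifiers: extraction (A = H2O:MeOH 20:80 -> "meoh",
#: B = ethyl acetate -> "etac") crossed with ionization polarity.
BLOCK_ORDER = ("meohpos", "meohneg", "etacpos", "etacneg")

#: (extraction, polarity) -> block id.
BLOCK_OF: dict[tuple[str, str], str] = {
    ("A", "pos"): "meohpos",
    ("A", "neg"): "meohneg",
    ("B", "pos"): "etacpos",
    ("B", "neg"): "etacneg",
}

#: block id -> (extraction, polarity).
BLOCK_META: dict[str, tuple[str, str]] = {v: k for k, v in BLOCK_OF.items()}

POLARITIES = ("pos", "neg")
EXTRACTIONS = ("A", "B")
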