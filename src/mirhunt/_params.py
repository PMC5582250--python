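"""Embedded nearest-neighbor energy parameters (37 degC, 1 M NaCl regime).

All energies are free-energy changes in kcal/mol, stored internally as
integers in tenths of a kcal/mol so the dynamic program is exact and
tie-breaking is well defined.

The table covers the 21 unique nearest-neighbor stacking contexts over the
six canonical pairs (Watson-Crick plus G:U wobble), loop-initiation
penalties for hairpin, bulge and interior loops (tabulated for small sizes,
Jacobson-Stockmayer logarithmic extrapolation beyond), and an affine
multibranch-loop penalty.  Dangling ends, terminal mismatches and coaxial
stacking are deliberately omitted: the screen's thresholds are calibrated
against this model, not against any external parameter set.
"""

from __future__ import annotations

import math

import numpy as np

# residue codes: A=0 C=1 G=2 U=3 N=4
BASES = "ACGUN"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# pair codes
_PAIRS = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
PAIR_INDEX = np.full((5, 5), -1, dtype=np.int64)
for _k, (_x, _y) in enumerate(_PAIRS):
    PAIR_INDEX[BASE_INDEX[_x], BASE_INDEX[_y]] = _k

#: gas constant * 310.15 K, kcal/mol
RT37 = 0.0019872 * 310.15
#: Jacobson-Stockmayer prefactor for loop-entropy extrapolation
JS_COEF = 1.75 * RT37

MIN_HAIRPIN = 3  # minimum unpaired residues closed by a hairpin
MAX_LOOP_DEFAULT = 30  # maximum interior/bulge loop size

# ---------------------------------------------------------------------------
# stacking: E[(outer, inner)] for the motif
#     5'-X Z-3'
#     3'-Y W-5'
# with outer pair (X, Y) = (seq[i], seq[j]) and inner pair (Z, W) =
# (seq[i+1], seq[j-1]).  Reverse-complement symmetry
# E[(X,Y),(Z,W)] == E[(W,Z),(Y,X)] fills the remaining contexts.
# Watson-Crick/Watson-Crick values follow the published unified nearest-
# neighbor set; wobble-containing contexts are weaker by construction.
_STACK_SEED: dict[tuple[tuple[str, str], tuple[str, str]], float] = {
    (("A", "U"), ("A", "U")): -0.9,
    (("A", "U"), ("U", "A")): -1.1,
    (("U", "A"), ("A", "U")): -1.3,
    (("C", "G"), ("U", "A")): -2.1,
    (("C", "G"), ("A", "U")): -2.1,
    (("G", "C"), ("U", "A")): -2.2,
    (("G", "C"), ("A", "U")): -2.4,
    (("C", "G"), ("G", "C")): -2.4,
    (("G", "C"), ("G", "C")): -3.3,
    (("G", "C"), ("C", "G")): -3.4,
    # wobble-containing contexts
    (("A", "U"), ("G", "U")): -0.5,
    (("A", "U"), ("U", "G")): -1.4,
    (("U", "A"), ("G", "U")): -1.0,
    (("U", "A"), ("U", "G")): -1.3,
    (("G", "C"), ("G", "U")): -1.5,
    (("G", "C"), ("U", "G")): -2.5,
    (("C", "G"), ("G", "U")): -2.1,
    (("C", "G"), ("U", "G")): -1.4,
    (("G", "U"), ("G", "U")): -0.5,
    (("G", "U"), ("U", "G")): -0.3,
    (("U", "G"), ("G", "U")): -0.6,
}


def _build_stack_table() -> np.ndarray:
    table = np.full((6, 6), 10**6, dtype=np.int64)
    pair_code = {p: k for k, p in enumerate(_PAIRS)}
    entries: dict[tuple[int, int], int] = {}
    for (outer, inner), dg in _STACK_SEED.items():
        tenths = round(dg * 10)
        o, i = pair_code[outer], pair_code[inner]
        # reverse-complement symmetric context
        o2 = pair_code[(inner[1], inner[0])]
        i2 = pair_code[(outer[1], outer[0])]
        for key in ((o, i), (o2, i2)):
            if key in entries and entries[key] != tenths:
                raise AssertionError(f"inconsistent stack symmetry at {key}")
            entries[key] = tenths
    if len(entries) != 36:
        raise AssertionError(f"stacking table incomplete: {len(entries)}/36")
    for (o, i), tenths in entries.items():
        table[o, i] = tenths
    return table


#: 6x6 stacking table in tenths of kcal/mol, indexed [outer_pair, inner_pair]
STACK10 = _build_stack_table()

# loop initiation penalties (kcal/mol) for tabulated sizes
_HAIRPIN_SMALL = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_SMALL = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERIOR_SMALL = {2: 1.5, 3: 1.8, 4: 2.0, 5: 2.2, 6: 2.5}

# affine multibranch penalty a + b*branches + c*unpaired (tenths)
MULTI_A10 = 34
MULTI_B10 = 4
MULTI_C10 = 0


def _extrapolated(small: dict[int, float], size: int) -> float:
    base = max(small)
    if size <= base:
        return small[size]
    return small[base] + JS_COEF * math.log(size / base)


def hairpin_table(max_size: int) -> np.ndarray:
    """Hairpin-loop initiation penalties, tenths of kcal/mol, index = loop size."""
    t = np.full(max_size + 1, 10**6, dtype=np.int64)
    for size in range(MIN_HAIRPIN, max_size + 1):
        t[size] = round(_extrapolated(_HAIRPIN_SMALL, size) * 10)
    return t


def bulge_table(max_loop: int) -> np.ndarray:
    t = np.full(max_loop + 1, 10**6, dtype=np.int64)
    for size in range(1, max_loop + 1):
        t[size] = round(_extrapolated(_BULGE_SMALL, size) * 10)
    return t


def interior_table(max_loop: int) -> np.ndarray:
    t = np.full(max_loop + 1, 10**6, dtype=np.int64)
    for size in range(2, max_loop + 1):
        t[size] = round(_extrapolated(_INTERIOR_SMALL, size) * 10)
    return t
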