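"""Minimum-free-energy RNA secondary structure prediction.

A nearest-neighbor dynamic program over non-crossing canonical pairs
(Watson-Crick and G:U), with stacking energies, tabulated/log-extrapolated
loop penalties and an affine multibranch term, evaluated in exact tenths of
a kcal/mol.  Interior and bulge loops are capped (default 30 nt); hairpin
loops hold at least 3 residues; N never pairs; pseudoknots are excluded by
construction.

Ties are resolved toward fewer pairs and then by a fixed, documented
decomposition order in the traceback, so folding is fully deterministic.

`exhaustive_mfe` and `max_pairing` are independent reference routines for
short sequences: the former enumerates every valid pair set and scores it
with `structure_energy`, the latter is a Nussinov-style pair maximizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._params import (
    BASE_INDEX,
    MAX_LOOP_DEFAULT,
    MIN_HAIRPIN,
    MULTI_A10,
    MULTI_B10,
    MULTI_C10,
    PAIR_INDEX,
    STACK10,
    bulge_table,
    hairpin_table,
    interior_table,
)
from .io_formats import ValidationError, reverse_complement

INF = 1 << 28

MIN_FOLD_LEN = 10
MAX_FOLD_LEN = 1000


def encode(sequence: str) -> np.ndarray:
    try:
        return np.array([BASE_INDEX[c] for c in sequence], dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(f"illegal residue {exc.args[0]!r} in RNA sequence") from exc


@dataclass(frozen=True)
class SecondaryStructure:
    """A predicted structure: sequence, dot-bracket, MFE and 1-based pairs."""

    sequence: str
    pairing: str
    mfe: float
    pair_list: tuple[tuple[int, int], ...]

    def partner_array(self) -> np.ndarray:
        """0-based partner index per position, -1 if unpaired."""
        partner = np.full(len(self.sequence), -1, dtype=np.int64)
        for i, j in self.pair_list:
            partner[i - 1] = j - 1
            partner[j - 1] = i - 1
        return partner


@njit(cache=True)
def _fill(codes, pair_index, stack, hairpinT, bulgeT, interiorT,
          ma, mb, mc, max_loop):  # pragma: no cover - exercised via fold()
    n = codes.shape[0]
    V = np.full((n, n), INF, np.int64)
    VP = np.zeros((n, n), np.int64)
    WM = np.full((n, n), INF, np.int64)
    WMP = np.zeros((n, n), np.int64)
    WM2 = np.full((n, n), INF, np.int64)
    WM2P = np.zeros((n, n), np.int64)
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            p = pair_index[codes[i], codes[j]]
            if p >= 0:
                beste = hairpinT[span - 1]
                bestp = 1
                ip_hi = min(i + max_loop + 1, j - MIN_HAIRPIN - 2)
                for ip in range(i + 1, ip_hi + 1):
                    l1 = ip - i - 1
                    jp_lo = j - 1 - (max_loop - l1)
                    if jp_lo < ip + MIN_HAIRPIN + 1:
                        jp_lo = ip + MIN_HAIRPIN + 1
                    for jp in range(jp_lo, j):
                        if V[ip, jp] >= INF:
                            continue
                        l2 = j - jp - 1
                        if l1 == 0 and l2 == 0:
                            q = pair_index[codes[ip], codes[jp]]
                            e = stack[p, q] + V[ip, jp]
                        elif l1 == 0 or l2 == 0:
                            e = bulgeT[l1 + l2] + V[ip, jp]
                        else:
                            e = interiorT[l1 + l2] + V[ip, jp]
                        pr = VP[ip, jp] + 1
                        if e < beste or (e == beste and pr < bestp):
                            beste = e
                            bestp = pr
                if WM2[i + 1, j - 1] < INF:
                    e = ma + mb + WM2[i + 1, j - 1]
                    pr = WM2P[i + 1, j - 1] + 1
                    if e < beste or (e == beste and pr < bestp):
                        beste = e
                        bestp = pr
                V[i, j] = beste
                VP[i, j] = bestp
            # WM: >=1 helix in a multiloop context
            beste = INF
            bestp = 0
            if V[i, j] < INF:
                beste = V[i, j] + mb
                bestp = VP[i, j]
            if WM[i + 1, j] < INF:
                e = WM[i + 1, j] + mc
                pr = WMP[i + 1, j]
                if e < beste or (e == beste and pr < bestp):
                    beste = e
                    bestp = pr
            if WM[i, j - 1] < INF:
                e = WM[i, j - 1] + mc
                pr = WMP[i, j - 1]
                if e < beste or (e == beste and pr < bestp):
                    beste = e
                    bestp = pr
            beste2 = INF
            bestp2 = 0
            for k in range(i + MIN_HAIRPIN + 1, j - MIN_HAIRPIN - 1):
                if WM[i, k] < INF and WM[k + 1, j] < INF:
                    e = WM[i, k] + WM[k + 1, j]
                    pr = WMP[i, k] + WMP[k + 1, j]
                    if e < beste2 or (e == beste2 and pr < bestp2):
                        beste2 = e
                        bestp2 = pr
            WM2[i, j] = beste2
            WM2P[i, j] = bestp2
            if beste2 < beste or (beste2 == beste and bestp2 < bestp):
                beste = beste2
                bestp = bestp2
            WM[i, j] = beste
            WMP[i, j] = bestp
    W = np.zeros(n + 1, np.int64)
    WP = np.zeros(n + 1, np.int64)
    for j in range(n):
        beste = W[j]
        bestp = WP[j]
        for i in range(0, j - MIN_HAIRPIN):
            if V[i, j] < INF:
                e = (W[i] if i > 0 else 0) + V[i, j]
                pr = (WP[i] if i > 0 else 0) + VP[i, j]
                if e < beste or (e == beste and pr < bestp):
                    beste = e
                    bestp = pr
        W[j + 1] = beste
        WP[j + 1] = bestp
    return V, VP, WM, WMP, WM2, WM2P, W, WP


def _loop_tables(n: int, max_loop: int):
    return hairpin_table(max(n, MIN_HAIRPIN)), bulge_table(max_loop), interior_table(max_loop)


class _Traceback:
    """Replays the DP decisions in the same candidate order as the kernel."""

    def __init__(self, codes, tables, max_loop):
        self.codes = codes
        self.hairpinT, self.bulgeT, self.interiorT = tables
        self.max_loop = max_loop

    def run(self, V, VP, WM, WMP, WM2, WM2P, W, WP):
        pairs: list[tuple[int, int]] = []
        n = len(self.codes)
        stack: list[tuple[str, int, int]] = [("W", 0, n - 1)]
        while stack:
            kind, i, j = stack.pop()
            if kind == "W":
                self._trace_w(i, j, V, VP, W, WP, pairs, stack)
            elif kind == "V":
                self._trace_v(i, j, V, VP, WM2, WM2P, pairs, stack)
            else:
                self._trace_wm(kind, i, j, V, VP, WM, WMP, WM2, WM2P, stack)
        return pairs

    def _trace_w(self, i, j, V, VP, W, WP, pairs, stack):
        while j >= i:
            target = (W[j + 1], WP[j + 1])
            if target == (W[j], WP[j]):
                j -= 1
                continue
            found = False
            for k in range(i, j - MIN_HAIRPIN):
                if V[k, j] < INF:
                    e = (W[k] if k > 0 else 0) + V[k, j]
                    pr = (WP[k] if k > 0 else 0) + VP[k, j]
                    if (e, pr) == target:
                        stack.append(("V", k, j))
                        j = k - 1
                        found = True
                        break
            if not found:  # should not happen
                raise AssertionError("external traceback failed")

    def _trace_v(self, i, j, V, VP, WM2, WM2P, pairs, stack):
        pair_index = PAIR_INDEX
        codes = self.codes
        p = pair_index[codes[i], codes[j]]
        pairs.append((i, j))
        target = (V[i, j], VP[i, j])
        if target == (self.hairpinT[j - i - 1], 1):
            return
        ip_hi = min(i + self.max_loop + 1, j - MIN_HAIRPIN - 2)
        for ip in range(i + 1, ip_hi + 1):
            l1 = ip - i - 1
            jp_lo = max(j - 1 - (self.max_loop - l1), ip + MIN_HAIRPIN + 1)
            for jp in range(jp_lo, j):
                if V[ip, jp] >= INF:
                    continue
                l2 = j - jp - 1
                if l1 == 0 and l2 == 0:
                    q = pair_index[codes[ip], codes[jp]]
                    e = STACK10[p, q] + V[ip, jp]
                elif l1 == 0 or l2 == 0:
                    e = self.bulgeT[l1 + l2] + V[ip, jp]
                else:
                    e = self.interiorT[l1 + l2] + V[ip, jp]
                if (e, VP[ip, jp] + 1) == target:
                    stack.append(("V", ip, jp))
                    return
        if WM2[i + 1, j - 1] < INF:
            e = MULTI_A10 + MULTI_B10 + WM2[i + 1, j - 1]
            if (e, WM2P[i + 1, j - 1] + 1) == target:
                stack.append(("WM2", i + 1, j - 1))
                return
        raise AssertionError("paired-region traceback failed")

    def _trace_wm(self, kind, i, j, V, VP, WM, WMP, WM2, WM2P, stack):
        if kind == "WM2":
            target = (WM2[i, j], WM2P[i, j])
            for k in range(i + MIN_HAIRPIN + 1, j - MIN_HAIRPIN - 1):
                if WM[i, k] < INF and WM[k + 1, j] < INF:
                    e = WM[i, k] + WM[k + 1, j]
                    pr = WMP[i, k] + WMP[k + 1, j]
                    if (e, pr) == target:
                        stack.append(("WM", i, k))
                        stack.append(("WM", k + 1, j))
                        return
            raise AssertionError("multiloop traceback failed")
        target = (WM[i, j], WMP[i, j])
        if V[i, j] < INF and (V[i, j] + MULTI_B10, VP[i, j]) == target:
            stack.append(("V", i, j))
            return
        if WM[i + 1, j] < INF and (WM[i + 1, j] + MULTI_C10, WMP[i + 1, j]) == target:
            stack.append(("WM", i + 1, j))
            return
        if WM[i, j - 1] < INF and (WM[i, j - 1] + MULTI_C10, WMP[i, j - 1]) == target:
            stack.append(("WM", i, j - 1))
            return
        if (WM2[i, j], WM2P[i, j]) == target:
            stack.append(("WM2", i, j))
            return
        raise AssertionError("multiloop-segment traceback failed")


def fold(sequence: str, max_loop_size: int = MAX_LOOP_DEFAULT) -> SecondaryStructure:
    """Minimum-free-energy structure of an RNA sequence at 37 degC.

    Energies are reported to 0.1 kcal/mol; the returned MFE is never
    positive (the open chain scores zero).
    """
    if len(sequence) < MIN_FOLD_LEN:
        raise ValidationError(
            f"sequence of length {len(sequence)} below folding minimum {MIN_FOLD_LEN}"
        )
    if len(sequence) > MAX_FOLD_LEN:
        raise ValidationError(f"sequence longer than {MAX_FOLD_LEN} nt")
    codes = encode(sequence)
    n = len(codes)
    tables = _loop_tables(n, max_loop_size)
    V, VP, WM, WMP, WM2, WM2P, W, WP = _fill(
        codes, PAIR_INDEX, STACK10, tables[0], tables[1], tables[2],
        MULTI_A10, MULTI_B10, MULTI_C10, max_loop_size,
    )
    tb = _Traceback(codes, tables, max_loop_size)
    pairs0 = tb.run(V, VP, WM, WMP, WM2, WM2P, W, WP) if W[n] < 0 else []
    db = ["."] * n
    for i, j in pairs0:
        db[i] = "("
        db[j] = ")"
    mfe = min(int(W[n]), 0) / 10.0
    pair_list = tuple(sorted((i + 1, j + 1) for i, j in pairs0))
    return SecondaryStructure(sequence, "".join(db), mfe, pair_list)


# --- independent reference routines ----------------------------------------

def structure_energy(sequence: str, pairs, max_loop_size: int = MAX_LOOP_DEFAULT) -> float:
    """Free energy (kcal/mol) of a given pair set by loop decomposition.

    Returns ``inf`` for structures the model forbids (non-canonical pair,
    hairpin loop < 3, interior/bulge loop above the cap, crossing pairs).
    """
    codes = encode(sequence)
    n = len(codes)
    pairs = sorted((min(i, j), max(i, j)) for i, j in pairs)
    partner = {}
    for i, j in pairs:
        if i == j or i < 0 or j >= n:
            return float("inf")
        if i in partner or j in partner:
            return float("inf")
        if PAIR_INDEX[codes[i], codes[j]] < 0:
            return float("inf")
        partner[i] = j
        partner[j] = i
    # crossing check + nesting tree
    stack: list[tuple[int, int]] = []
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    for i, j in pairs:
        while stack and stack[-1][1] < i:
            stack.pop()
        if stack and not (stack[-1][0] < i and j < stack[-1][1]):
            return float("inf")
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append((i, j))
        children.setdefault((i, j), [])
        stack.append((i, j))
    hT, bT, iT = _loop_tables(n, max_loop_size)
    total = 0
    for key, kids in children.items():
        if key is None:
            continue
        i, j = key
        if not kids:
            size = j - i - 1
            if size < MIN_HAIRPIN:
                return float("inf")
            total += hT[size]
        elif len(kids) == 1:
            (a, b), = kids
            l1, l2 = a - i - 1, j - b - 1
            if l1 == 0 and l2 == 0:
                total += STACK10[PAIR_INDEX[codes[i], codes[j]],
                                 PAIR_INDEX[codes[a], codes[b]]]
            elif l1 == 0 or l2 == 0:
                if l1 + l2 > max_loop_size:
                    return float("inf")
                total += bT[l1 + l2]
            else:
                if l1 + l2 > max_loop_size:
                    return float("inf")
                total += iT[l1 + l2]
        else:
            unpaired = (j - i - 1) - sum(b - a + 1 for a, b in kids)
            total += MULTI_A10 + MULTI_B10 * (len(kids) + 1) + MULTI_C10 * unpaired
    return total / 10.0


def _all_pair_sets(codes, i, j):
    """Yield every non-crossing canonical pair set in ``[i, j]`` (0-based)."""
    if j - i < MIN_HAIRPIN + 1:
        yield []
        return
    for rest in _all_pair_sets(codes, i + 1, j):
        yield rest
    for k in range(i + MIN_HAIRPIN + 1, j + 1):
        if PAIR_INDEX[codes[i], codes[k]] >= 0:
            for inner in _all_pair_sets(codes, i + 1, k - 1):
                for outer in _all_pair_sets(codes, k + 1, j):
                    yield [(i, k)] + inner + outer


def exhaustive_mfe(sequence: str, max_loop_size: int = MAX_LOOP_DEFAULT) -> float:
    """Exact MFE by brute-force enumeration of all valid pair sets.

    Intended for short sequences (exponential in length); the reference
    against which the dynamic program is validated.
    """
    codes = encode(sequence)
    best = 0.0
    for pairs in _all_pair_sets(codes, 0, len(codes) - 1):
        e = structure_energy(sequence, pairs, max_loop_size)
        if e < best:
            best = e
    return best


def max_pairing(sequence: str) -> int:
    """Maximum number of non-crossing canonical pairs (hairpin loops >= 3).

    Nussinov-style reference, independent of the energy model.
    """
    codes = encode(sequence)
    n = len(codes)
    if n == 0:
        return 0
    M = np.zeros((n, n), dtype=np.int64)
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j]
            for k in range(i + MIN_HAIRPIN + 1, j + 1):
                if PAIR_INDEX[codes[i], codes[k]] >= 0:
                    left = M[i + 1, k - 1] if k - i > MIN_HAIRPIN + 1 else 0
                    right = M[k + 1, j] if j - k > 1 else 0
                    cand = 1 + left + right
                    if cand > best:
                        best = cand
            M[i, j] = best
    return int(M[0, n - 1])


# --- hairpin feature extraction --------------------------------------------

@dataclass
class HairpinFeatures:
    """Features of the hairpin containing a mature window (0-based half-open)."""

    arm: str  # 5p | 3p | loop | outside
    duplex_mismatches: int
    largest_mature_break: int
    loop_start: int | None = None
    loop_end: int | None = None


def extract_hairpin(structure: SecondaryStructure, mature_range: tuple[int, int]) -> HairpinFeatures:
    """Locate the mature window on the folded hairpin and derive its features.

    ``arm`` is 5p when the mature's partners lie downstream, 3p when
    upstream, ``loop`` when the window straddles the terminal loop (or is
    entirely unpaired between stem arms) and ``outside`` when no pairing
    context exists.  ``duplex_mismatches`` counts mature positions unpaired
    against the star arm; ``largest_mature_break`` is the longest run of
    consecutive unpaired positions inside the mature window.
    """
    start, end = mature_range
    partner = structure.partner_array()
    n = len(partner)
    if start < 0 or end > n or start >= end:
        raise ValidationError("mature range outside structure")
    window = partner[start:end]
    down = int(np.sum(window > np.arange(start, end)))
    up = int(np.sum((window >= 0) & (window < np.arange(start, end))))
    unpaired = int(np.sum(window < 0))
    # longest unpaired run within the mature window
    run = best_run = 0
    for v in window:
        run = run + 1 if v < 0 else 0
        best_run = max(best_run, run)
    # terminal loop of the enclosing hairpin, if locatable
    loop_start = loop_end = None
    paired_idx = [start + k for k in range(end - start) if window[k] >= 0]
    if paired_idx:
        inner_i = max(min(i, partner[i]) for i in paired_idx)
        inner_j = min(max(i, partner[i]) for i in paired_idx)
        if inner_i < inner_j:
            loop_start, loop_end = inner_i + 1, inner_j  # half-open
    if down == 0 and up == 0:
        # fully unpaired: inside some hairpin loop, or outside any stem
        enclosing = [
            (i, partner[i]) for i in range(n)
            if partner[i] > i and i < start and partner[i] >= end
        ]
        arm = "loop" if enclosing else "outside"
        return HairpinFeatures(arm, end - start, best_run)
    if down > 0 and up > 0 and min(down, up) / max(down, up) > 0.2:
        arm = "loop"
    else:
        arm = "5p" if down >= up else "3p"
    return HairpinFeatures(arm, unpaired, best_run, loop_start, loop_end)


def fold_reverse_complement(sequence: str, max_loop_size: int = MAX_LOOP_DEFAULT) -> SecondaryStructure:
    """Fold the reverse complement (convenience for strand checks)."""
    return fold(reverse_complement(sequence), max_loop_size)
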