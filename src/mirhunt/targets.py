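"""miRNA-target complementarity scoring and inhibition-mode calls.

An expectation penalty accumulates over the antiparallel miRNA/site
duplex: Watson-Crick pairs are free, G:U wobbles cost 0.5, mismatches 1.0
and gaps 2.0, with every penalty doubled inside the seed region (miRNA
positions 2-13 counted from the 5' end).  Sites up to a cutoff (default
3.0) are reported; repression mode is called translation inhibition when
any non-Watson-Crick position falls at the duplex center (miRNA positions
10-11, the slicing site), cleavage otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import SequenceRecord, ValidationError

PENALTY_GU = 0.5
PENALTY_MISMATCH = 1.0
PENALTY_GAP = 2.0
SEED_START = 2
SEED_END = 13
CENTRAL_POSITIONS = (10, 11)

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}
_ALPHABET = set("ACGUN-")

_CODE = {c: i for i, c in enumerate("ACGUN")}


def _pair_symbol(m: str, s: str) -> str:
    if (m, s) in _WC:
        return "|"
    if (m, s) in _WOBBLE:
        return "o"
    return " "


@dataclass(frozen=True)
class TargetSite:
    """A scored duplex between a miRNA and a transcript site."""

    mirna_id: str
    transcript_id: str
    site_start: int  # 1-based inclusive on the transcript
    site_end: int
    expectation: float
    alignment: tuple[str, str, str]  # miRNA 5'->3', match line, site 3'->5'
    mode: str  # cleavage | translation

    def pretty(self) -> str:
        mir, line, site = self.alignment
        return (
            f"{self.mirna_id} vs {self.transcript_id}"
            f" [{self.site_start}-{self.site_end}]"
            f" E={self.expectation:g} mode={self.mode}\n"
            f"  miRNA  5' {mir} 3'\n"
            f"            {line}\n"
            f"  target 3' {site} 5'\n"
        )


def score_duplex(mirna: str, site: str) -> tuple[float, tuple[str, str, str]]:
    """Expectation of an aligned duplex.

    ``mirna`` is written 5'->3'; ``site`` is the aligned transcript window
    written 3'->5' so that column k pairs position k of each string.  Both
    may contain ``-`` gap characters; positions are counted along the
    miRNA from its 5' end (a site base facing a miRNA gap is charged at
    the position of the last consumed miRNA base).
    """
    if len(mirna) != len(site):
        raise ValidationError("aligned strings must have equal length")
    for s, name in ((mirna, "miRNA"), (site, "site")):
        bad = set(s) - _ALPHABET
        if bad:
            raise ValidationError(f"illegal characters in {name} string: {sorted(bad)}")
    expectation = 0.0
    match_line = []
    pos = 0  # last consumed miRNA position, 1-based
    for m, s in zip(mirna, site):
        if m == "-" and s == "-":
            raise ValidationError("column with gaps on both strands")
        if m != "-":
            pos += 1
        in_seed = SEED_START <= max(pos, 1) <= SEED_END
        weight = 2.0 if in_seed else 1.0
        if m == "-" or s == "-":
            expectation += PENALTY_GAP * weight
            match_line.append("-")
        else:
            sym = _pair_symbol(m, s)
            match_line.append(sym)
            if sym == "o":
                expectation += PENALTY_GU * weight
            elif sym == " ":
                expectation += PENALTY_MISMATCH * weight
    return expectation, (mirna, "".join(match_line), site)


def call_mode(site: TargetSite) -> str:
    """Cleavage unless a non-Watson-Crick column sits at miRNA position 10
    or 11 (then translation inhibition)."""
    mir, line, _ = site.alignment
    pos = 0
    for m, sym in zip(mir, line):
        if m != "-":
            pos += 1
        if sym != "|" and max(pos, 1) in CENTRAL_POSITIONS:
            return "translation"
    return "cleavage"


def _penalty_matrix() -> np.ndarray:
    P = np.full((5, 5), PENALTY_MISMATCH)
    for a, b in _WC:
        P[_CODE[a], _CODE[b]] = 0.0
    for a, b in _WOBBLE:
        P[_CODE[a], _CODE[b]] = PENALTY_GU
    P[_CODE["N"], :] = PENALTY_MISMATCH
    P[:, _CODE["N"]] = PENALTY_MISMATCH
    return P


_P = _penalty_matrix()


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq], dtype=np.int8)


def _site_string(transcript: str, start: int, end: int) -> str:
    """Transcript window written 3'->5' for column-wise pairing."""
    return transcript[start:end][::-1]


def find_sites(
    mirna: SequenceRecord,
    transcripts: list[SequenceRecord],
    max_expectation: float = 3.0,
    max_gaps: int = 1,
) -> list[TargetSite]:
    """Every site with expectation <= the cutoff, by exhaustive sliding
    alignment of the miRNA against both possible single-gap registers.

    Overlapping sites on one transcript are deduplicated to the
    best-scoring (ties: leftmost, then gap-free first).
    """
    if not transcripts:
        raise ValidationError("no transcripts supplied")
    m = len(mirna.residues)
    mir = mirna.residues
    # weights per duplex column for the ungapped register, from the 3' site
    # end: column k of the duplex is transcript offset m-1-k in the window
    weights = np.array(
        [2.0 if SEED_START <= (m - i) <= SEED_END else 1.0 for i in range(m)]
    )
    rev_mir = _encode(mir[::-1])
    results: list[TargetSite] = []
    for tx in transcripts:
        t = tx.residues
        n = len(t)
        raw: list[tuple[float, int, int, int, tuple[str, str, str]]] = []
        if n >= m:
            windows = sliding_window_view(_encode(t), m)
            pen = _P[rev_mir[None, :], windows] * weights[None, :]
            totals = pen.sum(axis=1)
            for p in np.nonzero(totals <= max_expectation + 1e-9)[0]:
                p = int(p)
                e, aln = score_duplex(mir, _site_string(t, p, p + m))
                raw.append((e, p, p + m, 0, aln))
        if max_gaps >= 1:
            # site-side gap: the window is one base short; miRNA base g+1
            # (from the 5' end) faces a gap
            for p in range(0, n - (m - 1) + 1):
                win = _site_string(t, p, p + m - 1)
                for g in range(1, m - 1):
                    site = win[:g] + "-" + win[g:]
                    e, aln = score_duplex(mir, site)
                    if e <= max_expectation + 1e-9:
                        raw.append((e, p, p + m - 1, 1, aln))
            # miRNA-side gap: the window is one base long
            if n >= m + 1:
                for p in range(0, n - (m + 1) + 1):
                    win = _site_string(t, p, p + m + 1)
                    for g in range(1, m):
                        gapped_mir = mir[:g] + "-" + mir[g:]
                        e, aln = score_duplex(gapped_mir, win)
                        if e <= max_expectation + 1e-9:
                            raw.append((e, p, p + m + 1, 1, aln))
        # deduplicate overlapping windows to the best-scoring site
        raw.sort(key=lambda r: (r[0], r[3], r[1], r[2]))
        chosen: list[tuple[float, int, int, int, tuple[str, str, str]]] = []
        for cand in raw:
            if all(cand[2] <= c[1] or cand[1] >= c[2] for c in chosen):
                chosen.append(cand)
        chosen.sort(key=lambda r: r[1])
        for e, start, end, _gaps, aln in chosen:
            site = TargetSite(
                mirna_id=mirna.id,
                transcript_id=tx.id,
                site_start=start + 1,
                site_end=end,
                expectation=e,
                alignment=aln,
                mode="cleavage",
            )
            results.append(replace(site, mode=call_mode(site)))
    return results
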