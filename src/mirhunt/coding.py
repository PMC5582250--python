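"""Database-free protein-coding classification of ESTs.

A six-frame open-reading-frame rule stands in for a protein-database
search: an EST is called coding when its longest ORF reaches a length
threshold (default 80 aa).  Because ESTs are fragments, ORFs may open at a
sequence edge, not only at AUG; every ORF ends at a stop codon or at the
edge.  A precomputed exclusion list can be supplied instead by callers
that ran an external homology search.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import SequenceRecord, normalize_residues, reverse_complement

STOP_CODONS = {"UAA", "UAG", "UGA"}
START_CODON = "AUG"

FRAME_ORDER = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class OrfCall:
    """The longest open reading frame found in any of the six frames.

    Coordinates are 1-based nucleotide positions on the given (plus)
    strand; for minus frames start > end would be confusing, so the
    interval is reported in plus-strand orientation with the frame sign
    carrying the direction.
    """

    est_id: str
    frame: int
    orf_start: int
    orf_end: int
    orf_aa_len: int


def _frame_orfs(rna: str, offset: int):
    """Yield (codon_start_index, n_codons, ends_at_stop, at_edge) per segment."""
    n = len(rna)
    seg_start = offset
    pos = offset
    while pos + 3 <= n:
        codon = rna[pos:pos + 3]
        if codon in STOP_CODONS:
            yield seg_start, (pos - seg_start) // 3, True, seg_start == offset
            seg_start = pos + 3
        pos += 3
    if seg_start < n:
        yield seg_start, (pos - seg_start) // 3, False, seg_start == offset


def _best_in_frame(rna: str, offset: int) -> tuple[int, int] | None:
    """Best ORF (aa length, nt start) in one frame of an RNA string."""
    best: tuple[int, int] | None = None
    for seg_start, n_codons, _stop, at_edge in _frame_orfs(rna, offset):
        if at_edge:
            start = seg_start
        else:
            start = None
            for k in range(n_codons):
                if rna[seg_start + 3 * k: seg_start + 3 * k + 3] == START_CODON:
                    start = seg_start + 3 * k
                    break
            if start is None:
                continue
        aa = n_codons - (start - seg_start) // 3
        if best is None or aa > best[0] or (aa == best[0] and start < best[1]):
            best = (aa, start)
    return best


def longest_orf(est: SequenceRecord) -> OrfCall:
    """Longest ORF across all six reading frames.

    Ties prefer the earlier frame in (+1, +2, +3, -1, -2, -3) order, then
    the smaller start coordinate.
    """
    rna = normalize_residues(est.residues, "RNA")
    rc = reverse_complement(rna)
    n = len(rna)
    best_call: OrfCall | None = None
    for frame in FRAME_ORDER:
        seq = rna if frame > 0 else rc
        offset = abs(frame) - 1
        found = _best_in_frame(seq, offset)
        if found is None:
            continue
        aa, start = found
        end = start + 3 * aa  # exclusive, excluding stop codon
        if frame > 0:
            s1, e1 = start + 1, end
        else:  # map reverse-strand coordinates back to plus strand
            s1, e1 = n - end + 1, n - start
        call = OrfCall(est.id, frame, s1, e1, aa)
        if best_call is None or call.orf_aa_len > best_call.orf_aa_len:
            best_call = call
    assert best_call is not None  # every frame yields at least a 0-aa segment
    return best_call


def is_protein_coding(est: SequenceRecord, min_orf_aa: int = 80) -> tuple[bool, OrfCall]:
    """True when the longest six-frame ORF reaches ``min_orf_aa`` residues."""
    call = longest_orf(est)
    return call.orf_aa_len >= min_orf_aa, call
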