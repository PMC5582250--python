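"""Precursor excision, folding statistics and the filtration criteria.

For each homology hit a ladder of candidate windows anchored on the mature
match is excised and folded; the structurally valid window with the best
(most negative) MFEI is kept.  The screen then applies, in order:

  arm                  mature lies on one stem arm (5p or 3p)
  mature_contiguity    no unpaired run longer than 3 nt inside the mature
  duplex_mismatches    mature positions unpaired against the star <= 6
  mfe                  MFE <= -15 kcal/mol (more negative passes)
  mfei                 MFEI <= -0.7 (MFEI <= -0.85 flags high confidence)
  gc                   GC content within 20-70 %
  length               precursor length within 50-350 nt

The verdict is the conjunction of all criteria.  Whether the mature starts
with U is recorded but never filtered on.  Simple tandem repeats are
annotated (transposon-like content) but likewise never filtered on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import folding
from .homology import HomologyHit
from .io_formats import (
    CRITERIA_ORDER,
    RunConfig,
    SequenceRecord,
    ValidationError,
    family_of,
    reverse_complement,
)

#: numerical slack when comparing statistics against thresholds
EPS = 1e-9

#: candidate precursor window lengths (clipped to the configured bounds)
WINDOW_LADDER = (60, 80, 100, 120, 160, 200, 250, 300)

#: leader/trailer kept between the window edge and the mature match
WINDOW_MARGIN = 10


@dataclass
class PrecursorCandidate:
    """An excised, folded putative pre-miRNA window.

    ``window_start``/``window_end`` are 0-based half-open on the EST plus
    strand; ``precursor_seq`` and ``mature_offset`` are in hit orientation
    (reverse complemented when the hit is on the minus strand).
    """

    candidate_id: str
    hit: HomologyHit
    window_start: int
    window_end: int
    precursor_seq: str
    structure: folding.SecondaryStructure
    mature_offset: int
    mature_len: int
    arm: str
    features: folding.HairpinFeatures


def gc_percent(seq: str) -> float:
    """GC content in percent; N residues are excluded from both counts."""
    if not seq:
        raise ValidationError("empty sequence")
    gc = sum(1 for c in seq if c in "GC")
    denom = sum(1 for c in seq if c in "ACGUT")
    return 100.0 * gc / denom if denom else 0.0


def amfe(mfe: float, length: int) -> float:
    """Adjusted MFE: energy per 100 nt, (MFE / length) * 100."""
    if length <= 0:
        raise ValidationError("length must be positive")
    return mfe / length * 100.0


def mfei(mfe: float, length: int, gc: float) -> float:
    """Minimal folding free energy index: AMFE / GC%, GC given as a
    percentage number (50, not 0.5).  Undefined (0 GC) is the caller's
    criterion failure, not a crash: returns 0.0."""
    if gc <= 0:
        return 0.0
    return amfe(mfe, length) / gc


@dataclass(frozen=True)
class RepeatRun:
    """A maximal exact tandem repeat (unit)^n, 1-based inclusive span."""

    unit: str
    begin: int
    end: int
    copies: float
    span: int


def _smallest_rotation(s: str) -> str:
    return min(s[i:] + s[:i] for i in range(len(s)))


def _is_primitive(unit: str) -> bool:
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return False
    return True


def find_tandem_repeats(seq: str, min_unit: int = 1, max_unit: int = 6,
                        min_copies: float = 3.0, min_span: int = 12) -> list[RepeatRun]:
    """All maximal exact tandem runs meeting the thresholds.

    The reported unit is the unit as it appears at the start of the run;
    overlapping runs with different (primitive) units are all reported.
    """
    n = len(seq)
    runs: list[RepeatRun] = []
    seen: set[tuple[int, int, str]] = set()
    for u in range(min_unit, max_unit + 1):
        i = 0
        while i + u <= n:
            unit = seq[i:i + u]
            if not _is_primitive(unit):
                i += 1
                continue
            # extend the run of period u starting at i
            j = i + u
            while j < n and seq[j] == seq[j - u]:
                j += 1
            span = j - i
            copies = span / u
            if copies >= min_copies and span >= min_span:
                # maximality to the left is guaranteed by scan order only if
                # the previous position does not extend the period
                if i == 0 or seq[i - 1] != seq[i - 1 + u]:
                    key = (i, j, _smallest_rotation(unit))
                    if key not in seen:
                        seen.add(key)
                        runs.append(RepeatRun(unit, i + 1, j, copies, span))
                i = j - u + 1
            else:
                i += 1
    runs.sort(key=lambda r: (r.begin, r.end, r.unit))
    return runs


@dataclass
class ScreenReport:
    """Per-candidate statistics, criterion flags and the overall verdict."""

    candidate_id: str
    est_id: str
    family: str
    strand: str
    mature_start: int
    mature_end: int
    arm: str
    length: int
    mfe: float
    amfe: float
    mfei: float
    gc_percent: float
    starts_with_u: bool
    high_confidence: bool
    criteria: dict[str, bool]
    verdict: bool
    repeat_annotations: list[RepeatRun] = field(default_factory=list)


def is_high_confidence(mfei_value: float, config: RunConfig) -> bool:
    """MFEI at or below -0.85 is strongly indicative of a genuine pre-miRNA."""
    return mfei_value <= config.mfei_high_confidence + EPS


def threshold_criteria(mfe: float, mfei_value: float, gc: float, length: int,
                       config: RunConfig) -> dict[str, bool]:
    """The thermodynamic/compositional criteria on precomputed statistics."""
    return {
        "mfe": mfe <= config.mfe_cutoff + EPS,
        "mfei": mfei_value <= config.mfei_cutoff + EPS,
        "gc": (config.gc_min - EPS <= gc <= config.gc_max + EPS) and gc > 0,
        "length": config.precursor_min <= length <= config.precursor_max,
    }


def structural_criteria(features: folding.HairpinFeatures, config: RunConfig) -> dict[str, bool]:
    return {
        "arm": features.arm in ("5p", "3p"),
        "mature_contiguity": features.largest_mature_break <= config.max_mature_break,
        "duplex_mismatches": features.duplex_mismatches <= config.duplex_max_mismatches,
    }


def screen(candidate: PrecursorCandidate, config: RunConfig) -> ScreenReport:
    """Evaluate every criterion on a folded candidate."""
    seq = candidate.precursor_seq
    length = len(seq)
    mfe = candidate.structure.mfe
    gc = gc_percent(seq)
    amfe_v = amfe(mfe, length)
    mfei_v = mfei(mfe, length, gc)
    criteria = structural_criteria(candidate.features, config)
    criteria.update(threshold_criteria(mfe, mfei_v, gc, length, config))
    criteria = {k: criteria[k] for k in CRITERIA_ORDER}
    mature = seq[candidate.mature_offset:candidate.mature_offset + candidate.mature_len]
    hit = candidate.hit
    return ScreenReport(
        candidate_id=candidate.candidate_id,
        est_id=hit.est_id,
        family=family_of(hit.query_id),
        strand=hit.strand,
        mature_start=hit.est_start,
        mature_end=hit.est_end,
        arm=candidate.arm,
        length=length,
        mfe=mfe,
        amfe=amfe_v,
        mfei=mfei_v,
        gc_percent=gc,
        starts_with_u=mature.startswith("U"),
        high_confidence=is_high_confidence(mfei_v, config),
        criteria=criteria,
        verdict=all(criteria.values()),
        repeat_annotations=find_tandem_repeats(seq),
    )


def excise_candidates(hit: HomologyHit, est: SequenceRecord,
                      config: RunConfig) -> list[PrecursorCandidate]:
    """Candidate windows anchored on a mature hit; best-MFEI valid one kept.

    For each ladder length two placements are tried: mature near the 5' end
    of the window (10-nt leader) and near the 3' end (10-nt trailer), in
    hit orientation.  A window is structurally valid when the mature maps
    onto one arm, is contiguous enough and pairs the star within the
    mismatch budget.  Ties on MFEI go to the shorter window.
    """
    n = len(est.residues)
    mat_lo, mat_hi = hit.est_start - 1, hit.est_end  # 0-based half-open, plus strand
    lengths = sorted({
        min(max(L, config.precursor_min), config.precursor_max)
        for L in WINDOW_LADDER
        if config.precursor_min <= min(L, config.precursor_max)
    })
    best: tuple[float, int, PrecursorCandidate] | None = None
    tried: set[tuple[int, int]] = set()
    for L in lengths:
        if L < (mat_hi - mat_lo) + WINDOW_MARGIN:
            continue
        placements = []
        if hit.strand == "+":
            placements = [mat_lo - WINDOW_MARGIN, mat_hi + WINDOW_MARGIN - L]
        else:  # margin in hit orientation mirrors on the plus strand
            placements = [mat_hi + WINDOW_MARGIN - L, mat_lo - WINDOW_MARGIN]
        for w_start in placements:
            w_start = max(0, min(w_start, n - L))
            w_end = w_start + L
            if w_end > n:
                continue
            if not (w_start <= mat_lo and mat_hi <= w_end):
                continue
            if (w_start, w_end) in tried:
                continue
            tried.add((w_start, w_end))
            window_seq = est.residues[w_start:w_end]
            if hit.strand == "+":
                oriented = window_seq
                offset = mat_lo - w_start
            else:
                oriented = reverse_complement(window_seq)
                offset = w_end - mat_hi
            mature_len = mat_hi - mat_lo
            structure = folding.fold(oriented, config.max_loop_size)
            features = folding.extract_hairpin(structure, (offset, offset + mature_len))
            if not all(structural_criteria(features, config).values()):
                continue
            if not (config.precursor_min <= L <= config.precursor_max):
                continue
            mfei_v = mfei(structure.mfe, L, gc_percent(oriented))
            cand = PrecursorCandidate(
                candidate_id=f"{hit.est_id}:{hit.strand}{hit.est_start}:{hit.query_id}",
                hit=hit,
                window_start=w_start,
                window_end=w_end,
                precursor_seq=oriented,
                structure=structure,
                mature_offset=offset,
                mature_len=mature_len,
                arm=features.arm,
                features=features,
            )
            key = (mfei_v, L)
            if best is None or key < (best[0], best[1]):
                best = (mfei_v, L, cand)
    return [best[2]] if best else []
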