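"""Synthetic EST collections with planted pre-miRNA hairpins.

The generator emulates the statistical structure the pipeline assumes:
background ESTs are i.i.d. residues at a target GC content (default 40 %,
the genome-wide average of the crucifer the method was developed on),
planted precursors are mutated known matures folded back on a
near-reverse-complement star with a 2-nt 3' overhang, protein-coding
decoys carry a long open reading frame, repeat decoys carry a tandem run.
Every planted item is listed in a truth table so recall and precision are
computable without re-inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import SequenceRecord, ValidationError, family_of, reverse_complement

RNA = "ACGU"
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
# bases that neither Watson-Crick nor wobble pair with the key
_NON_PAIRING = {
    "A": ("A", "C", "G"),
    "C": ("A", "C", "U"),
    "G": ("A", "G"),
    "U": ("C", "U"),
}

DEFAULT_BACKGROUND_GC = 40.0
DEFAULT_EST_LENGTH = (200, 800)


@dataclass(frozen=True)
class PlantSpec:
    """How one precursor is planted into the EST collection."""

    query_id: str
    n_mutations: int = 0
    arm: str = "5p"
    loop_len: int = 8
    duplex_mismatches: int = 0
    overhang: int = 2
    flank_len_5: int = 60
    flank_len_3: int = 60
    target_gc: float = DEFAULT_BACKGROUND_GC
    strand: str = "+"

    def validate(self, mature_len: int, precursor_min: int = 50,
                 precursor_max: int = 350, max_mismatches: int = 4) -> None:
        if not 0 <= self.n_mutations <= max_mismatches:
            raise ValidationError("n_mutations outside the homology budget")
        if not 0 <= self.duplex_mismatches <= 6:
            raise ValidationError("duplex_mismatches outside 0..6")
        if self.loop_len < 3:
            raise ValidationError("loop_len must be >= 3")
        if self.arm not in ("5p", "3p"):
            raise ValidationError("arm must be 5p or 3p")
        core = 2 * mature_len + self.loop_len + self.overhang
        if not precursor_min <= core <= precursor_max:
            raise ValidationError(f"planted core length {core} outside precursor bounds")


@dataclass(frozen=True)
class PlantedPrecursor:
    """Truth annotation for one planted hairpin (coords 0-based, half-open)."""

    query_id: str
    family: str
    core_seq: str
    mature_seq: str
    mature_start: int  # within core
    mature_end: int
    arm: str
    n_mutations: int
    duplex_mismatches: int


@dataclass(frozen=True)
class TruthEntry:
    """One planted item in the EST collection."""

    est_id: str
    kind: str  # precursor | coding | repeat
    strand: str = "+"
    mature_start: int = -1  # 0-based half-open on the EST plus strand
    mature_end: int = -1
    query_id: str = ""
    family: str = ""
    plant: PlantedPrecursor | None = None


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    g = gc / 200.0
    a = (100.0 - gc) / 200.0
    return "".join(rng.choice(list(RNA), size=length, p=[a, g, g, a]))


def _mutate(rng: np.random.Generator, seq: str, n: int) -> str:
    positions = rng.choice(len(seq), size=n, replace=False) if n else []
    out = list(seq)
    for p in sorted(int(x) for x in positions):
        alternatives = [b for b in RNA if b != out[p]]
        out[p] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(out)


def make_precursor(mature: SequenceRecord, spec: PlantSpec,
                   rng_seed: int) -> tuple[SequenceRecord, PlantedPrecursor]:
    """Build a hairpin precursor around a (mutated) mature sequence.

    5p arm: mutated-mature + loop + star + 2-nt overhang; 3p arm mirrored
    (star + loop + mature + overhang).  The star is the reverse complement
    of the planted mature with ``duplex_mismatches`` non-pairing positions,
    planted away from the duplex ends so the stem stays recognizable.
    """
    m = len(mature.residues)
    if not 18 <= m <= 26:
        raise ValidationError("mature length must be 18-26 nt")
    spec.validate(m)
    rng = np.random.default_rng(rng_seed)
    planted_mature = _mutate(rng, mature.residues, spec.n_mutations)
    star = list(reverse_complement(planted_mature))
    if spec.duplex_mismatches:
        # mature indices eligible for a planted duplex mismatch: keep the
        # outermost two positions of both duplex ends intact
        eligible = list(range(2, m - 2))
        chosen = rng.choice(eligible, size=spec.duplex_mismatches, replace=False)
        for mat_idx in sorted(int(x) for x in chosen):
            star_idx = m - 1 - mat_idx
            options = _NON_PAIRING[planted_mature[mat_idx]]
            star[star_idx] = options[int(rng.integers(len(options)))]
    star_seq = "".join(star)
    # loop and overhang are drawn from {A, C}: those bases cannot pair with
    # each other, so the terminal loop cannot seed a competing register and
    # the planted duplex is the unambiguous optimum of the fold
    loop = "".join(rng.choice(["A", "C"], size=spec.loop_len,
                              p=[0.6, 0.4]))
    overhang = "".join(rng.choice(["A", "C"], size=spec.overhang))
    if spec.arm == "5p":
        core = planted_mature + loop + star_seq + overhang
        mat_start = 0
    else:
        core = star_seq + loop + planted_mature + overhang
        mat_start = m + spec.loop_len
    truth = PlantedPrecursor(
        query_id=mature.id,
        family=family_of(mature.id),
        core_seq=core,
        mature_seq=planted_mature,
        mature_start=mat_start,
        mature_end=mat_start + m,
        arm=spec.arm,
        n_mutations=spec.n_mutations,
        duplex_mismatches=spec.duplex_mismatches,
    )
    rec = SequenceRecord(
        id=f"pre-{mature.id}-{rng_seed}",
        description=f"synthetic precursor ({spec.arm} arm)",
        residues=core,
    )
    return rec, truth


def _coding_decoy(rng: np.random.Generator, gc: float) -> str:
    """A transcript fragment with an ORF of at least 100 codons."""
    n_codons = int(rng.integers(100, 161))
    codons = ["AUG"]
    while len(codons) < n_codons:
        c = _random_seq(rng, 3, gc)
        if c not in ("UAA", "UAG", "UGA"):
            codons.append(c)
    codons.append("UAA")
    utr5 = _random_seq(rng, int(rng.integers(20, 60)), gc)
    utr3 = _random_seq(rng, int(rng.integers(20, 60)), gc)
    # keep the 5' UTR frame free of upstream edge-open ORF interference is
    # not required: the decoy only needs *an* ORF >= 100 codons
    return utr5 + "".join(codons) + utr3


def _repeat_decoy(rng: np.random.Generator, gc: float) -> str:
    unit_len = int(rng.integers(2, 5))
    unit = _random_seq(rng, unit_len, gc)
    copies = max(3, int(np.ceil(24 / unit_len)) + int(rng.integers(0, 6)))
    left = _random_seq(rng, int(rng.integers(80, 200)), gc)
    right = _random_seq(rng, int(rng.integers(80, 200)), gc)
    return left + unit * copies + right


def make_est_collection(
    n_background: int,
    plants: list[PlantSpec],
    n_coding_decoys: int,
    n_repeat_decoys: int,
    rng_seed: int,
    queries: list[SequenceRecord],
    background_gc: float = DEFAULT_BACKGROUND_GC,
    est_length: tuple[int, int] = DEFAULT_EST_LENGTH,
) -> tuple[list[SequenceRecord], list[TruthEntry]]:
    """An EST collection with planted precursors, decoys and background.

    Deterministic for a given seed.  Planted precursors are embedded at
    recorded offsets on recorded strands; the truth table lists every
    planted item.
    """
    if min(n_background, n_coding_decoys, n_repeat_decoys) < 0:
        raise ValidationError("counts must be non-negative")
    rng = np.random.default_rng(rng_seed)
    query_by_id = {q.id: q for q in queries}
    ests: list[SequenceRecord] = []
    truth: list[TruthEntry] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"EST{counter:06d}"

    for spec in plants:
        if spec.query_id not in query_by_id:
            raise ValidationError(f"plant references unknown query {spec.query_id!r}")
        _, planted = make_precursor(
            query_by_id[spec.query_id], spec, int(rng.integers(2**31))
        )
        flank5 = _random_seq(rng, spec.flank_len_5, spec.target_gc)
        flank3 = _random_seq(rng, spec.flank_len_3, spec.target_gc)
        insert = flank5 + planted.core_seq + flank3
        mat_lo = len(flank5) + planted.mature_start
        mat_hi = len(flank5) + planted.mature_end
        if spec.strand == "-":
            n = len(insert)
            insert = reverse_complement(insert)
            mat_lo, mat_hi = n - mat_hi, n - mat_lo
        est_id = next_id()
        ests.append(SequenceRecord(est_id, "synthetic planted precursor", insert))
        truth.append(TruthEntry(
            est_id=est_id, kind="precursor", strand=spec.strand,
            mature_start=mat_lo, mature_end=mat_hi,
            query_id=spec.query_id, family=family_of(spec.query_id),
            plant=planted,
        ))
    for _ in range(n_coding_decoys):
        est_id = next_id()
        ests.append(SequenceRecord(est_id, "synthetic coding decoy",
                                   _coding_decoy(rng, background_gc)))
        truth.append(TruthEntry(est_id=est_id, kind="coding"))
    for _ in range(n_repeat_decoys):
        est_id = next_id()
        ests.append(SequenceRecord(est_id, "synthetic repeat decoy",
                                   _repeat_decoy(rng, background_gc)))
        truth.append(TruthEntry(est_id=est_id, kind="repeat"))
    for _ in range(n_background):
        est_id = next_id()
        length = int(rng.integers(est_length[0], est_length[1] + 1))
        ests.append(SequenceRecord(est_id, "synthetic background EST",
                                   _random_seq(rng, length, background_gc)))
    return ests, truth


# --- target transcripts -----------------------------------------------------

#: penalties of the complementarity scheme (kept in sync with targets module)
PENALTY_GU = 0.5
PENALTY_MISMATCH = 1.0
PENALTY_GAP = 2.0
SEED_START = 2
SEED_END = 13


@dataclass(frozen=True)
class TruthSite:
    transcript_id: str
    site_start: int  # 1-based inclusive on the transcript
    site_end: int
    expectation: float
    mode: str  # cleavage | translation
    mirna_positions: tuple[int, ...]  # 1-based positions carrying a change


def make_target_transcripts(
    mature: SequenceRecord,
    site_specs: list[tuple[int, int, int, bool]],
    rng_seed: int,
    transcript_len: int = 400,
    background_gc: float = DEFAULT_BACKGROUND_GC,
) -> tuple[list[SequenceRecord], list[TruthSite]]:
    """Transcripts each carrying one planted complementary site.

    ``site_specs`` entries are (mismatches, gu_pairs, gaps, in_seed); the
    planted modifications are placed inside the seed (miRNA positions
    2-13) when ``in_seed`` is set and strictly outside it otherwise, and
    the truth expectation is computed from the penalty scheme (seed
    penalties doubled).
    """
    m = len(mature.residues)
    if not 18 <= m <= 26:
        raise ValidationError("mature length must be 18-26 nt")
    rng = np.random.default_rng(rng_seed)
    records: list[SequenceRecord] = []
    truths: list[TruthSite] = []
    for idx, (n_mm, n_gu, n_gaps, in_seed) in enumerate(site_specs, start=1):
        # perfect site: reverse complement of the mature; column k of the
        # duplex places miRNA position k+1 against site position (from the
        # site's 3' end) k+1, i.e. transcript offset m-1-k within the site.
        site = list(reverse_complement(mature.residues))
        seed_range = range(SEED_START, SEED_END + 1)
        if in_seed:
            allowed = [p for p in seed_range if p <= m]
        else:
            allowed = [p for p in range(1, m + 1) if p not in seed_range]
        gu_eligible = [p for p in allowed if mature.residues[p - 1] in "GU"]
        chosen_gu = [int(x) for x in rng.choice(gu_eligible, size=n_gu, replace=False)] if n_gu else []
        rest = [p for p in allowed if p not in chosen_gu]
        chosen_mm = [int(x) for x in rng.choice(rest, size=n_mm, replace=False)] if n_mm else []
        rest = [p for p in rest if p not in chosen_mm and 1 < p < m]
        chosen_gap = [int(x) for x in rng.choice(rest, size=n_gaps, replace=False)] if n_gaps else []
        expectation = 0.0
        for p in chosen_gu:
            base = mature.residues[p - 1]
            site[m - p] = "U" if base == "G" else "G"
            expectation += PENALTY_GU * (2 if p in seed_range else 1)
        for p in chosen_mm:
            base = mature.residues[p - 1]
            site[m - p] = _NON_PAIRING[base][
                int(rng.integers(len(_NON_PAIRING[base])))]
            expectation += PENALTY_MISMATCH * (2 if p in seed_range else 1)
        for p in sorted(chosen_gap, reverse=True):
            del site[m - p]  # target-side deletion: miRNA base p faces a gap
            expectation += PENALTY_GAP * (2 if p in seed_range else 1)
        site_seq = "".join(site)
        flank_total = transcript_len - len(site_seq)
        left_len = int(rng.integers(flank_total // 4, 3 * flank_total // 4))
        left = _random_seq(rng, left_len, background_gc)
        right = _random_seq(rng, flank_total - left_len, background_gc)
        transcript = left + site_seq + right
        changed = tuple(sorted(chosen_gu + chosen_mm + chosen_gap))
        mode = "translation" if any(p in (10, 11) for p in changed) else "cleavage"
        tid = f"TX{idx:04d}"
        records.append(SequenceRecord(tid, "synthetic target transcript", transcript))
        truths.append(TruthSite(
            transcript_id=tid,
            site_start=left_len + 1,
            site_end=left_len + len(site_seq),
            expectation=expectation,
            mode=mode,
            mirna_positions=changed,
        ))
    return records, truths


# --- canned benchmark -------------------------------------------------------

def random_mature(rng: np.random.Generator, length: int | None = None,
                  gc: float = DEFAULT_BACKGROUND_GC) -> str:
    if length is None:
        length = int(rng.integers(20, 23))
    return _random_seq(rng, length, gc)


def planted_est_is_compliant(est: SequenceRecord, truth: TruthEntry,
                             config=None) -> bool:
    """Excise and screen a planted EST in isolation: does it pass?"""
    from .homology import HomologyHit
    from .io_formats import RunConfig
    from .screen import excise_candidates, screen

    config = config or RunConfig()
    hit = HomologyHit(truth.query_id, est.id, truth.strand,
                      truth.mature_start + 1, truth.mature_end, 0, "")
    candidates = excise_candidates(hit, est, config)
    return bool(candidates) and screen(candidates[0], config).verdict


def benchmark_collection(
    rng_seed: int,
    n_plants: int = 30,
    n_background: int = 100,
    n_coding_decoys: int = 10,
    n_repeat_decoys: int = 5,
    background_gc: float = DEFAULT_BACKGROUND_GC,
    max_tries_per_plant: int = 40,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[TruthEntry], list[PlantSpec]]:
    """The default planted-recovery benchmark.

    Thirty screen-compliant precursors (mutated matures of thirty synthetic
    "known" queries, 0-4 substitutions, 0-3 duplex mismatches, loops of
    8-16 nt, both arms and strands) hidden among one hundred background
    ESTs at 40 % GC, ten protein-coding decoys and five tandem-repeat
    decoys.  Each plant is rejection-sampled until its EST, excised and
    screened in isolation, passes every criterion: the planted set is
    compliant by construction, so recall measures the pipeline's recovery
    machinery rather than the thermodynamic lottery of a particular draw.
    Returns (queries, ests, truth, plant specs).
    """
    from dataclasses import replace as _replace

    rng = np.random.default_rng(rng_seed)
    queries: list[SequenceRecord] = []
    specs: list[PlantSpec] = []
    ests: list[SequenceRecord] = []
    truth: list[TruthEntry] = []
    for k in range(n_plants):
        qid = f"syn-miR{9000 + k}"
        accepted = None
        for _attempt in range(max_tries_per_plant):
            query = SequenceRecord(qid, "synthetic known mature",
                                   random_mature(rng))
            spec = PlantSpec(
                query_id=qid,
                n_mutations=int(rng.integers(0, 5)),
                arm="5p" if rng.integers(2) == 0 else "3p",
                loop_len=int(rng.integers(8, 17)),
                duplex_mismatches=int(rng.integers(0, 4)),
                flank_len_5=int(rng.integers(30, 121)),
                flank_len_3=int(rng.integers(30, 121)),
                target_gc=background_gc,
                strand="+" if rng.integers(2) == 0 else "-",
            )
            (est,), (entry,) = make_est_collection(
                0, [spec], 0, 0, int(rng.integers(2**31)), [query],
                background_gc=background_gc)
            if planted_est_is_compliant(est, entry):
                accepted = (query, spec, est, entry)
                break
        if accepted is None:
            raise ValidationError(
                f"could not draw a compliant plant for {qid} in "
                f"{max_tries_per_plant} tries")
        query, spec, est, entry = accepted
        est_id = f"EST{len(ests) + 1:06d}"
        queries.append(query)
        specs.append(spec)
        ests.append(SequenceRecord(est_id, est.description, est.residues))
        truth.append(_replace(entry, est_id=est_id))
    decoy_ests, decoy_truth = make_est_collection(
        n_background=n_background,
        plants=[],
        n_coding_decoys=n_coding_decoys,
        n_repeat_decoys=n_repeat_decoys,
        rng_seed=int(rng.integers(2**31)),
        queries=[],
        background_gc=background_gc,
    )
    offset = len(ests)
    id_map = {e.id: f"EST{offset + i + 1:06d}" for i, e in enumerate(decoy_ests)}
    ests += [SequenceRecord(id_map[e.id], e.description, e.residues)
             for e in decoy_ests]
    truth += [_replace(t, est_id=id_map[t.est_id]) for t in decoy_truth]
    return queries, ests, truth, specs
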