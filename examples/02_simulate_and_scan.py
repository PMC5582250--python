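"""Generate a small synthetic EST collection and run the homology scan.

Planted precursors carry a known mature with up to 4 substitutions, so
every plant is found by the exact Hamming scan at the 4-mismatch budget;
background ESTs almost never match.
"""

from mirhunt.homology import dereplicate_queries, queries_from_records, scan
from mirhunt.synthetic import benchmark_collection

queries, ests, truth, specs = benchmark_collection(
    7, n_plants=5, n_background=20, n_coding_decoys=2, n_repeat_decoys=1)

unique = dereplicate_queries(queries_from_records(queries))
hits = scan(unique, ests, max_mismatches=4)
print(f"{len(unique)} unique queries vs {len(ests)} ESTs "
      f"-> {len(hits)} hits at <=4 mismatches")
for h in hits:
    print(f"  {h.query_id} ~ {h.est_id} [{h.strand}] {h.est_start}-{h.est_end} "
          f"({h.mismatches} mismatches)")
planted = {t.est_id for t in truth if t.kind == "precursor"}
found = {h.est_id for h in hits}
print(f"planted ESTs recovered by the scan: {len(planted & found)}/{len(planted)}")
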