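"""Score miRNA-target duplexes with the expectation-penalty scheme.

Watson-Crick pairs cost 0, G:U wobbles 0.5, mismatches 1, gaps 2; every
penalty doubles in the seed (miRNA positions 2-13).  A non-paired column
at positions 10-11 switches the repression call from mRNA cleavage to
translation inhibition.
"""

from mirhunt.io_formats import SequenceRecord
from mirhunt.synthetic import make_target_transcripts
from mirhunt.targets import find_sites

mirna = SequenceRecord("bra-miR-demo", "", "UGACAGAAGAGAGUGAGCACA")
site_specs = [
    (0, 0, 0, False),  # perfect complement            -> expectation 0.0
    (0, 1, 0, False),  # one wobble outside the seed   -> 0.5
    (1, 1, 0, False),  # mismatch + wobble outside     -> 1.5
    (1, 0, 0, True),   # one mismatch inside the seed  -> 2.0 (doubled)
]
transcripts, truths = make_target_transcripts(mirna, site_specs, rng_seed=4)

for tx, truth in zip(transcripts, truths):
    (site,) = [s for s in find_sites(mirna, [tx], max_expectation=3.0)
               if s.site_start == truth.site_start]
    print(f"planted expectation {truth.expectation:3.1f} -> "
          f"found {site.expectation:3.1f}, mode {site.mode}")
    print(site.pretty())
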