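# mirhunt

Homology-based discovery of conserved plant microRNAs in EST collections.

Plant mature miRNAs are strongly conserved — orthologs typically differ by
no more than 4 nucleotide substitutions — so new family members can be
found by searching expressed sequence tags (ESTs) for near-matches of
known matures and then asking whether the surrounding sequence folds into
a genuine pre-miRNA hairpin. `mirhunt` implements that workflow end to
end as a tested Python library plus a thin CLI:

1. **Homology scan** — exact Hamming search of every EST window, both
   strands, within a mismatch budget (default 4).
2. **Redundancy collapse** — clone overlaps and resubmitted accessions are
   clustered by flanking-region alignment identity (default 95 %) and
   reduced to one representative locus.
3. **Coding filter** — ESTs whose longest six-frame ORF reaches 80 aa are
   treated as protein coding and removed (ESTs are fragments, so ORFs may
   open at a sequence edge).
4. **Folding** — candidate precursor windows are excised around each hit
   and folded with a nearest-neighbor minimum-free-energy dynamic program
   (37 °C parameters, interior/bulge loops capped at 30 nt, no
   pseudoknots).
5. **Screening** — candidates pass when the mature maps onto one hairpin
   arm without large breaks, pairs the star arm within 6 mismatches, and
   the statistics satisfy MFE ≤ −15 kcal·mol⁻¹, MFEI ≤ −0.7,
   20 % ≤ GC ≤ 70 % and 50–350 nt, where

       AMFE = (MFE / length) × 100        MFEI = AMFE / GC%

   MFEI ≤ −0.85 is flagged as high confidence. Simple tandem repeats
   (transposon-like content) and a 5′ uracil at the mature start are
   annotated but never filtered on.
6. **Targets** — mature candidates are scored against transcripts with an
   expectation penalty (WC 0, G:U 0.5, mismatch 1, gap 2; doubled in the
   seed, miRNA positions 2–13; cutoff 3.0). A non-WC column at positions
   10–11 calls translation inhibition instead of cleavage.
7. **Phylogenetics** — family members are related by neighbor joining on
   1 − identity distances from global pairwise alignments.

Because real dbEST/miRBase downloads are out of scope, the package ships a
first-class synthetic-data generator that plants screen-compliant hairpins
(mutated matures folded back on a near-complementary star with a 2-nt 3′
overhang), protein-coding decoys, tandem-repeat decoys and 40 %-GC
background ESTs, together with a complete truth table, so recall and
precision of the whole pipeline are measurable.

## Worked example

```
$ python examples/03_full_pipeline.py
filter chain: 56 hits -> 30 unique loci -> 30 non-coding -> 30 pass
families: 30   mature sequences starting with U: 11
passing-set MFE  -48.8 .. -19.7 (mean -30.92) kcal/mol
passing-set MFEI -1.354 .. -0.703 (mean -0.962)
recall 1.000  precision 1.000 against the planted truth (1.0 = perfect recovery)
```

All 30 planted hairpins are re-discovered and nothing else passes: the
counts shrink monotonically along the filter chain, the passing set's
energies sit in the range typical of real plant pre-miRNAs, and recall and
precision are computed against the generator's truth table. The other
examples (`examples/01…05`) demonstrate folding statistics, the homology
scan, target prediction with printed duplex alignments, and family trees.

The same workflow is available from the shell:

```
mirhunt simulate --seed 17 --outdir sim/
mirhunt run --queries sim/queries.fasta --ests sim/ests.fasta --outdir out/ --seed 17
```

`out/` then contains every intermediate artifact (hit tables, dot-bracket
structures, the per-criterion screen report, Newick trees, a JSON summary)
and a log with per-criterion rejection tallies. Reruns with the same seed
and config are byte-identical.

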