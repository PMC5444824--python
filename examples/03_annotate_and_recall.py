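"""Annotate called positions against genes and score recall of known sites.

Uses a tiny hand-made annotation to show the strand-aware distance
conventions, then scores recall of a known-site list with the same-strand
+/- 5 nt rule used for transcription start sites.
"""

import enrichfit as ef

genes = [
    ef.GeneRecord("sim1", 1000, 2000, "+", "geneA"),
    ef.GeneRecord("sim1", 2500, 3200, "-", "geneB"),
]
calls = [
    ef.GenomicPosition("sim1", 950, "+"),    # 50 nt upstream of geneA's start
    ef.GenomicPosition("sim1", 1500, "+"),   # inside geneA
    ef.GenomicPosition("sim1", 3250, "-"),   # 50 nt upstream of geneB's 5' end
]
print(ef.annotate_positions(calls, genes).to_string(index=False))
# On the minus strand a gene's END coordinate is its 5' boundary, so the
# call at 3250 is 50 nt upstream of geneB in transcription direction.

known = [ef.GenomicPosition("sim1", 953, "+"),   # 3 nt from a call: detected
         ef.GenomicPosition("sim1", 1600, "+")]  # 100 nt away: missed
records = {ef.GenomicPosition("sim1", p, "+") for p in range(900, 1700)}
res = ef.recall_known_tss({c for c in calls if c.strand == "+"},
                          known, records, window=5)
print(f"\nrecall: {res.n_detected}/{res.n_evaluable} evaluable known sites "
      f"= {res.recall_percent:.1f}% (of {res.n_known} known)")
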