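"""The composite LGT screen on a panel with a known transfer event.

Six AT-leaning recipient strains carry a utp copy implanted with a +10-point
GC offset, alien codon usage and donor-clade placement in the gene tree; six
GC-rich donors carry it natively.  The screen should call LGT_candidate for
the recipients and vertical for the donors.
"""

from nitriscan.lgt import lgt_verdicts, verdicts_table
from nitriscan.simulate import make_lgt_panel

profiles, trees, groups, truths = make_lgt_panel(seed=5, transfer=True)
verdicts = lgt_verdicts(profiles, trees, groups)
print(verdicts_table(verdicts).to_string(index=False))
print("\nRecipient row: significant gene-vs-genome GC deviation (gc_p < 0.05,"
      "\ngene_higher) plus a gene tree that nests recipients among donors"
      "\n(phylo_flag incongruent) -> LGT_candidate.  Donor row: native"
      "\ncomposition, no signal -> vertical.")
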