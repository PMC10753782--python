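"""Background amino-acid frequencies for synthetic proteins.

The LG model's equilibrium frequencies double as a realistic average
proteome composition for background ORFs.
"""

from .phylo._lg import AA_ORDER, LG_FREQS

AA_BACKGROUND_FREQS: dict[str, float] = dict(zip(AA_ORDER, LG_FREQS))
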