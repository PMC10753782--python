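"""SA/V morphometrics and the copy-number correlation.

Builds strain metadata whose cell sizes encode a positive association
between dur3 copy number and surface-to-volume ratio, then recovers it with
Spearman rank correlation — the analysis used to argue that small,
high-SA/V cells favor extra urea-transporter copies.
"""

from nitriscan.morphometrics import sav, sav_table
from nitriscan.simulate import make_sav_panel
from nitriscan.stats import spearman

print("sphere d=1.0 um -> SA/V =", sav("sphere", 1.0), "per um")
print("rod d=0.5, h=2.0 um -> SA/V =", sav("rod", 0.5, 2.0), "per um")

copies, metadata = make_sav_panel(seed=2, n_strains=12)
table = sav_table(metadata)
table["dur3_copies"] = copies
print("\n", table.to_string(index=False))

res = spearman(copies, table["sav_per_um"].tolist())
print(f"\nSpearman rho = {res.statistic:.3f}, p = {res.p_value:.4f} "
      f"(construction encodes a positive rank correlation; "
      f"noise keeps |rho| below 1).")
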