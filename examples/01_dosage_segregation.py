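"""Segregation arithmetic for an autooctoploid cross.

Prints the per-dose segregation table: the probability a gamete misses a
dose-d allele, the presence:absence odds in the F1, and the merged read
depth needed to discover the pooled allele at 95%/99% certainty.  A
simplex (dose 1) allele segregates 1:1 and its pooled 1/16 read fraction
needs 72 merged reads for 99% discovery.
"""

from octomap import dosage

table = dosage.segregation_table(ploidy=8)
print(table.to_string(index=False))
print()
print("pooled simplex minor fraction:", dosage.pooled_minor_fraction(1, 0, 8),
      f"(odds 1:{dosage.pooled_minor_odds(1, 0, 8):g})")
print("min merged depth for 99% discovery:", dosage.min_depth(1 / 16, 0.99))
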