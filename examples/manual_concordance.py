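"""Validate automated scoring against manual observation.

Emulates the standard validation step for an automated behavior scorer:
a human rater's bout counts for a handful of animals are compared with the
system's counts via Pearson correlation (association) and a paired t-test
(systematic bias).
"""

from norkit import concordance

# per-animal novel-object bout counts: human rater vs automated system
manual = [12, 18, 9, 15, 21, 11]
system = [13, 17, 9, 16, 20, 12]

result = concordance(manual, system, metric="NT2_freq_novel")
print(f"Pearson r      = {result.pearson_r:.3f} (p = {result.pearson_p:.4f})")
print(f"paired-t p     = {result.paired_t_p:.3f}")
print()
print("r near 1 means the system ranks animals like the human does; a")
print("non-significant paired t-test means there is no systematic offset")
print("between the two scoring methods.")
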