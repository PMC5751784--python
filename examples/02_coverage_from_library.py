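"""Deriving sequencing coverage from library arithmetic.

Coverage b = S/N needs the pre-sequencing fragment population N, which
can be reconstructed three ways: from the post-PCR yield and the cycle
count, from the loading concentration via Avogadro's number, or taken as
the 300 M standard. Imperfect PCR shrinks the real population, which
inflates the effective coverage.
"""

from cornas import (
    adjusted_coverage,
    coverage_from_reads,
    fragments_from_concentration,
    pcr_retention,
    prepcr_fragments,
)

# A standard library: 40 uL of 200 nM post-PCR cDNA ~= 4.818e12 fragments,
# amplified over 14 cycles.
N = prepcr_fragments(4.818e12, cycles=14)
print(f"pre-PCR fragment population : {N:.4g} (~300 M)")

S = 75_000_000
print(f"coverage for {S/1e6:.0f} M reads     : {coverage_from_reads(S, N):.3f}")

# Loading-concentration route (e.g. a 3 pM loading in the standard 120 uL):
N_conc = fragments_from_concentration(3.0, 120.0)
print(f"population from 3 pM loading: {N_conc:.4g} fragments")

# If amplification ran at 95% per-cycle efficiency, only ~70% of the
# nominal population was really there, so the same reads dig deeper:
print(f"retention at 95% efficiency : {pcr_retention(0.95, 14):.3f}")
b_adj = adjusted_coverage(S, 300e6, efficiency=0.95, cycles=14)
print(f"adjusted coverage           : {b_adj:.3f} (nominal 0.25 -> 0.36)")
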