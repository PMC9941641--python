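"""Analytic MR power for a binary outcome.

Computes the statistical power of a two-sample MR test in a case-control
cohort of 8021 cases / 16,489 controls for three instrument sets, given
the exposure variance each explains (r2) and the causal odds ratio to
detect.  Values near 1 mean the cohort was large enough that a true
effect of that size would almost surely reach significance.
"""

from protmr import mr_power_binary

N, CASES = 24_510, 8_021
K = CASES / N

print(f"discovery cohort: {CASES} cases / {N - CASES} controls (K={K:.3f})")
print(f"{'r2':>6} {'OR':>6} {'power':>6}")
for r2, or_alt in [(0.278, 0.890), (0.096, 0.814), (0.111, 0.822)]:
    power = mr_power_binary(r2, or_alt, N, K, alpha=0.05)
    print(f"{r2:>6.3f} {or_alt:>6.3f} {power:>6.2f}")
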