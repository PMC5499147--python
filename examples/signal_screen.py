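"""Screen candidate signal pairs for the oscillation-capable sign pattern.

Given pairwise sensitivity measurements between N candidate signals, a
pair can support undamped health oscillations when its self-sensitivity is
positive, its cross sensitivities have opposite signs, and its two
diagonal sensitivities share a sign.  The same criterion applies to
Jacobian blocks built from micro-level fragility parameters.
"""

import numpy as np

import autoimmsim as ai

planted = [(0, 3), (2, 1), (4, 2)]
m = ai.generate_screen_fixture(5, planted, noise_sd=0.05, seed=2024)
verdicts = ai.screen_pairs(m)

hits = [(v.p, v.q) for v in verdicts if v.passes]
print(f"planted oscillation-capable pairs: {sorted(planted)}")
print(f"screen hits:                       {sorted(hits)}")

print("\nwhy pair (0, 1) fails:")
v01 = next(v for v in verdicts if (v.p, v.q) == (0, 1))
for name, ok in v01.reasons.items():
    print(f"  {name}: {'pass' if ok else 'FAIL'}")

print("\nmicro-level check: identical fragility micro-parameters with an")
print("antisymmetric cross pair give the exact rotation form:")
rep = ai.micro_gradient_map(
    theta_2j=0.5, theta_2k=-0.8, theta_3j=0.8, theta_3k=0.5,
    eps_2j=0.2, eps_2k=0.2, eps_3j=0.2, eps_3k=0.2,
)
print(f"  block =\n{rep.block}")
print(f"  exact growth condition:    {rep.exact_growth_condition}")
print(f"  exact frequency condition: {rep.exact_frequency_condition}")
print(f"  regime:                    {rep.regime.value}")
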