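"""Walk the micro-level trigger cascade from extracellular trigger to
fragility-protein expression.

An extracellular trigger crosses a membrane port, a fraction of the induced
intracellular trigger binds a nuclear enzyme, and the resulting protein
shifts expression of a fragility-related surface protein.  Each stage is a
bounded tanh switch, so the composite response saturates; the fragility
increment itself grows super-linearly in the relative signal change.
"""

import numpy as np

import autoimmsim as ai

cfg = ai.PathwayConfig(
    r=0.6, s=0.5, e=0.4, g_p=0.5, g_e=0.2, g_Q=0.3,
    T0_base=1.0, T1_nominal=2.0, delta_Q=0.5, Q_max=10.0,
)

print("stage thresholds:")
print(f"  port half-max at [T0] = {cfg.T0_base}  ->  h_p = "
      f"{ai.port_activation(cfg.T0_base, cfg):.3f} (= r/2)")
x0 = cfg.r * cfg.T1_nominal / 2.0
print(f"  enzyme half-max at transported amount {x0}  ->  h_e = "
      f"{ai.enzyme_activation(x0, cfg):.3f} (= s/2)")
print(f"  expression floor at zero protein: "
      f"{ai.expression_change(0.0, cfg):.3f} (= e*dQ*Qmax/2)")

print("\ncomposite response (baseline-subtracted):")
for T0 in [0.0, 0.5, 1.0, 2.0, 5.0, 20.0]:
    dq = ai.compose_pathway(T0, cfg, subtract_baseline=True)
    print(f"  [T0] = {T0:5.1f}  ->  delta Q_max = {float(dq):.4f}")
print(f"  hard ceiling: e*delta_Q*Q_max = {cfg.e * cfg.delta_Q * cfg.Q_max}")

print("\nfragility is explosive in the relative increment eps:")
for eps in [0.1, 0.2, 0.4, 0.8]:
    print(f"  eps = {eps:.1f}  ->  delta_T/mu = {ai.fragility_delta(1.0, eps):.3f}")
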