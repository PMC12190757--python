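"""Benchmark reflection knockoffs against equicorrelated Model-X knockoffs.

Small power / realized-FDR comparison on an AR(1) design: both methods run
on identical replicates; true and false positives are pooled.
"""

from reko import SimulationConfig, run_benchmark

cfg = SimulationConfig(
    n=300, p=60, structure="ar1", rho=0.8,   # strong neighbor correlation
    n_causal=8, pve=0.5,
    q_grid=(0.1, 0.2), replicates=10, copies=3,
    methods=("reko", "modelx"), variant="knockoff_plus", seed=2024,
)
res = run_benchmark(cfg)
cols = ["method", "q", "power", "realized_fdr", "tp", "fp", "n_selected"]
print(res.table[cols].to_string(index=False))
print()
print("power = pooled true positives / pooled causal count;")
print("realized_fdr = pooled false positives / pooled selections —")
print("with the knockoff_plus rule it should stay at or below q up to "
      "Monte-Carlo noise; at high correlation the reflection construction "
      "typically keeps more power than equicorrelated Model-X")
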