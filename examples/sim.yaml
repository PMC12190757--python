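# Example config for `reko simulate --config examples/sim.yaml --out results/`
# Small benchmark: reflection knockoffs vs equicorrelated Model-X on an
# AR(1) design. Field names mirror reko.SimulationConfig.
n: 300
p: 60
structure: ar1
rho: 0.8
n_causal: 8
pve: 0.5
q_grid: [0.1, 0.2]
replicates: 10
copies: 3
methods: [reko, modelx]
variant: knockoff_plus
priors: eb
noise_mode: gaussian
seed: 2024
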