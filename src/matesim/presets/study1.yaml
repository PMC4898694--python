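# Full competitive model: seven algorithms, 50 agents per sex each.
n_agents: 700
pop_cap: 700
n_generations: 200
algorithm_roster:
  - [regression, 50]
  - [threshold_regression, 50]
  - [polynomial, 50]
  - [euclidean, 50]
  - [threshold_euclidean, 50]
  - [aspiration, 50]
  - [random, 50]
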