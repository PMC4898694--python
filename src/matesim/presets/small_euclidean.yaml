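# Single-algorithm model for couples-level analyses.
n_agents: 100
pop_cap: 200
n_generations: 200
algorithm_roster:
  - [euclidean, 50]
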