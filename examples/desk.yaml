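# Desk-scale run configuration: shrinks the island GA from the full-scale
# defaults (200 chromosomes x 400 generations) to a configuration that
# finishes in seconds on a laptop.
ga:
  population_size: 80
  n_islands: 4
  n_generations: 40
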