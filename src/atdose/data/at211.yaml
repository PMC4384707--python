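# Alpha spectrum of 211At in equilibrium with its 211Po daughter.
# The two alpha energies are the nuclide's main lines; branching ratios
# (direct alpha branch vs. the EC -> 211Po branch) are external constants
# from standard decay data and may be edited to match another evaluation.
half_life_h: 7.214
lines:
  - {yield: 0.418, energy_mev: 5.87}
  - {yield: 0.582, energy_mev: 7.45}
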