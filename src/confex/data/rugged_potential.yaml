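# Rugged 2-D potential fixture: two deep wells (E, B) separated by a
# small length scale, with two shallow intermediate traps off the direct
# path.  Depths in multiples of kbt, lengths in reduced units.
version: 1
kbt: 1.0
diffusion: 1.0
confine_k: 1.5
wells:
  - {center: [-1.2, 0.0], depth: 7.0, width: 0.4}   # E (minor)
  - {center: [1.2, 0.0], depth: 8.5, width: 0.4}    # B (major)
  - {center: [-0.1, 0.5], depth: 3.0, width: 0.3}   # intermediate trap 1
  - {center: [0.5, -0.4], depth: 2.5, width: 0.3}   # intermediate trap 2
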