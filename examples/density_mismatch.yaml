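# Density-mismatch collision assay: equal rectangles, unequal seeding
# density.  After fusion the boundary drifts toward the less dense tissue.
world: {width: 6500, height: 3200}
default_speed: 29.5
tissues:
  - id: 1
    shape: {kind: rectangle, center: [2500, 1600], width: 1000, height: 3000}
    density: 2600
    color: orange
  - id: 2
    shape: {kind: rectangle, center: [4000, 1600], width: 1000, height: 3000}
    density: 1800
    color: magenta
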