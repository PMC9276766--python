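# Archetypal unequal pair: a circle colliding with a long rectangle.
# The fused boundary curves away from the larger (rectangle) tissue.
world: {width: 5000, height: 3200}
default_speed: 29.5
tissues:
  - id: 1
    shape: {kind: circle, center: [1400, 1600], radius: 500}
    color: orange
  - id: 2
    shape: {kind: rectangle, center: [3600, 1600], width: 700, height: 2800}
    color: magenta
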