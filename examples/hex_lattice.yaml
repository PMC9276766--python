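# Hexagonal lattice of circles: self-assembles into a honeycomb
# tessellation of pinned boundaries.
world: {width: 6000, height: 5200}
default_speed: 29.5
tissues:
  - id: 1
    shape: {kind: circle, center: [900, 800], radius: 350}
  - id: 2
    shape: {kind: circle, center: [2100, 800], radius: 350}
  - id: 3
    shape: {kind: circle, center: [3300, 800], radius: 350}
  - id: 4
    shape: {kind: circle, center: [4500, 800], radius: 350}
  - id: 5
    shape: {kind: circle, center: [1500, 1839], radius: 350}
  - id: 6
    shape: {kind: circle, center: [2700, 1839], radius: 350}
  - id: 7
    shape: {kind: circle, center: [3900, 1839], radius: 350}
  - id: 8
    shape: {kind: circle, center: [5100, 1839], radius: 350}
  - id: 9
    shape: {kind: circle, center: [900, 2878], radius: 350}
  - id: 10
    shape: {kind: circle, center: [2100, 2878], radius: 350}
  - id: 11
    shape: {kind: circle, center: [3300, 2878], radius: 350}
  - id: 12
    shape: {kind: circle, center: [4500, 2878], radius: 350}
  - id: 13
    shape: {kind: circle, center: [1500, 3918], radius: 350}
  - id: 14
    shape: {kind: circle, center: [2700, 3918], radius: 350}
  - id: 15
    shape: {kind: circle, center: [3900, 3918], radius: 350}
  - id: 16
    shape: {kind: circle, center: [5100, 3918], radius: 350}
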