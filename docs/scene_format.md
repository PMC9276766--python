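# Scene file format

A scene file is YAML describing the initial footprints of all tissues in a
collision or tessellation experiment.  All geometry is in micrometres; the
origin is the top-left corner of the world and y increases downward.

```yaml
world: {width: 5000, height: 3000}   # um
default_speed: 29.5                  # um/h, used when a tissue omits `speed`
tissues:
  - id: 1                            # positive integer, unique
    shape: {kind: circle, center: [1200, 1500], radius: 500}
    speed: 29.5                      # um/h (optional)
    density: 2600                    # cells/mm^2 (optional)
    color: orange                    # free-text tag (optional)
  - id: 2
    shape: {kind: rectangle, center: [3600, 1500], width: 800, height: 2400, angle: 0}
```

## Shape kinds

| kind      | keys                                              |
|-----------|---------------------------------------------------|
| rectangle | `center [x, y]`, `width`, `height`, `angle` (deg, optional) |
| circle    | `center [x, y]`, `radius`                         |
| ellipse   | `center [x, y]`, `a`, `b` (semi-axes), `angle` (deg, optional) |
| polygon   | `vertices [[x, y], ...]` (simple, non-self-intersecting) |
| mask      | `path` (TIFF, nonzero = inside), `spacing` (um/px), `origin [x, y]` (optional) |

Validation: ids must be unique positive integers, footprints pairwise
disjoint, speeds non-negative, the world extent strictly positive.
Overlapping seeds are rejected with the offending pair named.

Example scenes live in `examples/`:

- `pair_circle_rectangle.yaml` — archetypal unequal pair (circle vs long
  rectangle), whose collision boundary curves away from the larger tissue;
- `density_mismatch.yaml` — equal rectangles seeded at 2600 vs 1800
  cells/mm^2, the boundary-motion assay;
- `hex_lattice.yaml` — a hexagonal lattice of circles that self-assembles
  into a honeycomb tessellation.
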