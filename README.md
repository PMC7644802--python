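# blockfold

A headless library and CLI for designing large protein architectures from
compatible structural building blocks ("modules"): repeat-protein cores,
bent junctions, multi-chain cyclic hubs, and terminal caps.

What it does:

- **Module database** (`module_library`) — builds a JSON library from PDB
  fragment files plus posed pair structures: per-module center of mass and
  collision radius, termini interface types, and pairwise rigid transforms
  recovered by least-squares superposition.
- **Transform algebra** (`geometry`) — proper rigid transforms (no scaling,
  reflections rejected), composition/inversion, Kabsch superposition.
- **Design scene** (`design_model`) — place modules, extrude compatible
  successors at free termini, mirror-linked symmetric growth (hubs are
  auto-mirror-linked), link-occupancy bookkeeping, automatic
  connected-component networks, whole-network moves and joins, and
  sphere-based collision checks.
- **Path guides** (`path_guide`) — geometry-only joint/bridge graphs that
  describe a target shape; hybrid designs pin joints to placed modules;
  partial-design sanity checks; solver-spec export.
- **Solver** (`solver`) — deterministic beam search (with exhaustive mode)
  over the extrusion graph, minimizing a chamfer-style fit score between
  module centers of mass and the guide polyline; emits an importable
  solution JSON.
- **Stitcher** (`stitcher`) — converts a coarse design into an all-atom
  model: projects fragment atoms through placement transforms, caps every
  free terminus, assigns chains to maximal N→C paths, renumbers residues,
  and writes mmCIF.
- **Toy library** (`fixtures`) — a deterministic synthetic module set with
  analytically known transforms, used as ground truth by the test suite
  (no downloads needed).

Design/guide/spec/solution files are JSON with coordinates in nm; the
library and all internal math use Angstrom.

## CLI

```sh
blockfold fixtures -o toy/                       # generate the toy library
blockfold build-library toy/fragments toy/pairs toy/manifest.json -o lib.json
blockfold solve spec.json lib.json -o solution.json --seed 1 --beam 8
blockfold stitch design.json lib.json -o model.cif
blockfold validate design.json lib.json --json report.json
blockfold roundtrip design.json lib.json
```

Exit codes: 0 success, 2 validation findings, 3 no solution, 1 other errors.

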