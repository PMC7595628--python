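# Full-scale periodic bifurcation channel (micrometre / microsecond units).
#
# A 30 um parent channel splits into two daughter branches (10 um and 20 um,
# the 1:2 asymmetric case) around a rhomboid divider and re-converges; the
# channel height is 20 um. 40 oblate elastic cells of radius 3.91 um are
# seeded at random upstream, plus one large stiff spherical cell (radius
# 7.5 um, 642-node mesh) at the centre of the parent channel. Kinematic
# viscosity 1.5, density 1.0 in lattice units.
#
# This is a cluster-scale configuration kept as a template: expect hours of
# runtime on one core. For a desk-scale version use the built-in
# `bifurcation_demo` scenario.
name: bifurcation_full
box: [150, 30, 20]
fluid:
  viscosity: 1.5
  density: 1.0
  spacing: 1.0
  body_force: [2.0e-4, 0.0, 0.0]
md:
  dt: 0.1
  substep_ratio: 1
  seed: 1
boundaries:
  - {kind: wall, normal: [0, 1, 0], offset: 0.5}
  - {kind: wall, normal: [0, -1, 0], offset: -29.5}
  - {kind: wall, normal: [0, 0, 1], offset: 0.5}
  - {kind: wall, normal: [0, 0, -1], offset: -19.5}
  # divider: daughter branches of widths 10 (upper) and 20 (lower)
  - {kind: rhomboid, corner: [55.0, 10.0, 0.0],
     a: [40.0, 0.0, 0.0], b: [0.0, 10.0, 0.0], c: [0.0, 0.0, 20.0]}
cell_types:
  rbc:
    icosphere: {subdivisions: 2, radius: 3.91}
    resize: [1.0, 1.0, 0.4]
    mass: 1.0
    ks: 0.005
    kb: 0.02
    kal: 0.007
    kag: 0.7
    kv: 0.9
  rare:
    icosphere: {subdivisions: 3, radius: 7.5}   # 642 mesh nodes
    resize: [1.0, 1.0, 1.0]
    mass: 1.0
    ks: 0.05
    kb: 0.2
    kal: 0.07
    kag: 0.7
    kv: 0.9
cells:
  - {type: rare, origin: [25.0, 15.0, 10.0], label: rare}
# min_gap is a centroid-distance guard only; mild residual contacts at
# startup are resolved by the membrane-collision repulsion within a few
# hundred steps
seed_cells:
  - {type: rbc, n: 20, min_gap: 5.0, rng_seed: 1,
     region_lo: [2.0, 5.0, 4.0], region_hi: [53.0, 25.0, 16.0]}
  - {type: rbc, n: 20, min_gap: 5.0, rng_seed: 2,
     region_lo: [97.0, 5.0, 4.0], region_hi: [148.0, 25.0, 16.0]}
coupling:
  gamma: auto
interactions:
  wall: {a: 0.002, n: 2.0, d_cut: 1.0}
  cell_cell: {a: 0.01, n: 2.0, d_cut: 1.0}
  self_cell: {a: 1.0e-4, n: 2.0, d_cut: 0.5, exclusion_depth: 2}
run:
  steps: 200000
  output_every: 1000
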