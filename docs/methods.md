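# Methods

This note documents the generative model, its tunable parameters, the
numerical choices made where the published description leaves the design
open, and what the bundled studies do and do not demonstrate.

## Model overview

The placenta is an oblate spheroid: volume `V` (cm³), long in-plane radius
`r_maj` (cm) and eccentricity `E` give the short radius
`r_min = r_maj·sqrt(1 − E²)` and half-thickness
`t_half = 3V/(4π r_maj²)`. The surface is meshed as a latitude–longitude
quadrangulation split into triangles and refined by midpoint (1→4)
subdivision, new vertices being projected back onto the spheroid; the
refinement target is a seed density of 13 vertices/mm² by default (the mesh
vertices are the candidate endpoints for chorionic growth). The chorionic
plate is the +z cap obtained by removing whole latitude rows from the −z
pole until the cap area best matches the Knud Thomsen half-ellipsoid area
(exponent 1.6); the basal plate is the −z cap. The cord insertion is the
plate vertex whose in-plane distance from the plate centroid best matches
`d_c = CCI·r_maj`, constrained to lie at least `m_t` (default 20 mm) from
the plate margin; ties in distance are broken by a seeded random azimuth.

Vessel trees are stored as node coordinates, per-node parent indices and
per-segment diameters/labels (umbilical, chorionic, stem, villous). Every
bifurcation satisfies Murray's law `d0^k = d1^k + d2^k` jointly with the
asymmetry constraint `d1 = a·d2`, `a` sampled per bifurcation (default
N(1, 0.05)); daughter lengths are `l = ltd·d`, with a generation-dependent
cubic `ltd_c(g) = 0.02629 g³ − 0.655 g² + 5.176 g − 0.7898` for chorionic
vessels and a stationary `ltd_v` (default N(10.5, 0.8)) for villous ones.
Candidate daughters must fall in tolerance windows `l·(1 ± tol_l)` and
`θ_pd·(1 ± tol_θ)` (defaults 0.10 and 0.30 for chorionic growth, angle-only
0.15 for villous growth) and respect daughter-daughter angle limits
(chorionic 70–100°, villous ≥ 25°).

Chorionic growth starts from two 20 mm umbilical segments laid tangentially
on the plate at the insertion, running in opposite directions along an
in-plate axis of seeded random azimuth (the cord's orientation about its
own axis is arbitrary), each displaced by `ud` in the perpendicular
direction so the antiparallel cylinders clear each other rather than sit in
contact. The random azimuth also lets an eccentric cord split the plate
into unequal territories, which is what makes the arterial supply more
asymmetric for non-central insertions. Candidates are plate
vertices; they are ranked by `L = cf1·norm(D1) + cf2·norm(1/D2)` with `D1`
the distance to the existing tree (spread) and `D2` the distance to the
plate centroid (coverage). Growth stops at `bg_c` generations (default 8)
or `bn_c` segments (default 100); a branch dies when its tip is closer than
its diameter to other tree nodes or closer than twice its diameter to the
plate margin. Stems are 2 mm connectors from each chorionic segment's
midpoint into the volume at 60–90° to the segment axis; their diameter is
drawn from the stem distribution but capped at the carrying segment's
diameter so diameters stay non-increasing along every path.

Villous growth samples 500 approximately uniform points on the sphere of
radius `l` about the tip. The plane through tip, parent and grandparent
(normal `n_V`) splits candidates so the two daughters leave on opposite
sides — the source of out-of-plane alternation; ranking uses the distance
to that plane (`cf1`, maximised) and the distance to the basal plate
(`cf2`, minimised). Branches stop at `bg_v` generations or by the same
distance criteria (tip vs. tree nodes, 2× diameter vs. basal plate). The
0.03–0.04 mm terminal-caliber band is what `bg_v = 13–15` achieves for
healthy inputs; it is reported and validated but deliberately *not* a
termination rule — with the FGR preset (thinner stems, lower bifurcation
exponent) terminal calibers fall to ~0.014–0.018 mm, which a band stop
would make impossible.

Collision handling: candidates are tested against segments intersecting a
spherical ROI around the candidate midpoint of radius (3/5)·l plus the
pair's contact radius. The classical endpoint-membership ROI rule is
exposed as `roi_filter`, but the pipeline uses the exact
segment-to-midpoint distance with the contact padding: the endpoint rule
lets a long segment slice through a short candidate's ROI undetected, and
post-hoc audits of grown trees then report genuine overlaps.
A pair passes immediately when the line-to-line distance exceeds
`(7/4)·(d_i + d_j)` — the contact radius `(d_i+d_j)/2` plus two venous
radii `(3/4)(d_i+d_j)`, strictified from the 5/4 floor; the printed
constants 5· and 7· contradict their own derivation and would forbid any
realistic branching, so the derived 5/4 / 7/4 values are used and the
multiplier is exposed in configuration. Pairs failing the clearance are
decided by finite-cylinder geometry: an exact segment-distance screen
settles clear-cut cases and GJK on 16-facet polygonal cylinder hulls
decides ambiguous end-cap contacts. Parent/child and sibling pairs sharing
a node are exempt. Mesh containment uses a column voxelization of the
watertight domain surface with ray-crossing parity (pitch 1/50 of the
smallest extent by default); the cuboid placentone uses its exact box and
cavity predicates.

The placentone is a cuboid `X_p = Y_p = sqrt(V/(2t_half·n_p))` of the full
placental thickness. Its villous-free central cavity is a semi-ellipsoid of
radius `CC_r` and height `CC_h` rising from the centre of the basal face —
spiral arteries open through the basal plate, and anchoring the cavity at
the chorionic face would put it around the stem entry. The stem enters
through the centre of the chorionic (+z) face.

Venous space is never meshed: each arterial branch reserves a co-axial
venous counterpart of length `l/2` and diameter `(3/2)d`, giving total
vessel volume exactly 2.125× arterial volume; density maps rasterize both
(binary voxel-centre test, default voxel 0.1165 mm, diameter band
[0.1165, 0.9) mm). Spread is implemented literally as the RMS coordinate
deviation about the centroid (a `distance_sd` variant is exposed).

## Metric conventions

* Branching generations count *bifurcation levels*: monopodial
  continuations (a daughter whose sibling found no viable candidate) do not
  increment the level. The "mean branching generations" statistic averages
  the level over **all** segments, not only terminals: for a dichotomous
  chorionic tree capped at 100 segments the all-segment mean reproduces the
  published 3.85 (central) / 4.27 (non-central) values, whereas a
  terminal-only mean sits near 5.5.
* Path lengths sum segment lengths from the stem root (the stem segment
  included) to each terminal node.
* Strahler ratios are antilogs of least-squares slopes of log10(count /
  mean diameter / mean length) against order; empty orders are excluded.

## Sensitivity and stochasticity machinery

Morris screening runs `r` randomized one-at-a-time trajectories on inputs
scaled to [0, 1] over their ranges (so μ* is directly comparable across
inputs), with 4-level grids, Δ = 2/3, Latin-hypercube-seeded base points
and per-coordinate direction randomization. Failed model evaluations void
only the elementary effects touching the failed point. Inputs are ranked by
`0.5·μ*_norm + 0.5·(1 − σ_norm)`, the top three per output flagged highly
influential. Run-to-run variability fits a univariate Gaussian to each
metric's within-tree values per run and reports the closed-form KL
divergence over all unordered run pairs (or all cross pairs between two
presets); scalar-per-run metrics such as the Strahler branching ratio can
be given a spread by bootstrap resampling of segments.

## Problem sizes used

Unit and property tests run on coarse meshes (0.5–2 seeds/mm²) and shallow
trees (`bg_v` ≤ 6); the reproduction studies use ten seeded runs per
scenario at the published depths (`bg_v` = 15 placentones, `bg_c` = 8 /
`bn_c` = 100 chorionic trees at 13 seeds/mm²), and the whole-organ
assembly is exercised at `bg_v` ≤ 6 as a scaled, directional check —
full-depth organ builds contain ~10⁶ branches and are multi-day
computations by construction.

## What the generator does and does not emulate

The synthetic structures reproduce the arterial tree's topology and
space-filling statistics under idealized geometry: perfect spheroid,
cuboid placentones, straight cylindrical segments, no vessel tortuosity or
cross-section variation, no explicit venous or capillary geometry, no
hyper-branching adaptive responses, and no preferential
monopodial-vs-dichotomous control by insertion type. Passing tests
demonstrate internal consistency and agreement with the published summary
statistics of the same generative process — not anatomical fidelity to any
individual placenta.

## Known limitations and open choices

* The number of sphere candidates per villous daughter (500) is an exposed
  discretization choice; the published description fixes no count, and the
  emergent branch-failure rate — hence density and mean path length — is
  sensitive to it.
* With the published inputs, the ideal geometric path sum (Σ ltd·d over
  generations plus the stem) to the reported terminal calibers is
  30.9 mm (healthy) / 22.0 mm (FGR); the generated trees land on these
  sums, about 13% above the published 26.80 / 18.55 mm means, and the FGR
  density is correspondingly above the published 0.20%. No stated rule
  prunes early branches strongly enough to close that gap; see the
  candidate-count sensitivity above.
* Whole-placenta density uses the mesh volume as denominator; organ-scale
  interior-vs-periphery comparisons use z-averaged column densities, the
  same measure the published density maps report.
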