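# Model and methods

## The model

`myxosim` simulates gliding *Myxococcus xanthus* cells on a flat periodic
surface during the first 12–20 hours of starvation-induced development,
when cells stream along shared slime trails and condense into early
aggregation centers. Movement is governed entirely by five experimentally
motivated behaviours; there are no forces, no chemoattractant fields and no
fitted interaction potentials.

**Cell representation.** A cell is an off-lattice bead chain of `N` nodes
joined by `N-1` segments of equal length `L` (3 ≤ N ≤ 5, tied to the
sampled body length of 3–5 µm; width is a tenth of the length). Node 0 is
the leading pole; the orientation is the unit vector from the lagging to
the leading pole. The leading pole moves at a fixed speed v = 4.5 µm/min in
a per-step motility direction; one time step is Δt = 1/3 min. Body nodes
trail the pole *along its recorded path* at arc-length spacing `L`
(a waypoint queue per cell). This generalizes the shift-to-predecessor
update — which is exact only when vΔt = L — and keeps the equal-segment
invariant exact for every step length and turning history. After a polarity
reversal the reversed body itself becomes the recorded path, so an
undisturbed cell glides back along the track it came on.

**Per-step decision.** Each step every cell resolves exactly one mode, in
strict priority order:

1. **Reversal** — a per-cell clock with period T (baseline Normal,
   mean 6.24 min, sd 0.5 min, truncated at 0.1 min) advances by Δt; when it
   expires the poles swap and the cell does not translate this step.
2. **Collision** — the leading pole within one cell width of another
   cell's node. Side contact aligns the cell with the neighbour at an acute
   angle; head-on contact makes it swerve slightly (uniform ±[10°, 30°]) or
   reverse, with equal probability.
3. **EPS trail following** — slime in the forward semicircle (radius one
   cell length) steers the cell toward the angular sector with the most
   slime, always an acute turn.
4. **Active turning** — with no external cue, the cell turns spontaneously
   once its turning timer (Normal, mean 3 min, sd 1 min) elapses, by a
   Normal-distributed magnitude (mean 30°, sd 10°, truncated to (0°, 90°]),
   left or right with equal chance.
5. **Straight** gliding along the tail-to-head axis otherwise.

All decisions read the positions other cells had at the start of the step
and all updates are applied simultaneously, so no per-step iteration order
exists and runs are bit-reproducible for a fixed seed. Named random
substreams (initialization, reversal, turning, collision, tie-breaks) keep
mutant presets replayable: disabling one behaviour does not shift the draws
of the others.

**Quorum sensing.** At a reversal the cell counts neighbours inside its
measuring domain (the axis-aligned square of side one cell length centred
on the body centroid; any cell with a node partly inside counts) and
re-draws its current period uniformly from the matching density class:
5–19 neighbours → 8–12 min, 20–99 → 15–30 min, 100–999 → 30–40 min,
≥ 1000 → 300–360 min (capped at 360 min, i.e. behaviourally non-reversing
within any simulated horizon). Below five neighbours the cell returns to
its baseline sampled period, so cells that leave a dense region recover the
normal rhythm. Head-on collision reversals modulate the clock the same way
as clock reversals: both are polarity reversals.

**EPS slime.** Moving cells deposit one EPS point per step from the lagging
pole. The domain's slime is quantized on a 0.5 µm lattice of deposition
counts — a raw point list at developmental scale would hold ~10⁷ points —
and never decays. Sensing scans the forward semicircle of radius one cell
length, splits it into six 30° sectors, sums counts per sector, and steers
toward the count-weighted centroid of the winning sector (ties broken
toward the smaller turning angle, then randomly). A cell's own deposits of
the last few steps (`eps.self_exclude_steps`, default 5) are invisible to
its own sensing so it cannot chase its own tail.

## Interpretive rules the source description leaves open

Three rules required interpretation beyond the verbal description; each is
a configuration value and each changes the emergent phenotype:

* **Trail following is an encounter, not a leash.** Cells turn onto trails
  they cross; a trail running straight ahead does not steer the cell. With
  `eps.straight_tol_deg > 0`, a winning direction within that dead band
  leaves the step open to a *due* active turn. At the default 0 the
  steering claims every step in which any eligible slime is sensed, and
  spontaneous turning operates on unslimed ground only.
* **Alignment is an event.** A side contact aligns a cell only while the
  two axes differ by more than `collision.align_tol_deg` (default 15°);
  cells already gliding (anti-)parallel in contact are a stream, not a
  collision, and stay responsive to slime and turning. Without this rule
  cells in streams re-trigger alignment every step and the pattern freezes.
* **Own-trail blindness.** Trail following targets slime laid by *other*
  cells; the own-trail exclusion window is short by default (5 steps) so
  that a reversing cell still retraces its own old track.

## Emergent behaviour and the study conditions

At low density (the 100-cell, 2 h gliding experiment; 100×100 µm) the model
produces wiggly individual tracks, local alignment and curly slime trails.
At developmental density the sequence is: trail reinforcement → streams →
closed circulating loops → dense centers. The wild-type developmental
preset uses 5000 cells in 246×246 µm (0.083 cells/µm²). The real assay
spots cells near-confluently; the absolute simulation density is a model
choice (the source states none), picked so that streams reach the 20–99
quorum class and circulating centers condense. Desk-scale runs shrink cell
count and domain area together (`scale_preset`), preserving this density.

Runs are stochastic and strongly history-dependent: whether a given seed
ends at 12 h with a compact round center, a dense ring, or dense elongated
stream fragments varies. Recruitment into dense structures (the fraction
of cells in density-connected clusters) is robust at 75–95%; the *shape*
of the largest structure is the most seed-sensitive readout. On a periodic
desk-scale domain, loops that wind around the torus cannot contract and
persist as dense bands — a finite-size artifact the full-size domain
suffers less from.

## Analysis definitions

* **Aggregation center**: a density-connected cluster of cell centroids —
  every member has ≥ 10 neighbours within one cell length (4 µm,
  minimum-image); clusters below 2% of the population are discarded. The
  one-cell-length radius is chosen so that a uniform random scatter at
  study density yields no clusters (a dispersed EPS-null population must
  read recruitment ≈ 0).
* **Recruitment fraction**: fraction of all cells in any qualifying
  cluster.
* **Shape**: the cluster footprint is rasterized at 2 µm, closed, and
  filled. Circularity is 4πA/P². ROUND requires circularity ≥ 0.6 and an
  interior-hole fraction ≤ 0.2 — orbiting aggregates keep a small central
  dimple by construction, while the persistent middle hole of a true ring
  is far larger. HOLED flags hole fractions above 0.2; LONG_MULTI flags
  principal-axis ratios ≥ 3 or ≥ 3 density peaks; anything else is NONE.
* **Time to aggregation**: the earliest snapshot time at which recruitment
  ≥ 0.8 *and* the largest cluster is ROUND, sustained over the following
  hour of snapshots; unconfirmed or never-reached horizons report "not
  reached".

All thresholds are keyword arguments with the defaults above.

## Numerical choices

* Truncated-Normal sampling uses inverse-CDF on uniform draws, so a value
  is one draw regardless of truncation (stream-stable determinism).
* The slime stencil probes at most half the lattice per axis, so a bin is
  never double-counted through the periodic wrap; sub-bin pole positions
  are respected in all distance and angle tests.
* Collision detection queries a periodic cKD-tree over all nodes (an exact
  superset of any radius query); the nearest foreign node decides.
* Sector ties break toward the smaller turning angle, then by a dedicated
  tie-break stream; perpendicular alignment contacts break by the same
  stream.
* Reversal-clock quantization: with Δt = 1/3 min a period T fires after
  ⌈T/Δt⌉ steps, so measured inter-reversal intervals exceed T by ~Δt/2 on
  average (≈ 0.17 min); pooled event-log means are additionally weighted
  toward short-period cells, which reverse more often. Parameter-recovery
  checks account for both effects.
* The batched slime-sensing step (the per-step hot spot) runs as a
  numba-compiled kernel over a radially sorted bin stencil with early
  exit; at 1000 cells a full step costs ~20 ms on one CPU, so a 12 h
  desk-scale run takes under a minute.

## What the synthetic conditions do and do not show

All inputs are generated: there is no microscopy data in the loop. Passing
tests show that the implemented rules reproduce the *mechanisms* —
streaming, trail reinforcement, circular paths, density-dependent reversal
slowdown, the dispersal of EPS-null cells, the non-aggregation of reversal
mutants — and recover the behavioural input statistics from event logs.
They do not calibrate absolute aggregation timing against real
development: timing at desk scale depends on the chosen density, the
periodic domain size and the seed, and the shape of the final structure is
chaotic at the single-run level.

## Known limitations

* No excluded volume: cells overlap freely, as the density of real
  monolayer aggregates requires; mechanical jamming is not represented.
* No slime decay (deliberate), no cell growth or division, no 3-D
  stacking, no later fruiting-body stages.
* The five behavioural rules are phenomenological; the Frz pathway,
  C-signal and pilus mechanics are abstracted away.
* Desk-scale periodic domains allow domain-winding dense bands that cannot
  contract into round centers; conclusions about aggregate *shape* at
  scale factors ≤ 0.2 carry that caveat.
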