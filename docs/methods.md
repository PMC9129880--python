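# Methods

This note documents the model, its parameters and the design choices made
where the design was genuinely open. Coordinates: `x` is anteroposterior,
`y` dorsoventral with y increasing ventrally and y = 0 at the dorsal edge.
Lengths are μm, times minutes, angles radians.

## Chain migration model

Cells are 2D discs with an identity (leader or follower), a radius, an
intrinsic speed and a unit heading. One update (time step `dt = 1 min`)
applies, in fixed order (the order is part of the model contract —
changing it changes the dynamics):

1. **Intrinsic motility** — displacement `speed · dt` along the heading.
   Motility arrests at the end of the migratory path (`y ≥ y_end`), and
   the arrest propagates dorsally by contact **for followers only**: a
   follower touching a stopped cell stops too (a chain parks behind its
   arrested front), while a leader keeps driving until it reaches the end
   itself. This asymmetry is what lets leader-rich fronts push past the
   path end (over-migration) while follower-rich chains park neatly.
2. **Contact inhibition of locomotion (CIL)** — for each contacting pair
   (centre distance < sum of radii + 0.5 μm) the eligible cells rotate
   their headings away from the partner by at most the turn angle of
   their CIL intensity level; the turn never overshoots the directly-away
   direction. In `differential` mode only leader–follower contacts
   trigger CIL; `all_pairs` applies it to every contact. A kicked heading
   persists for `cil_persistence = 1` step (noise and re-kicks are
   suppressed). Longer persistence was tried and rejected: a mid-chain
   leader kicked dorsally then plows through the chain for the whole
   refractory window and triggers a collective retreat. Coincident
   centres (degenerate contact) draw a random repulsion axis from the
   simulation's event stream.
3. **Co-attraction** — a displacement of magnitude `ε(level) · dt` toward
   the centroid of neighbours within `coattraction_range = 60 μm` but
   beyond a contact dead zone (touching distance + 2 μm). Co-attraction
   is an at-a-distance interaction; letting it act down to contact
   compresses the chain axially and buckles it out of single file.
   Alongside the displacement, co-attraction **re-polarises** separated
   cells: the heading relaxes (rate 0.15 for followers, 0 for leaders)
   toward the nearest detached in-range neighbour *ahead*; a follower
   with nobody ahead turns back toward the group centroid, while a
   leader with nobody ahead is the pioneer and keeps its own polarity.
   This is the model's expression of "leaders direct, followers follow":
   followers chase the chain, stray cells rejoin it, and the front
   leader's direction is set only by its own persistence and by the CIL
   kicks it receives from followers behind it (which point ventrally in
   a migrating chain — a self-sustaining ratchet).
4. **Volume exclusion** — iterative hard projection separating
   overlapping pairs along their centre line (tolerance 0.1 μm, ≤ 60
   sweeps). Wall constraints take precedence, so two cells squeezing
   past each other in the narrow corridor can transiently overlap — the
   disc stands in for a deformable cell. Measured across all default
   conditions the centre-distance deficit stays below 6 μm (~0.6
   follower radius); the non-overlap invariant is asserted at that
   tolerance.
5. **Heading alignment and noise** — a follower's heading relaxes toward
   its realized displacement at rate 0.05 (motility persistence feeding
   group motion back into polarity; leaders: 0), then every
   non-refractory heading is rotated by an angle ~ Normal(0, `zeta`),
   `zeta = 0.15` rad/step.
6. **Boundary reflection** — the corridor has reflective walls on both
   anteroposterior sides and at the dorsal staging boundary, acting on
   cell edges (centres confined to `[r, width − r]`). The ventral end is
   open: chains can over-migrate past `y_end`.

### Arena

`width = 18`, `y_premigratory = 25`, `y_ntnot = 65` (the neural-tube/
notochord landmark), `y_end = 150`, dorsal staging extent
`y_dorsal = −100`. The corridor width is ~1.6 follower diameters: wide
enough for followers to squeeze past one another (rearrangements), narrow
enough that the chain cannot collapse into a 2D cluster. Substantially
wider corridors (tested up to 5 radii) lose single-file arrangement under
any co-attraction level; substantially narrower ones forbid passing
entirely. The premigratory compartment extends dorsally behind the
dorsal edge so that chains of arbitrary length can pack single file with
the front cell at the ventral edge of the premigratory band; a chain
whose stacked length exceeds the compartment raises a configuration
error.

### Identity parameters

| parameter | leader | follower | note |
|---|---|---|---|
| radius (μm) | 5.70 | 4.79 | √(area/π) from in-vivo areas 102 / 72 μm² |
| speed (μm/min) | 0.7 | 0.5 | order-of-magnitude match to in-vivo orderings |
| CIL intensity | high (π/2) | low (π/12) | turn-angle levels |
| co-attraction steering | 0 | 0.15 | leaders pioneer |
| displacement alignment | 0 | 0.05 | motility persistence |

Interaction levels (calibration constants, not measured values): CIL turn
angles {off 0, low π/12, medium π/4, high π/2}; co-attraction drifts
{off 0, low 0.05, medium 0.15, high 0.3} μm/min; cell-size multipliers on
the leader radius {low 0.84, medium 1.0, high 1.2}.

### Compositions

Chains default to 8 cells. `1:2` and `1:3` leader:follower ratios repeat
their unit from the front (`LFFLFF…`, `LFFFLFFF`). `1:1` places its four
leaders as a front block (`LLLLFFFF`): with equal numbers the excess
leaders crowd the chain front. The arrangement matters — interleaved
mid-chain leaders act as brakes (they receive dorsal CIL kicks from the
followers ahead), and an interleaved 1:1 chain does not over-migrate,
whereas the leader block presses persistently into the arrested front
(leader–leader contacts trigger no differential CIL back-off) and pushes
it past the path end.

### Randomness

One master seed per simulation; per-agent heading-noise substreams and a
shared discrete-event stream are derived by stable SHA-256 hashing, so a
run is bit-reproducible and independent of execution order. Sweeps derive
replicate seeds from (master seed, combination index, replicate index)
only.

## Scoring

`ScoreConfig` defaults: cohesion limit 57 μm (strict: a single frame over
the limit fails; a tolerant variant is available behind a flag),
single-file fraction ≥ 0.80, front-retention fraction ≥ 0.95,
overtake margin 2 μm sustained ≥ 3 frames (15 min), over-migration margin
one leader diameter (11.4 μm). A frame is single file when no pair is
side by side; a pair is side by side when in effective contact (centre
distance < sum of radii + 2 μm) while laterally level, |Δy| < 0.5·min
radius. The half-radius levelness counts genuinely abreast cells but not
the transient diagonal contacts of a passing manoeuvre; with full-radius
levelness the stable wedges that hard discs form in a passing-permissive
corridor dominate, and single-file ≥ 80 % becomes incompatible with the
rearrangement criterion for rigid discs. Follower rearrangement passes
with ≥ 1 sustained follower–follower rank swap (same margin rules).
Front retention counts frames whose most ventral cell is a leader;
overtakers are counted among followers only, so a second leader passing
the designated front cell does not fail the criterion. Path completion
uses the maximum ventral position reached by any leader (any cell for
leaderless chains); over-migration flags a final front beyond
`y_end + margin`.

## Sweeps

Full factorial grids over the leader's CIL intensity, the group
co-attraction level and the leader cell size (3³ = 27 combinations),
simulated with `n_reps` (default 20) derived-seed replicates; a
combination "matches" a score when ≥ 70 % of its replicates pass it, and
matches overall when that holds for all five. Both replicate-level and
aggregated views are exported. Under the default calibration no
homogeneous composition matches all five scores (all-follower chains
fail leader-front and path completion; all-leader chains lose cohesion),
while many 1:3 differential-CIL combinations do. The exact *number* of
matching combinations depends on grid extent, replicate count and the
underlying force laws, and is not treated as a reproducible quantity.

## Track metrics

Per-step speed is exactly the tracking formula
`(√((X₁−X₂)²+(Y₁−Y₂)²+(Z₁−Z₂)²)/T)·60` (μm/hr); a cell's mean speed is
the mean of per-step speeds (not net-over-total). Directionality is net
displacement over path length, computed in 3D (z = 0 for simulations);
the definition used by the original tracking macro is not public, so
this standard operationalisation is documented rather than asserted as
identical. Ventral distance is the final y minus the dorsal edge
(default 0, configurable). The leader/follower mean-area ratio is
reported when an area column is present.

## Identity LDA

Two-class Fisher discriminant in closed form,
`w ∝ Σ_w⁻¹(μ_L − μ_F)`, with ridge regularisation
`λ = 10⁻⁶·tr(Σ_w)/p` on the pooled within-class covariance (samples are
small, n ≈ 10–50 cells). Features are z-scored before fitting because
they mix units (μm, μm/hr, dimensionless); importance is defined on the
standardized coefficients, with raw-scale coefficients reported
alongside and ties broken alphabetically. The axis is oriented so the
leader class projects positive. The random-data control keeps the table
shape and labels but replaces features with i.i.d. standard normals.
With two classes there is exactly one discriminant axis; any additional
axes shown in exploratory plots of such data must come from a different
decomposition, and this package emits only the discriminant axis.

## Cell-cycle analysis

Phase durations are extracted from per-frame label sequences
(G1/S/G2/M/unknown, cyclic order validated): a run counts only when
bounded on both sides by a different known phase; partially observed
runs are censored, not imputed. Duration = run length × frame interval
(5 min default), quantising boundaries to frame resolution (≤ half a
frame per boundary). Total cycle length is the time between two M→G1
transitions. Onset phase maps to the two-colour FUCCI classes (G1 vs
S/G2, with M grouped into S/G2 as the geminin reporter persists through
mitosis).

Duration distributions are fit with Gaussian mixtures (k = 1, 2) by EM
with 10 seeded restarts and a variance floor of 10⁻³ h²; k is selected
by BIC and the minor component weight quantifies bimodality. The in-vivo
minor-peak proportions were reported from frequency histograms, without a
named fitting method; the mixture fit is this package's
operationalisation.

`auto_compare` implements the normality-gated test choice: every sample
is gated by d'Agostino–Pearson followed by Shapiro–Wilk at α = 0.05
(samples with n < 8 use Shapiro–Wilk alone — the omnibus test's skewness
component requires n ≥ 8); all-normal → unpaired two-tailed t-test (two
groups) or one-way ANOVA; otherwise Mann–Whitney U or Kruskal–Wallis,
with Welch's heteroscedastic ANOVA available via a flag. Under a Normal
null (n = 30/group) the procedure's type-I error is calibrated to ≈ 5 %.

## Synthetic data

All duration and area draws are Normals truncated at zero — the source
measurements are reported as mean ± SD only, so Normality is an
assumption, flagged in generator provenance output. Defaults are the
published statistics: leader phases G1 3.2 ± 0.6, S 8.7 ± 1.3,
G2 1.6 ± 0.4, M 0.6 ± 0.1 h; follower G2 1.5 ± 0.3, M 0.5 ± 0.1 h;
onset-in-S probabilities 0.79 (leaders) / 0.23 (followers); daughter
areas 102 ± 20 and 72 ± 9 μm² (asymmetric divisions), 87 ± 27 μm²
(symmetric).

Follower G1 and S are two-component mixtures whose minor (leader-like)
peaks carry 26 % and 31 % of cells. Only the minor components and the
overall moments are published, so the major components are derived:
G1 major mean 8.9 h satisfies 0.26·3.2 + 0.74·8.9 ≈ 7.4 h and major SD
1.13 h reproduces the overall 2.7 h; S major mean
(4.6 − 0.31·8.7)/0.69 ≈ 2.76 h with SDs (0.6, 0.51) reproduces 4.6 ±
≈2.8 h. The Notch-inhibition configuration collapses followers to single
components at the control means with the halved SDs (1.42 h for G1,
1.38 h for S) and gives former leaders the follower profile.

Synthetic tracks are biased random walks at 5-min cadence: per-step
heading = ventral-bias·(0,1) + noise·η (η standard normal), step length
= per-cell speed × interval. Leaders are configured faster, straighter
and more ventrally biased (speeds 25 ± 5 vs 15 ± 5 μm/hr; bias
0.90 ± 0.08 vs 0.55 ± 0.18; heading noise 0.5 vs 0.7). The per-cell
bias spread models cell-to-cell variability in ventral persistence;
without it, within-class directionality variance is unrealistically
tiny and directionality rather than ventral distance would dominate the
discriminant. These contrasts are generator choices shaped to realise
the in-vivo orderings, not measured values. What passing tests on these
data show is that the pipeline recovers the structure the generator put
in; they cannot certify behaviour on features real imaging data have
and the generator lacks (segmentation error, drift, track breaks,
non-Normal durations).

## Problem sizes

The test suite exercises the simulator at 8 cells × 960 steps; the
composition-contrast panel uses 50 seeded replicates per architecture,
the sweep checks 27 combinations × 8 replicates (1:3) and × 3
(homogeneous compositions), mixture recovery uses 100 repetitions at
n = 200, and the type-I calibration 1000 simulated nulls. Generator
fidelity checks draw 10⁴ samples.

## Known limitations

* The interaction force laws are simple kinematic rules (instantaneous
  turns, constant-magnitude drifts, hard projection); no mechanics
  (forces, friction, deformation) are modelled, and exact counts from
  sweep analyses are therefore calibration-dependent.
* Identities are fixed inputs: no Notch signalling network, no division,
  no identity switching inside the simulator.
* The corridor is a straight 2D channel; real intersomitic paths are 3D
  and curved.
* Censoring in the cell-cycle extraction discards partially observed
  phases rather than modelling them.
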