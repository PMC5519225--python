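# Methods

## The reconstruction problem

A small, isolated wood-borer infestation is discovered in a closed-canopy
stand shortly before the stand is felled. The available evidence is a
one-shot survey: every stem's position, taxon and diameter at breast
height (dbh); counts of oviposition pits and adult exit holes per tree;
and ring counts over healed damage in cross-cut sections. The package
reconstructs the establishment history that evidence supports: when the
infestation began, how it moved between trees, what drove host choice,
and where long-range dispersers likely went.

## Models and procedures

### Stem mapping

Survey shots are polar observations from a control-point network: one
primary point (the local origin) and sub-points each shot from an already
resolved point. With bearing `b` (degrees clockwise from grid north) and
distance `d` from a point at `(E, N)`, the stem sits at
`(E + d sin b, N + d cos b)`. Bearings are grid bearings; a constant
magnetic declination cancels inside one small survey and is not modelled.
UTM output is a pure translation onto a single anchored coordinate —
appropriate for a stand tens of meters across, where reprojection effects
are far below the 0.1 m survey resolution. Distances are two-dimensional;
elevation is not recorded by the survey protocol and is ignored.

### Damage dating

Wood laid down over a wound dates it: an unhealed hole is assigned the
felling year, a healed (or partially healed) hole with `k` rings over it
is assigned `felling_year − k`. Partial healing is treated like healing —
the rings over the damage carry the date either way. Oviposition pits are
dated by the same overgrowth rule. A section claiming to be healed with
zero rings over it is contradictory and rejected rather than dated.
Cross-dating against reference chronologies and false/missing-ring
corrections are out of scope; ring counts enter as integers. The stand
summary takes minima per damage kind; an exit hole earlier than every pit
is reported as a contradiction, not returned silently.

### Infestation levels

Levels follow the eradication-program field key: A = pits only, B = 1–10
exit holes, C = 11–100. Exit holes dominate pits (emergence implies prior
oviposition), so a tree with exits and no recorded pits is still B/C.
Counts above 100 have no named level in the key; they are classified C
and flagged with a warning instead of inventing a new category. The
classifier is monotone in exit count and the level tally always conserves
the stand size.

### Dispersal-graph inference

The adjacency rules: (1) an infested tree received beetles from the
nearest tree with a strictly higher infestation level (assumed older);
(2) a tree may source many trees but receives beetles once. Hence each A
tree gets exactly one in-edge from its nearest B-or-C tree, each B tree
from its nearest C tree, and C trees get none — the graph is acyclic by
construction and has exactly (#A + #B) edges. Exact distance ties are
broken by lexicographic source id so runs are reproducible. The root is
the tree with the earliest dated oviposition; ties fall through earlier
earliest exit year, then more exit holes, then id. With several C trees
each heads its own subtree while the root names the earliest-dated tree.

Distance distributions: *inferred* = edge lengths; *potential* = root to
every other stem (the root itself excluded from both sides); *observed* =
root to every other infested stem. The distribution comparison is run for
both the edge-length and the observed framing, each labelled in the
report, because the two framings answer slightly different questions
(per-hop movement vs realised spread from the source) and field reports
commonly mix them.

### Statistics

The Kolmogorov–Smirnov statistic is the supremum of |ECDF₁ − ECDF₂| over
the pooled sample points, with an asymptotic p-value from the Kolmogorov
distribution at effective size n₁n₂/(n₁+n₂). The rank-sum statistic is
reported in the Mann–Whitney U convention for the first sample — the
count of (x, y) pairs with x > y, ties counting ½, equal to the midrank
sum minus n₁(n₁+1)/2 — with the raw rank sum also carried for
transparency, since software packages differ in which quantity they print
as "W". Its p-value uses the normal approximation with tie-corrected
variance and continuity correction; exact small-sample distributions are
out of scope because every comparison in this analysis has n > 50.
Quantiles use linear interpolation; IQR = Q3 − Q1. Both statistics are
tested exactly against brute-force enumeration oracles and independently
against SciPy; SciPy is never the implementation.

The dbh comparison contrasts infested trees against un-infested trees *of
the infested taxa only*, so tree size is compared within the host species
rather than against the whole species mix.

### Wind analysis

Sixteen 22.5° bins anchored at 0° (bin b covers [22.5·b, 22.5·(b+1)),
half-open) tally daily fastest-5-s gust source directions over the
flight season, June–October inclusive. Because dispersers travel with the
wind, the destination (expected landing) sector of each source bin is its
opposite compass point; destination frequencies are the source
frequencies cyclically shifted by 8 bins, an involution. Bins are ranked
1 (rarest) to 16 (most frequent); equal frequencies are broken by compass
row order (N first) — a deterministic rule is required because published
roses print distinct ranks even for tied bins. Percentages are recomputed
from frequencies rather than copied: in the reference climatology table
bundled as the generator default, the W row's printed percentage (12.17)
disagrees with its own frequency (351/2665 = 13.17), and the recomputed
value is the one asserted. An outlying infestation at bearing θ from the
source tree lands in sector ⌊θ/22.5⌋; its destination likelihood is the
rank of the opposite source bin, and "inside" means that rank is among
the top k (default k = 4, matching the common field framing).

## Synthetic data: what it emulates

`generate_stand` places n = 526 stems in a 2,860 m² rectangle (aspect
2:1) — clustered by default via a parent–offspring (Thomas-like) process
with σ = 4 m and ~20 stems per parent, mimicking a clumped wetland stand;
"uniform" is the null. Taxa are drawn per-stem: preferred host
(*Acer rubrum*) with probability 0.81, another host genus up to the 0.94
host fraction, otherwise a non-host. dbh is lognormal(meanlog 1.95,
sdlog 0.8) cm — median ≈ 7 cm, right-skewed — chosen so the whole-stand
median sits near the small-stem medians seen in dense regenerating
stands, while size-biased infestation pushes the infested median into the
high teens. The generated host-count and sector-count distributions are
verified against exact binomial/multinomial 99% envelopes.

`simulate_establishment` is phenomenological. Founders (default 2,
reflecting "one or two" initially infested stems) are drawn uniformly
among preferred hosts in the start year (2008). From the first emergence
season (start + lag, lag = 2 years) the yearly number of new
colonisations is Poisson (or negative binomial with size `dispersion`)
with mean `annual_mean · annual_growth^step` (defaults 1.0 and 3.7):
expected cohorts 1, 3.7, 13.7, 50.6 over 2010–2013, i.e. ~71 infested
stems with spread strongly back-loaded — a constant yearly mean cannot
produce a 65-tree pits-only cohort alongside only ~4 B trees, so the
growth factor is structural, not cosmetic. Each event picks a natal tree
weighted by emergence activity, then a target among the natal tree's 40
nearest un-infested preferred hosts with probability ∝ dbh^γ (default
γ = 2). The neighborhood is deliberately wide: beetles bypass small
nearby stems and search tens of meters for suitable hosts, and a narrow
neighborhood would exhaust local hosts and erase the size signal.
Transmission is attributed to the nearest tree with emerging adults — the
strict nearest-active-source rule the adjacency inference assumes. With
probability `long_distance_rate` (default 0.02) an event instead leaves
the stand: direction drawn from the destination shift of the wind-rose
weights, distance lognormal around 1,400 m; landings are recorded as
off-stand outlier points, not new stands.

Damage scales with occupancy: a tree colonised in year c carries
~Poisson(6 · years occupied) pits and, once adults have emerged,
~Poisson(2 · 2.75^(seasons − 1)) exit holes — founders end at C level
(tens of holes), mid-history colonists at B, late colonists at A. Every
exit hole becomes a wood section (first emergence pinned to c + lag);
the first-season pit section is always sampled, mirroring the field
practice of sectioning the oldest-looking pits, so the dating stage
recovers the simulated start year exactly.

`SpreadConfig.strict()` is the two-wave scenario used for parameter
recovery: a single founder, no long-distance events, and an explicit
yearly schedule (5, 0, 0, 65) — a first wave colonised in the founder's
first emergence season, a pause while the population builds, then a mass
pits-only wave in the felling season. Under that timing each colonist's
nearest active source coincides with the nearest higher-level tree at
felling, so graph inference is consistent with the generative process;
measured over 200 replicates it recovers > 99% of true edges and the true
root in 100% of runs (the acceptance thresholds are 95%).

What the generator does **not** emulate: within-tree beetle demography,
phenology-driven flight timing, human-mediated transport, host depletion
feedbacks, and landscape context beyond a rectangle. Passing tests show
the inference machinery is correct under its own assumptions, not that
real beetles obey the strict adjacency rules.

## Numerical choices and degenerate inputs

- Angles are stored in [0, 360); 360.0 wraps to 0.0 (half-open circle).
- Bin boundaries are half-open, so a direction exactly on a boundary
  belongs to the upper bin.
- Rounding uses Python round-half-even; 16 two-decimal roundings bound
  the percentage-column sum within 100 ± 0.08.
- Empty samples, empty stands, missing coordinates, unknown control
  points, orphan infested trees (an A with no B/C anywhere, a B with no
  C) and contradictory sections all raise typed errors naming the
  offending record rather than propagating NaNs.
- All generators take a single integer seed (NumPy `default_rng`) and are
  bit-reproducible for a fixed seed.

## Problem sizes

Recovery and calibration experiments run at the full emulated stand scale
(n = 526, ~71 infested): 200 replicates for edge/root recovery and
100 + 100 replicates for the size-bias power and null-calibration checks,
which complete in seconds. Wind-invariant checks sweep 1,000 random roses.

## Known limitations

- The adjacency rules yield a single deterministic graph; no likelihoods
  over alternative transmission trees are computed.
- p-values are large-sample approximations throughout.
- The K-S comparison treats distances as independent draws, ignoring the
  spatial autocorrelation a point pattern induces.
- The wind analysis uses one station's gust climatology as-is; no
  interpolation or within-day trajectory modelling.
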