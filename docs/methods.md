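# Methods

## Model

A *mechanism* pairs one fixed association order of n factors with one of
the n! dissociation orders.  It induces a cycle of DNA states: the empty
promoter, the n nested assembly intermediates, and the n − 1 disassembly
intermediates, each consecutive pair differing by one factor.  The same
subset can occur on both legs (e.g. a lone first factor before the second
arrives and again after it leaves); such states are pooled into a single
species/dwell variable, since occupancy data cannot distinguish how a
bound configuration was reached.

The central assumption is that per-factor percent occupancy equals the
summed steady-state dwell fraction of all states containing the factor.
A mechanism is *compatible* with an occupancy vector when nonnegative
dwell fractions over its occupied states reproduce the vector exactly.

Mechanism ids are assigned lexicographically over dissociation
permutations written in association-rank indices (1-based).  Id 1 is
always first-in-first-out and id n! last-in-first-out.  The convention is
arbitrary but fixed; the mechanism-key file ties every id to its
sequence, and re-fixing a different association order permutes ids but
never the set of sequences.  Simultaneous steps (two factors leaving
"together") are represented only by the strict permutations they cover,
never as distinct mechanism objects.

## Decision routes and their exact relationship

**Rules.**  Rule 1 (pairwise): if j associates before i and dissociates
after i, every occupied state containing i contains j, forcing
Occ(i) ≤ Occ(j).  Rule 2 (triples): a middle factor m with
Occ(m) > Occ(a) + Occ(b) for some earlier-associating a and
later-associating b must at some point sit on DNA without either, which
requires m to dissociate after both.  Violations use strict inequalities
with a tolerance of ε = 1e−9 on the percent scale, so preprocessing
round-off cannot flip a verdict; exact equality is always allowed (it is
physically attainable).

**Linear feasibility.**  The compatibility question is literally a linear
feasibility problem in the dwell fractions and is decided by a phase-1 LP
(minimize total artificial slack on the per-factor equality constraints;
feasible iff the optimum is ≤ 1e−7).  On infeasibility the equality
duals give a Farkas certificate: weights y with y·Occ > 0 that sum to
≤ 0 on every occupied state.  An optional flag additionally caps the
total dwell at 100% of DNA; it is off by default because the rules make
no use of it and it cannot bind in any two-factor case (the minimum total
dwell of a feasible two-factor vector is max Occ).

**Their relationship.**  For n ≤ 3 the rules and the LP agree exactly —
verified exhaustively over the 5%-step occupancy grid (21³ vectors × 6
mechanisms, 55,566 cells, zero divergences).  For n ≥ 4 the rules are a
strict relaxation: with association T→B→P→H and dissociation B→P→H→T,
every occupied state contains at least as many of {T, P} as of {B, H},
so feasibility requires Occ(B) + Occ(H) ≤ Occ(T) + Occ(P) — a "2-vs-2"
constraint that no pairwise or triple rule expresses.  On the archetype
charts (L = 5%, H = 40%) the divergent cells are rare: 1/384 at n = 4,
23/3840 at n = 5, 377/46080 at n = 6; all divergences found are
one-sided (rules accept, LP refutes).  `divergence_report` surfaces every
disagreement rather than silently preferring either route, and the test
suite pins the known counterexample.

**Kinetics.**  Each mechanism becomes an irreversible mass-action network
over its cycle: n association steps (state + free factor → next state)
and n dissociation steps (state → next state + factor), 2n rate
constants.  DNA and every free protein start at concentration 10
(arbitrary units; a `dna_total=1` variant exists and leaves verdicts
unchanged, as the scale cancels in classification).  The fit targets the
free-protein concentrations, protein_total − dna_total·Occᵢ/100, with
measured occupancies floored at 0.1%; E is the weighted sum of squared
deviations on that scale.  Weights default to uniform (an inverse
mean-square option exists); the classification depends only on the
bimodal gap in log₁₀ E, not on E's absolute scale.

Steady states are located by a Newton (hybr) solve of the balance
equations with an analytic Jacobian — warm-started inside the fitter,
where successive rate vectors are close — and validated by requiring the
derivative norm below 1e−9 relative to the concentration and rate scale,
nonnegativity of all species, and the conservation laws (which hold by
construction: free and empty pools are eliminated through the totals).
If the direct solve lands outside the physical simplex, the system is
integrated (LSODA) from the empty-DNA initial condition over doubling
horizons with Newton polishing; exceeding the doubling budget raises an
explicit error, never a silent partial answer.

Rate constants are searched in log₁₀ space over [−4, 4] from 20 seeded
random starts (uniform in [−2, 2]) using bounded quasi-Newton (L-BFGS-B,
300 evaluations per start) with derivative-free Nelder-Mead polish
rounds for fits that reach E < 0.5; the search stops early once
E < 1e−6, which also makes compatible cells cluster tightly in log₁₀ E.
Fitted rate constants are reported but carry no meaning — the system is
deliberately under-determined; only E does.  Repeated runs with one seed
are identical; different seeds reach essentially the same E for
compatible mechanisms.

**Threshold.**  Over the full three-factor archetype chart (8 groups × 6
mechanisms) the log₁₀ E values are sharply bimodal: compatible cells end
below −6.0, incompatible cells above +0.48 (2-means silhouette 0.98).
The default threshold −2.75 is the midpoint of that gap, computed at
build time and user-overridable; any value inside the gap yields the
same classification.  An LP-infeasible cell cannot reach E = 0 at any
rates — its equality violation lower-bounds the attainable squared error
— which is why the two modes cannot merge.

## Preprocessing

1. Background replicates are each divided by their own grand median and
   combined per probe by the median.
2. Factor replicates are median-combined per probe, divided by the
   combined background probe-by-probe, then by the median ratio over
   tail-to-tail (T-T) intergenic probes, so the T-T median fold is
   exactly 1.
3. Percent scaling: fold ≤ 1 ↦ 0%; folds at or above the value at rank
   ⌈0.99·N⌉ of the sorted folds ↦ 100%; otherwise
   100·(fold − 1)/(p99 − 1).  Background (1.0) is subtracted from both
   numerator and denominator — the only reading under which the
   percentile value itself lands exactly on 100%.  A 98th-percentile
   variant is a flag.
4. Grouping: per factor, occupancy < 10% ↦ L, otherwise H (exact ties go
   to H, reading "below 10% → low, all others → high" literally); 15%
   and three-tier (10%/20%) variants are supported for robustness
   checks.
5. Consolidation (applied incrementally as the 4th and later factors are
   added; never for ≤ 3 factors): a parent group split into two children
   keeps both only if each exceeds 100 genes, or the split is ≤ 4:1 with
   both ≥ 10; otherwise the children merge under the larger child's
   label.  Membership is conserved.
6. Group medians over the per-gene occupancies form the modeling input;
   grouping and medians are the implemented mitigation for gene-specific
   crosslinking and detection variability.

Genes lacking a complete set of TSS measurements are dropped with a
logged count (the handling of missing data is this package's choice).

## Synthetic data

The generator emulates a low-density tiling ChIP-chip design: 20,000
probes, one TSS probe for each of 5,743 genes, 2,000 T-T intergenic
probes, two replicates per factor IP and per background strain.  Each
gene draws a true occupancy near its H/L archetype (L = 5%, H = 40%,
gene-level jitter sd 1%, kept on its side of the 10% cutoff); the TSS
probe's expected fold is 1 + κ_f·(occ/100)·(fold_gain − 1) with
fold_gain = 10 (top promoters enrich about tenfold over background) and
κ_f the factor-specific crosslinking scale, which the percent scaling
cancels by construction.  All signals carry multiplicative lognormal
noise (sd 0.1 on the log scale by default), the standard array noise
model.  Two percent of the non-gene probes are planted fully occupied;
this anchor tail pins the observed 99th-percentile fold to the
generator's gain (the rank falls in the middle of the anchor block, so
the percentile estimate is unbiased under noise), making percent
recovery the identity at zero noise and keeping the scaling
non-degenerate.  At noise sd 0.1 the full chain recovers 98–99.7% of
planted H/L patterns over ten seeds.

What the generator does *not* emulate: probe-sequence effects,
crosslinking nonlinearity with occupancy, spatial correlation along the
genome, replicate-specific batch effects, and dye or saturation
artifacts.  Passing tests on synthetic data therefore validate the
pipeline's arithmetic and the planted-structure recovery, not the
biology of any real array dataset.

## Problem sizes

The test suite runs the exhaustive rule/LP grid for n ≤ 3 (55k cells),
1,000 random cells each for n = 4..6, the full three-factor kinetic
chart at 20 restarts, and 10 sampled four-factor kinetic cells; the
acceptance script fits 20 four-factor cells.  These sizes mirror the
desk-scale validation surface: full charts where the method's claims are
exhaustive, seeded samples where they are spot checks.

## Known limitations

* The association order is an external constraint, not inferred; with a
  different fixed association the compatibility pattern changes.
* The rules are complete only for n ≤ 3 (see above); the LP oracle is the
  exact decision procedure for any n.
* The kinetic oracle's E magnitudes depend on the weighting and search
  hyperparameters; only the Boolean classification is meaningful.
* Boolean output by design: no probabilities or rankings over the
  compatible mechanisms.
* The input dialect places the group name after the occupancies; a
  leading-name layout is auto-detected as a fallback on parse failure.
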