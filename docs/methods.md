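# Methods

This note states the models and procedures `lithnet` implements, the
defaults and why they are set where they are, the numerical choices
that matter, and what the synthetic-data tests do and do not show.

## Typology

Artefacts are classified paradigmatically: a type is the ordered
5-tuple (shape, symmetry, edge form, retouch mode, retouch direction),
encoded as the hyphen-joined composite code (e.g. `Tra-As-RCc-A-D`).
The vocabulary is closed — 3 shapes, 2 symmetry states, 6 edge forms,
3 retouch modes, 5 retouch directions, a 540-cell paradigm — and any
out-of-vocabulary code is rejected at ingest with the row and dimension
named.  Encoding is a bijection with the trait tuple; decode∘encode is
the identity over the whole paradigm (property-tested).

**Shared-type filter.** Types observed exactly once in the entire
dataset cannot witness contact between two contexts.  The filter keeps
types with global count > 1 and their records; contexts left with no
records drop out of all later stages.  The filter is applied globally,
over the whole dataset, which is what reproduces the compilation's
published totals; an optional second *within-bin* frequency filter
(`per_bin_min_count`) exists but is off by default, because the global
filter alone accounts for the published per-bin tables.  The filter is
idempotent and conserves counts (kept + singletons = total).

## Calibration and time bins

Calibration is the standard Gaussian-likelihood procedure on a 1-year
calendar grid: for a measured age y ± σ and curve mean μ(t) with error
σ_c(t) (both linearly interpolated to the grid),

    p(t) ∝ exp(−(y − μ(t))² / 2(σ² + σ_c(t)²)) / sqrt(σ² + σ_c(t)²),

normalised to sum to 1 (flat calendar prior).  The "two sigma" set is
the 95.4% *highest-posterior-density* set, accumulated in descending
probability order (a central-interval variant is not provided; the HPD
choice matters only for strongly multimodal dates).  Curve files are
the common 3-column `.14c` dialect (cal BP, 14C BP, error; `#`
comments; either direction, normalised ascending).

**Date filters.** Dates with 1σ error strictly greater than 100 yr and
dates on aggregate material are dropped, each drop logged with the rule
applied.  Preferences among material classes (short-lived over
long-lived) and stratigraphic-association vetting are curatorial
decisions recorded as metadata, not computed.

**Bin rule.** Bins are closed 200-year calendar intervals tiling
8600–6801 cal BP (nine bins, no shared years; labels print older bound
first, `8600-8401`).  For each date the posterior is restricted to its
two-sigma set and renormalised; the context joins every bin holding at
least 35% of that mass for *any* of its dates.  Decisions taken where
the procedure was genuinely open, each switchable:

- *mass base*: two-sigma-restricted and renormalised (default) vs full
  posterior (`restrict_two_sigma=False`);
- *multiple dates*: per-date OR (default) vs AND (`combine="all"`).
  The OR rule is what allows a context with two discordant dates to
  span three consecutive bins.

Assignment is monotone in the threshold (raising it never adds a bin)
and with threshold ≤ 0.5 at least one bin is assigned whenever the
two-sigma mass lies inside the binned range; both are property-tested.

## Similarity

Per bin, records of member contexts are cross-tabulated (levels of the
same site stay separate rows, preserving the site's own diachrony),
binarised (presence ⇔ count ≥ 1), and compared pairwise with the
Jaccard index.  Frequencies are deliberately discarded: they reflect
excavation extent and preservation as much as culture.  A pair with an
empty union is defined to be 0 (it cannot arise after the shared-type
filter, but is guarded).

**Cross-bin normalisation.** Bins with few types in circulation
produce high Jaccard values by chance, so each bin's matrix is scaled
by `n_types(bin) / max_b n_types(b)`.  The linear form is this
package's reconstruction of the diversity correction used in earlier
diachronic network studies: the published descriptions state the intent
(normalise to the most diverse bin) but not the algebra.  The scale
factor is carried in every output, the scaling is strictly monotone
(within-bin structure untouched), and a no-normalisation mode exists
for sensitivity analysis.

## Networks and metrics

One undirected graph per bin; every strictly positive normalised
similarity is an edge with that weight; no threshold filter.  Metrics:

- density 2m/n(n−1);
- global clustering by the triangle method, 3·triangles / connected
  triples;
- APL: mean unweighted shortest-path length over reachable pairs,
  averaged within connected components (required for finite values on
  fragmented bins);
- betweenness: raw (unnormalised) shortest-path pair counts,
  unweighted; eigenvector centrality scaled to max 1.

Topology metrics use the *unweighted* graph while Leiden uses weights;
this split reproduces integer APL on fully connected bins and matches
the common practice of desktop network tools on dense similarity
graphs.

**Communities.** Leiden with the Constant Potts Model at resolution
γ = 0.02, 1000 iterations, 100 restarts (defaults as in the study
design this pipeline follows); the best partition over restarts by raw
CPM objective is returned, with restart seeds derived from the user
seed, so results are reproducible.  The reported normalised quality is
the raw objective divided by twice the total edge weight (the
objective's value on the all-in-one partition of a perfectly cohesive
graph at small γ); this is an approximate convention for a [0, 1]
scale and the raw objective is always also available.  On small graphs
the returned partition is verified against exhaustive search over all
set partitions.

**Node turnover.** For consecutive bins, created = |N_t \ N_{t−1}|,
destroyed = |N_{t−1} \ N_t|, and NTR = (created − destroyed)/|N_t|.
This algebra was chosen because it exactly reproduces the published
turnover values wherever the published node sets are reconstructible
(e.g. (5 − 2)/7 = 0.43 for the earliest transition), and it is exposed
as a plain function so an alternative convention can be substituted.

## Small-world test

The null ensemble is G(n, m) with m = round(density·n(n−1)/2) — fixed
edge count, so every replicate matches the observed density exactly
(an independent-edge G(n, p) mode exists).  1000 replicates by
default; identical seeds give bit-identical ensembles.  σ =
(C/⟨C_rand⟩)/(L/⟨L_rand⟩); for a complete graph every null is the same
complete graph and σ = 1 exactly.  σ is NaN when observed clustering,
null mean clustering, or either APL is undefined.  Null APL on
disconnected replicates averages within components (same convention as
the observed metric); edgeless replicates are excluded from the APL
mean and counted.  The categorical verdict codifies the comparison —
*small_world* (clustering above the null upper quartile, APL ≤ null
mean, σ > 1), *candidate* (clustering above and σ > 1 but APL not
below null — random graphs have short paths per se, so a higher APL
does not rule small-world out), *not_distinguishable*, *undefined* —
with each ingredient reported separately so users can apply their own
rule.

## Bootstrap

Per bin, each context's type counts are redrawn from
Multinomial(n_context, p̂_context) — sample sizes conserved exactly,
composition fluctuating — and the binary → Jaccard → network chain is
rebuilt.  The report gives, per context, the 95% band of its weighted
degree (strength: sum of its similarities), whether the observed value
falls inside, and the fraction of replicates in which its strength
rank stays within ±1 of the observed rank.  The plotted statistic in
earlier applications of this protocol is under-specified; this package
names its statistic (weighted-degree bands and rank stability)
explicitly.  Record-level resampling with replacement is statistically
equivalent to the multinomial redraw and is not separately implemented.

## Synthetic data

The generator emulates the *shape* of a real compilation — 12 sites by
default, 1–2 levels each, per-context counts 1–200, date errors
20–100 yr, one or two dates per context over 8600–6801 cal BP — with
cultural structure planted as regions: each region's type profile is
`c·Dirichlet(region block) + (1−c)·uniform(pool)` over a 40-type pool
drawn from the 540-cell paradigm.  At concentration c = 1 regions
share no types (between-region Jaccard is exactly 0); at c = 0 there
is no structure.  Dates sit on a synthetic identity curve (14C age =
calendar age, 1-yr error), so true bins are known exactly; a real
curve file can be substituted.  Default c = 0.9 gives strong but not
degenerate contrast.

What passing synthetic tests shows: the pipeline recovers planted
partitions when they exist (ARI 1.0 at disjoint repertoires, decaying
to ~0 at uniform profiles), conserves counts, and is deterministic
under fixed seeds.  What it does not show: robustness to the features
of real data the generator omits — taphonomic loss, curve plateaus and
multimodal calibrations, spatially autocorrelated sampling, types
shared through descent rather than contact, and research-intensity
bias between regions.

## Problem sizes and numerical notes

Test-suite simulations use reduced replicate counts (tens to hundreds)
and small graphs; the ensemble-convergence check uses 10⁴ replicates at
n = 50, where the G(n, m) transitivity mean matches density to < 0.01.
Defaults in `RunConfig` (1000 null replicates, 1000 bootstrap
replicates, Leiden 0.02/1000/100, threshold 0.35, σ-cutoff 100,
200-year bins over 8600–6801) are the study-design values and are all
echoed into the run manifest.  Ties in degree ranks are handled by
average ranks; HPD ties at the 95.4% boundary include the boundary
year; bins that end with fewer than two contexts are skipped with a
logged warning rather than producing degenerate networks.

## Known limitations

- The cross-bin normalisation algebra is a reconstruction (see above);
  conclusions sensitive to it should be re-run with normalisation off.
- The Leiden "quality" scale is a convention, not a calibrated
  statistic; compare raw CPM objectives across partitions of the *same*
  graph only.
- Bin membership from printed per-level time frames (the bundled
  summary table) under-determines bins where membership followed from
  individual dates; the per-date pipeline is authoritative when the
  full dataset is available.
- No spatial model: edges are cultural similarity only, and
  distance-decay or geographic confounds must be assessed externally.
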