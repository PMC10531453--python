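# Methods

## The scoring model

Each target is represented by a *descriptor template*: per molecular
descriptor, the mean and standard deviation over a set of known
high-affinity inhibitors. The training set is defined by a strict activity
cutoff (default IC50 < 100 nM; all activity arithmetic happens in nM after
unit conversion at ingest, strict `<` at the boundary).

Candidate scoring uses a Gaussian kernel per descriptor,
`s_j = exp(−z_j²/2)` with `z_j = (x_j − μ_j)/σ_j`, and aggregates the `Z`
largest `s_j` by arithmetic mean. The parameterization is the standard
(N, Z, G) triple of descriptor-template screening engines: `N` descriptors
retained in the template (default 500), `Z` best per-candidate scores
aggregated (default 50), `G = a` the arithmetic mean. The exact functional
form used by proprietary web servers of this kind is unpublished; the
kernel-plus-top-Z form was chosen because it respects the documented
(mean, SD) template structure, the [0, 1] score range, and the (N, Z, G)
parameterization, and is monotone in every |z_j| it uses — each of which
is property-tested. Absolute DAS values from other engines are therefore
not reproduced, only the score's contracts and ranking behavior.

Design choices inside the template:

* **Descriptor selection.** Descriptors are ranked by ascending
  coefficient of variation `σ/(|μ| + 1e−9)` across the actives — the
  descriptors a congeneric family agrees on are its most characteristic —
  with lexicographic name tie-breaks for determinism. Descriptors missing
  for more than 50% of the actives are dropped before ranking, since a
  (mean, SD) couple from a minority of molecules is unstable.
* **SD flooring.** `σ_j ← max(σ_j, r·max(|μ_j|, 1))` with `r = 1e−3` by
  default. A descriptor constant across the actives is *retained* (a
  candidate matching the constant scores 1 on it, which is informative)
  rather than dropped; the floor keeps its z-score finite. Constant
  descriptors have CV 0 and so rank first — intended, as they are the most
  conserved.
* **Population SD** (ddof = 0): the template describes the training set as
  a population, not as a sample from a larger family.

## Descriptor engine

The default `2D+3D` configuration emits 1314 columns per molecule: the
full RDKit 2D descriptor list and 2D autocorrelations, plus 3D
autocorrelations, RDF, MoRSE, WHIM, GETAWAY and principal-moment shape
descriptors computed on a single conformer (seeded ETKDGv3 embedding,
MMFF94 minimization). Computing 3D descriptors on a ligand-only conformer
rather than a receptor-bound pose is a deliberate scope decision: the
package performs no docking, so 3D descriptor values differ numerically
from pose-based pipelines while every downstream contract (template
structure, score range, ranking) is unaffected. Descriptors that fail for
a molecule (degenerate geometry, undefined value, failed embedding) are
recorded as missing, never as zero; infinities are coerced to missing at
matrix construction. A `2D`-only mode (402 columns) exists for speed.

## Multitarget screening

`MScore` is the product of per-target DAS values, generalized to any
number of targets (≥2). The selection threshold defaults to the MScore of
reference inhibitors and the comparison is inclusive (`≥`), so the
references pass their own bar; ranking ties break by compound id.
`retain_fraction` keeps `floor(f·n)` items, minimum 1 — the fraction rule
a rank cascade applies at each step — with explicit score polarity
(`higher`/`lower`) so it covers similarity scores and docking energies
alike.

## The matching statistic Φ

Both panel vectors are mean-centered and scaled by the maximum absolute
deviation; a constant vector normalizes to zeros (with a warning) and
annihilates Φ. Raw GI50 is a concentration, so the default ingest
orientation for it is `negated_log10` (−log10 of the molar value before
normalization), making positive Φ mean "more potent where the target is
more expressed"; `as_is` covers inputs already on a potency scale.

Mathematically Φ ∈ [−L, L] for an L-line panel. Raw Φ is reported by
default because aggregation (max over experiments, mean over targets) is
unaffected for positive matches and the sign carries information; a
`clamp_negative` mode floors Φ at 0 for conventions that treat
anti-correlation as "no match". Cell lines missing in either vector are
dropped pairwise (logged), which bounds Φ by the retained count. Per-target
values are maxima over that target's expression experiments; the
cross-target mean is reported at full precision, with round-half-up
integer display (so maxima 25 and 28 display as 27).

## Synthetic data

The generators are pure functions of their spec, seed included.

* **Descriptor populations.** Actives are drawn per-descriptor from
  `Normal(μ_j, σ_j)` (defaults: μ_j ~ U(−5, 5), σ_j ~ U(0.5, 2), 1000
  descriptors, 200 actives + 200 decoys); decoys share the distributions
  except that a random half of the descriptors (by default) has its mean
  displaced by 3 active SDs in a random direction. This emulates a
  congeneric family versus a background library that drifts on part of
  descriptor space. What it does not emulate: real descriptor
  correlations, non-Gaussian tails, and the discreteness of count-valued
  descriptors — so passing enrichment tests demonstrates the scoring math,
  not performance on any particular chemical library. Under these
  defaults, template-based ranking separates actives from decoys with
  AUC ≈ 0.999 even though decoys score high absolutely (the top-Z
  aggregation finds each decoy's unshifted descriptors); enrichment relies
  on the small but consistent gap in the top-Z order statistics.
* **Cell panels.** Per target, a latent pattern `z` over the lines
  (standard normal, or a balanced ±1 two-level option); expression
  experiments are `z` plus Gaussian noise (default SD 0.25, 16 and 8
  experiments for the two default targets); the compound potency pattern
  couples to one designated target's latent at concordance ρ:
  `potency = ρ·z + √(1−ρ²)·ε`. With the two-level latent, ρ = 1 and zero
  noise, Φ attains its saturation value L exactly. Since a single
  compound has one potency vector, it couples to the *first* target by
  default and other targets' latents are independent — the simplest model
  that exercises per-target aggregation.

## Numerical and interface choices

* All generated randomness flows through `numpy.random.default_rng(seed)`;
  repeated runs are byte-identical, which the suite asserts at file level.
* Template and matrix CSVs are written with shortest-repr floats, so a
  write/read round-trip is lossless to full float64 precision.
* Every CLI command echoes its configuration and the SHA-256 of each input
  into `run_manifest.json` beside its outputs; logs go to stderr, data
  only to files.
* Test problem sizes: statistical tests use 200-replicate panels and
  200+200-molecule populations over 1000 descriptors; chemistry smoke
  tests use the built-in 20-molecule fixture. These sizes give
  Monte-Carlo error comfortably below the tested margins while keeping the
  default suite fast.

## Known limitations

* DAS values are not comparable across engines with unpublished scoring
  functions; only within-run rankings and contracts are meaningful.
* The Gaussian-kernel/top-Z interpretation of (N, Z, G) is one reasonable
  reading of a family of proprietary engines; alternative semantics (e.g.
  global descriptor standardization before template building) would change
  absolute scores.
* The matching statistic is a concordance screen, not causal evidence: a
  high Φ is consistent with, but does not establish, target-mediated
  activity.
* The 60-line panel statistic depends on the identity and number of
  expression experiments; with public panel data of unknown experiment
  provenance, absolute Φ values cannot be independently re-derived — only
  the statistic's mathematical properties can.
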