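# Methods

This note records the models the package implements, the defaults and why
they were chosen, and what the synthetic-data tests do and do not show.

## Dated trees and polytomy grafting

Trees are held as `dendropy.Tree` objects.  A tree is *dated* when all
root-to-tip path lengths agree; the default tolerance is 1e-9 relative to
the root depth, relaxed to 1e-6 by `force=True` for inputs with harmless
rounding drift.  `scale_root_age` multiplies every branch by
`target / depth`, so national analyses can work on a common root age of 1.

`graft_congeners` expands each genus-representative tip into a polytomy of
its congeners.  The polytomy node's age is
`min(attachment_age / 2, Q_q(genus ages))`, where a tip's *genus age* is
defined as the age of the node its pendant branch attaches to (the stem
age; the only age intrinsic to a genus represented by a single tip), and
the quantile `Q_q` (default q = 0.8, type-7 linear interpolation) is taken
over the genus ages of **all** tips, not only the expanded ones.  The
half-way rule bisects the pendant branch; the quantile cap stops isolated
representatives (very old attachment ages) from granting their congeners
inflated distinctiveness.  Genera listing a single species are relabelled
in place.  Tip-to-genus matching uses the `Genus_species` underscore
convention, configurable by regex.  The output is checked ultrametric.

Robustness: on simulated backbones (60 genera, half expanded into 2–5
species), ln(ED) computed after cutting at quantiles 0.5–0.99 correlates
above 0.95 with the 0.8-quantile values.  ln(ED) is used because it is the
scale on which distinctiveness enters every measure; raw ED, dominated by
a few long-branch species on small simulated trees, is more sensitive.

## Fair-proportion evolutionary distinctiveness

`fair_proportion` distributes each branch's length equally among its
descendant tips in one pre-/post-order pass; tests compare it against an
independent brute-force enumeration.  The root edge, which subtends every
tip, is excluded by default (`include_root=True` reverses this).  ΣED
equals the total branch length (conservation identity, asserted to 1e-9
relative).  Polytomies are handled directly by the fair-proportion rule; a
multiplicative polytomy-correction hook exists but is not implemented
because no closed form is published for the variant used in legacy ED
software, and silently guessing one would be worse than none.
`log_ed` defaults to plain `ln(ED)`; `add_one` (ln(1+ED)) exists for
compatibility with early EDGE lists but badly skews values on root-age-1
trees, so it is off.

## Magnitude of decline

The relative change index regresses logit occupancy proportion in the later
period on the earlier one (statsmodels OLS) and takes residuals, negated by
default so larger = steeper decline relative to the assemblage.  Boundary
proportions (0 or 1 occupied cells) raise an error naming the species;
`adjust=True` applies the empirical correction `(k + 0.5) / (N + 1)` to all
species, never silently to some.  Period-specific cell totals are allowed
with a logged warning.  Red List categories map to the coarse integer scale
LC=0, NT=CD=1, VU=2, EN=3, CR=4 (IUCN 2001 vocabulary, case-insensitive,
"LR/cd" accepted); categories outside that scale are rejected.  The original
variance-weighted form of the change index is deliberately out of scope —
the plain-residual form is what national prioritisation practice uses.

## Temporal-validation accuracy

`Acc_TV = 1 − Σ w_q |ŷ(x_q) − x_q| / Σ w_q`, with `x_q` the change in
modelled probability of presence at site q, `ŷ` a least-squares natural
cubic spline (patsy `cr` basis, default 3 df) of observed change
`o_q ∈ {−1, 0, +1}` on x, and weights `w_q = |x_q|`.  The weight choice
concentrates the score on sites observed or predicted to change; it makes
the score invariant to duplicating sites and gives the exact value 0.5 for
a flat curve evaluated at x = ±0.5.  The spline basis contains linear
functions, so a perfectly calibrated model (conditional mean of o equal to
x) attains Acc_TV = 1 up to least-squares precision.

Directional variants restrict the fit to sites with predicted loss
(x < 0) or predicted gain (x > 0).  Masking on predicted change only is a
deliberate design choice: conditioning on the observed initial state breaks
the calibration identity (on occupied sites E[o|x] = x − (1 − p1)), which
would bias directional accuracy by range size — in simulation the
obs-conditioned variant correlates ≈ 0.8 with decline itself rather than
with prediction noise.  The headline A component pools both directions,
where the identity holds exactly and the estimate is least noisy; the
gain-direction score feeds EDAM′.  Species whose masked subset has fewer
than df + 2 distinct x values get NaN and are dropped listwise.

## Measures

Components are z-scaled with the sample (n−1) standard deviation.  A
`MeasureSpec` lists signed, weighted terms over {ED, M, A, A_GAIN, GE} and
a combiner (`sum`, or `ed_plus_max_of_rest` for precautionary measures).
Sign convention: M is already reversed (decline positive), and A enters
negated in EDAM so that *low* prediction accuracy raises priority; the sign
is overridable term by term.  EDGE is the unscaled `ln(ED) + GE`.  Ranks
are descending min-ranks; ties are exact equalities after rounding scores
to 12 decimal places (the tie count is reported, since coarse components
such as GE tie congeners).  Missing components drop species listwise with
a report in `DataFrame.attrs["dropped"]`; nothing is imputed.

## Phylogenetic uncertainty and mapping

`scores_over_trees` reruns graft → rescale → ED → measure → rank on every
tree of a set and returns per-species score and rank matrices; summaries
report median rank, rank s.d., mean score, and a likelihood-weighted mean
using softmax weights `exp(logL − max logL)`.  `topk_cell_counts` counts
top-k species per grid cell with boundary ties included (an excluded tie
would make the map depend on arbitrary ordering); `mean_cell_score`
averages present species' scores, NaN for cells with none.

## Synthetic studies

`simulate_study` generates: a pure-birth (Yule) backbone of `n_genera`
tips (dendropy `treesim`, tip branches extended by the Exp(nλ) waiting
time to the next unobserved split so no pendant has zero length, then
snapped exactly ultrametric and scaled to root age 1); a random
genus→species assignment (every genus keeps ≥1 species); occupancy with
species-level baseline logit p1 ~ N(−0.5, 0.8), cell suitability N(0, 1),
and logit p2 = logit p1 + δ with per-species decline δ ~ N(0, 1);
distribution-model predictions whose first-period probabilities are the
truth and whose second-period probabilities carry Gaussian noise of s.d. σ
(probability scale, clipped to [0, 1]); Red List labels from quantiles of
−δ (80/90/95/99th → NT/VU/EN/CR, rest LC); and a presence grid from the
second-period occupancy draws.  Default sizes — 50 species, 20 genera, 500
cells — are a scaled-down national atlas (a real one has a few thousand
10-km cells and ~10³ species).  `prediction_noise` accepts a per-species
vector because recovery tests need species to differ in how predictable
they are.  Occupancy draws are nudged off 0 and N so every species stays
analysable, matching real analyses that only include species observed in
both periods.

What the generator does *not* emulate: spatial autocorrelation, recording
effort, detection error, or any dependence between a species' position in
the tree and its decline.  Passing tests therefore show the estimators
recover the processes they target under clean conditions, not that the
measures are robust to survey artefacts.

`jitter_trees` emulates credible-tree sets by multiplying internal-node
*ages* by log-normal noise (scale ε), capping children at their parents'
ages and renormalising to root age 1.  Ages rather than raw branch lengths
are perturbed so every replicate remains dated, as rate-smoothed bootstrap
trees are; ε = 0 yields bitwise-identical copies, which the degeneracy
tests exploit.

## Numerical choices and limitations

- Ultrametricity: 1e-9 relative (strict) / 1e-6 (forced); grafting refuses
  polytomy ages ≤ 0.
- Spline fits use `numpy.linalg.lstsq`; fits are deterministic and
  permutation-invariant.
- Tie detection rounds to 12 d.p.; scores differing only at 1e-13 are ties.
- The parameter-recovery benchmark (EDAM score vs the z(−δ) + z(σ) truth
  composite, 50 species, 100 seeds) plateaus near rank correlation 0.73:
  the ED term is independent of the truth composite by construction and
  dilutes the attainable correlation (≈ 0.82 even with perfect M and A
  recovery), and Acc_TV estimates from 500 sites carry sampling noise.
- Likelihood weighting assumes comparable log-likelihood scales across
  trees; wildly different scales reduce to a single-tree answer by design.
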