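# Methods

## The problem being modelled

Real-time PCR with degenerate primer sets is routinely used to quantify
functional marker genes — here the dissimilatory sulfite reductase beta
subunit (*dsrB*), the standard marker for sulfate-reducing
microorganisms — in environmental DNA. When the target gene occurs as a
mixture of sequence variants, two community properties bias absolute
quantification: *evenness* (how the relative abundances are
distributed across variants) and *dominance* (whether the abundant
variants are ones the primers bind well). This package implements the
complete in-silico machinery for studying that bias: degenerate-primer
coverage analysis, designed mock template mixtures, a synthetic
amplification-curve generator standing in for the qPCR instrument,
Cy0-based absolute quantification, and the comparison statistics.

## Primer matching (`primer_match`)

A degenerate primer is an IUPAC string; its *degeneracy* is the number
of concrete oligos it encodes (product of per-position ambiguity-set
sizes), and a mix's degeneracy is the size of the deduplicated union of
its members' expansions. A template position *matches* when its base is
inside the primer position's IUPAC set — primer ambiguity is coverage,
never a mismatch — and a mix's mismatch count at a window is the
minimum over members (any oligo in the tube can prime). The search is
ungapped, every position is weighted equally (a per-position weight
hook exists for 3'-end studies but defaults to uniform), and
coordinates are 0-based half-open on the plus strand. A template is
*amplifiable* by an assay at tolerance `max_mm` (default 1, the
standard "0 or 1 MM" screening criterion) when a forward and a reverse
site exist in convergent orientation, each within tolerance; among
candidate pairs the minimal-total-mismatch, outermost pair is reported.
Templates are grouped by assay coverage: amplifiable by all assays →
"common", exactly two → "less common", exactly one → "rare".

## The synthetic assay panel (`synthetic_assay`)

The specific assay's primers (DSRp2060F, DSR4R) are the published
sequences; the two degenerate mixes and all twelve 390-bp gBlock
templates are synthetic stand-ins engineered to the documented design
constraints — mix degeneracies 4/1, 77/10, 98/29; per-assay coverage
7/8/9 of 12; a 4/4/4 common/less-common/rare Venn partition; rare
dominants named gb03/gb06/gb07. Mix members differ concretely at their
first position so the union degeneracy is exactly the sum of member
degeneracies. Binding sites (a handful deliberately carrying one
mismatch) are planted into seeded random backgrounds, and the generator
verifies each template's membership pattern with the package's own
matcher, redrawing the background on the (vanishingly rare) accidental
hit. The panel is a fixed reference object: its internal seed is a
constant, not a user parameter.

What the panel does *not* emulate: real phylogenetic sequence
covariance (backgrounds are i.i.d. random), GC-content effects,
secondary structure, and the actual supplementary-table sequences.
Tests passing on this panel demonstrate the machinery's correctness and
the designed coverage structure, not sequence-level conclusions about
real *dsrB* diversity.

## Mixture design (`mixture_design`)

Relative abundances follow LogNormal(μ, σ) with μ = 1 and σ ∈ {1, 2, 5}
(natural-log parameterization). Rather than random draws, the n = 12
fractions are taken at the midpoint quantiles (i − 0.5)/n and
normalized: designs are then exactly reproducible and Pielou evenness
J = H/ln n decreases strictly and monotonically in σ (J = 1.000, 0.843,
0.555, 0.114 for σ = 0, 1, 2, 5). A seeded random-draw mode is kept for
sensitivity analyses. Dominance assigns the largest fractions to the
named group ("common" or "rare"), then down the group priority; within
a group the order is a seeded permutation, or an explicit pinned
ranking for the packaged scenarios (mirroring how a wet-lab design
would fix its compositions in a table). The grid is 2 dominance × 3 σ ×
2 concentrations (high 10⁸, low 10⁵ copies/μL; 1 μL of template per
reaction), richness fixed at 12. Copy budgets are exact by default;
seeded Poisson rounding is available to model low-template sampling
stochasticity.

## Theoretical model (`theory_model`)

Strictly binary: members with ≤1 mismatch per primer amplify at 100%
efficiency, members beyond that not at all. The theoretical template
amplification percentage is 100 × the summed abundances of amplifiable
members — concentration-independent by construction. Assay pairs are
compared by percentage ratios with a boundary-inclusive four-fold rule
(ratio ≥ 4 or ≤ 1/4); raw ratios are always reported so either boundary
convention is auditable. A zero denominator leaves the ratio undefined
rather than infinite.

## Fluorescence simulator (`qpcr_synth`)

The kinetic model is the package's own choice (no instrument model
exists to copy): per cycle each template pool grows by
`N ← N (1 + E · s)` with shared saturation
`s = max(0, 1 − ΣN / K)`, i.e. a logistic plateau over a common
resource pool of capacity K (default 10¹¹ molecules). Fluorescence is
`scale · ΣN + baseline + drift · cycle + Gaussian(0, noise_sd)` with
defaults scale 3×10⁻⁸ per molecule (≈3000-unit plateau), baseline
100 + 0.5/cycle, noise SD 15 (≈0.5% of plateau amplitude), 35 cycles.
This model was chosen because it yields Richards-shaped curves and a
log-linear Cy0-vs-log₁₀(copies) calibration — the two properties the
downstream analysis requires — while capturing resource competition in
mixtures (fast-amplifying members crowd out slow ones at plateau, as in
real multi-template PCR).

Efficiency classes: clean match E = 0.95, one mismatch E = 0.6, blocked
E = 0; the template-level class is the worse of the forward and reverse
best-hit mismatch counts, consistent with the per-primer screen. The
one-mismatch default is a free parameter: real one-mismatch behaviour
is idiosyncratic, so scenario override tables keyed by (template,
assay), not constants, carry per-template truth. The packaged
"low-efficiency rare" scenario sets E = 0.5 for the three rare-group
templates bindable only by a degenerate assay; against a
perfect-efficiency standard curve that lands their recovery in the
few-percent range. High-template inhibition is deliberately not
modelled.

## Cy0 quantification (`cy0_quant`)

Curves are fitted to the 5-parameter Richards function
F(x) = Fb + Fmax/(1 + exp((c − x)/b))^d by bounded nonlinear least
squares (data-driven initialization: Fb from the early-cycle median,
Fmax from the range, c at the max-slope cycle, b from the logistic
max-slope relation Fmax/(4b), d = 1; up to 5 seeded jittered restarts;
10⁴ evaluation cap; 10⁻¹⁰ tolerances). Curves whose amplitude never
exceeds ~10× the early-cycle noise are reported as no-fit, not an
error. The inflection is at x* = c + b ln d; the tangent there, drawn
on the baseline-subtracted signal, crosses the baseline at

    Cy0 = c + b ln d − b (1 + 1/d),

which is parameterization-independent geometry (asserted against a
numeric tangent construction to 10⁻⁶ cycles). Standard curves are OLS
of Cy0 on log₁₀(copies) over the 7-level, 3-replicate series
2.34×10²…2.34×10⁸ copies/μL (0.1 ng of a 390-bp dsDNA is 2.34×10⁸
copies via m·N_A/(L·660·10⁹)). The detection limit rule — no numeric
rule exists to copy — is the lowest level with 100% converged fits and
monotone mean-Cy0 ordering above it. Unknowns are quantified as
10^((Cy0 − intercept)/slope), extrapolation beyond the calibrated range
flagged; replicate copy estimates are combined on the log₁₀ scale.

## Comparison statistics (`compare_stats`)

All tests run on log₁₀ copy numbers (qPCR error is multiplicative).
Theory-vs-empirical uses a one-sample t-test of replicate log-quants
against the log of the theoretically expected copies; assay-vs-assay
uses a paired t-test, paired by replicate index. Zero-variance
degeneracies return the limiting p (1 at the reference, 0 off it).
Benjamini–Hochberg adjustment (delegated to statsmodels, verified
against the step-up definition) is applied within each report panel —
one family per figure-analogue panel and concentration condition, the
most conservative partition consistent with per-family adjustment; the
partition is visible in the report keys. A comparison is *significant*
only when p_adj < 0.05 **and** the quantities differ at least four-fold
(boundary inclusive).

## Problem sizes and runtime

The packaged study grid is 12 mixture conditions × 3 assays × 3
replicates plus 3 × 21 standard wells — about 170 Richards fits, a few
seconds end to end. Property tests use 40-pair brute-force matcher
oracles (templates ≤ 300 nt, primers ≤ 25 nt), 1000-vector BH checks
and 1000-seed Poisson unbiasedness checks; the whole suite runs in well
under a minute.

## Known limitations

* The theoretical model's binary amplify/not-amplify assumption is the
  point of the comparison, not a belief about chemistry.
* Constant per-cycle efficiency before the plateau; no per-cycle drift,
  melt behaviour, probe chemistry or inhibitors.
* The synthetic panel reproduces the *structure* of the real gBlock
  panel, not its sequences; quantitative agreement with wet-lab copy
  numbers is out of reach by construction, and the pipeline's empirical
  claims are therefore qualitative pattern reproductions.
* Detection-limit differences between assays (10² vs 10³ copies/μL in
  the real system) are not reproduced: all assays share one standard
  template and noise model, so all reach the lowest simulated level.
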