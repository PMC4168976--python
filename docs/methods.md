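# Methods

## Data model and filters

Coordinates are 0-based half-open. A TA site is identified by the
plus-strand position of its T; insertion records reported at the T or the
A of the duplex collapse onto the same site, since the transposon targets
the duplex. Retained insertion records must map uniquely, carry at least
8 reads summed across the library samples, and coincide with a TA site;
discards are tallied by reason with precedence non-unique → non-TA →
low-count, so a planted non-TA fraction is recovered exactly regardless of
the read-depth distribution. All four samples are combined by union: a
site is "inserted" if any retained record hits it, and a gene's observed
count t_obs is its number of inserted core sites (site occupancy, not
read-weighted events — the probability model describes occupancy).

Core sites exclude (a) TA loci covered by two overlapping genes, which are
removed from the dataset entirely, and (b) the terminal 2% of each gene's
length at the 3′ end, where insertions frequently leave a functional
truncated protein; the 5′ end is not trimmed. Sites whose 6-mer context
contains N (possible only on linear test genomes, within 2 nt of an end)
stay countable but drop out of motif statistics and fall back to the mean
class rate.

## Multiplicity correction

The same site can be hit by several independent colonies. Under Poisson
occupancy with per-site rate λ = m/n, the untouched-site count has
expectation n·e^(−m/n), so the event (colony) count is recovered from the
unique-site count u by m = −n·ln(1 − u/n). This inversion is applied
genome-wide, per sliding window for the location fit, and per motif class.
It assumes a *homogeneous* rate within the pool being inverted; with a
10-fold motif spread this understates the event count by a few percent
(Jensen's inequality), which is why the model's expected unique-site total
sits slightly below the observed count in the self-consistency check. The
same approximation is inherent to the procedure being reimplemented.

## Location bias

Insertion frequency (events per site) is computed in 20 kb windows
stepped by 2 kb (windows wrap around the origin on circular chromosomes;
saturated or empty windows are skipped with a warning) and fitted by
ordinary least squares with f(x) = a·x² + b·|x| + c, x the signed distance
from the chromosome midpoint in Mb. This is the convention under which
the published coefficients (0.0032, 0.0081, 0.1615) put ~25% more
insertions at the origin than at the midpoint of a 5 Mb chromosome.
Because adjacent windows share 90% of their sites, naive OLS standard
errors are optimistic; reported SEs are inflated by √(window/step).
Location weights are f(x)/norm with norm the mean of f over all analysed
sites, so weights average exactly one. f is clamped at zero when
evaluated.

Colony placement fixes only relative rates, so a planted polynomial is
identified up to scale; recovery is assessed on the fitted polynomial
rescaled to the planted mean over sites, within 3 fitted SEs for a single
stochastic draw.

## Motif bias

Flanking 6-mers (2 nt on each side of the TA) are collapsed over strands
to the lexicographically smaller of {context, reverse complement}: 136
classes, 16 palindromic. Class rates are estimated only on genes whose
insertion counts are compatible with the genome-mean rate (binomial lower
tail > 0.1, single pass), so essential-gene depletion does not contaminate
the spectrum. Per class, the zero-truncation inversion gives a rate
m_j/n_j; its variance is the binomial occupancy variance pushed through
the inversion by the delta method, with the rule-of-three surrogate
p = 3/n_j for classes without insertions so χ² weights stay finite.

The independence test models each class rate as a global scale times the
product of per-position nucleotide contributions, symmetrised over the two
strand orientations (a class covers both). Contributions are identifiable
only up to scale; each position's four factors are normalised to mean one.
The weighted least-squares χ² is referred to a χ² distribution with
136 − 13 degrees of freedom. The exact multinomial variance of the
original analysis is not recoverable; the per-class binomial approximation
is used instead.

## Essentiality calling

Per-gene Poisson-binomial PMFs are built by exact iterative polynomial
multiplication of (1 − pᵢ + pᵢx) — O(s²), exact to machine precision for
s in the thousands, and reducing to the binomial for equal pᵢ. E = Σpᵢ,
V = Σpᵢ(1−pᵢ), NDE = (E − t_obs)/√V.

Cutoff calibration: for a candidate cutoff c, a gene's marginal false-call
probability is the cumulative probability at the most extreme count still
called (statistic strictly < c; ties are not called). The sum over genes
is a monotone step function of c; bisection (tolerance 1e-12, step
function evaluated exactly) finds the largest c with sum ≤ 1 expected
false call. The 1/n_genes heuristic is reported alongside but calibration
always uses the summed-marginals procedure. Nonessential calling scales
every site probability by ρ = Σt_obs/ΣE over essential calls (capped at
1) and calibrates the upper tail the same way, summing marginals over all
genes. Genes with zero core sites are unknown; genes whose strongest
possible evidence P(X=0) cannot reach the cutoff are marked not callable.

Known properties of ρ̂ at realistic library depth: the occupancy
convexity of residual insertions pushes the observed/expected ratio above
the planted residual rate, while conditioning on the called set (selected
for few insertions) pushes it below; at the default study scale the net
estimate is ~0.06–0.08 for a planted 0.1.

## Monte Carlo validation

Null libraries are simulated at the site level (independent Bernoulli per
site with its model probability) — equivalent to multinomial colony
placement at the occupancy level and much cheaper; the colony-level
sampler lives in the synthetic module for end-to-end tests. The NDE
histogram uses 61 fixed bins on [−6, 6] with overflow clipped into the end
bins (the original figure's binning is not stated; this is a package
choice), reporting per-bin observed counts, simulated mean and n−1 SD.
One master seed spawns per-replicate seeds deterministically.

## Operon polar screening

A transcriptionally terminated transposon silences downstream operon
genes, so an essential call is retained only if the gene is
operon-terminal or its immediately downstream neighbour is called
nonessential; an unknown neighbour does not rescue (conservative choice —
the original rule does not state this case). Genes absent from every
operon are monocistronic. Nonessential calls are never flagged.

## FBA comparator

Models are stoichiometric networks in a small JSON schema (SBML is out of
scope; the comparator accepts any model of this shape). Growth maximises
biomass flux under Sv = 0 and bounds, solved with HiGHS via
scipy.optimize.linprog; infeasible problems report zero growth. Media are
uptake bounds on exchange reactions (export convention: uptake bound b →
lower bound −b; unlisted exchanges are closed for uptake — units are the
caller's responsibility). GPR rules are parsed with cobrapy's GPR parser
and evaluated with deleted genes false; a gene is essential when its
knockout keeps < 1% of wild-type growth, with the < 1e-6 zero-growth call
reported alongside. Blocked reactions are those whose maximum |flux| in
either direction is < 1e-9. Constraint relaxations: `free_endpoints` adds
an export reaction per metabolite; `no_thermo` makes every reaction
reversible with symmetric bounds; `both` composes them
(order-independent). Confusion tables count call × prediction agreement
with integer percentages rounded half away from zero.

## Synthetic data generator

The generator emulates the structure of a real miniHimar experiment:
i.i.d. sequence with P(T) = P(A) = √(TA density) (default 0.03, ~150,000
sites on 5 Mb); log-normal gene lengths (mean 950 bp) packed without
overlap; geometric operon sizes with shared strand; a planted location
polynomial (default the published coefficients); a per-class motif
spectrum power-rescaled to an exact fold spread (default 10×) and unit
mean; essential genes (default 10% of genes) whose core sites carry the
residual rate ρ (default 0.1) while their terminal 2% stays fully
insertable; colonies placed multinomially (default 40,000); a 5% non-TA
colony fraction; log-normal per-clone read counts (meanlog 5, sdlog 1 —
a deeply sequenced library in which the ≥8-read filter removes ~0.2% of
clones, so read depth does not confound bias recovery; the original
read-depth distribution is unpublished) split across 4 samples. All
randomness flows from one seed; the truth manifest records every planted
parameter.

What it does **not** emulate: mapping errors and multi-mapping structure
(non-uniqueness is a flat planted rate, default 0), sequence composition
beyond i.i.d. (no codon structure, no TA depletion patterns), fitness
effects on read counts, bottlenecks during library expansion, and
real operon boundaries. Passing recovery tests therefore demonstrates the
estimators' correctness under the stated generative model, not robustness
to those real-data features.

## Problem sizes and known limitations

Tests and the acceptance script run the full analysis at study scale
(5 Mb, 4,200 genes, ~150,000 TA sites, 40,000 colonies, ~2,500 windows,
1,000-replicate NDE envelopes scaled to 200–300 where only the mean is
needed); the complete pipeline takes a few seconds.

At that library depth a gene needs roughly s·λ ≳ 8 expected insertions
(~45 TA sites at λ = 0.267) before even a zero count can clear the
one-false-positive cutoff, and essential genes still receive residual
insertions; sensitivity for planted essential genes with ≥ 20 TA sites is
therefore ~35–40%, not a deficiency of the implementation but the
information limit of a 40,000-colony library spread over 4,200 genes —
consistent with the original study calling only a minority of genes
essential and leaving ~40% unknown. Doubling the colony count at fixed
genome size pushes sensitivity toward 1 (the small worked example, at
20 events/kb, recovers 29/30 planted essentials).
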