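# Methods

## Scope and data model

`cytocin` implements the analysis pipeline of a two-group occupational
cytogenetic biomonitoring design: a cohort of pesticide-exposed individuals
and a matched unexposed group, characterised by (i) GTG-banded metaphase
karyotypes written in an ISCN-2020 subset and (ii) per-nucleus centromeric
FISH signal counts for chromosomes 2, 3, 8, 11, 15 and 17. Three layers sit
on top of the raw records:

1. **Aberration profile** — per-metaphase event classification, clonal vs
   non-clonal calls, and the carrier/frequency tables compared between
   groups.
2. **Chromosomal instability (CIN)** — the fraction of nuclei deviating
   from the population's modal signal count, per chromosome and averaged.
3. **Clonal heterogeneity (CH)** — Shannon diversity H and true diversity
   TD = e^H over clone abundances.

Because the motivating study deposited only printed summary tables (no
per-metaphase or per-nucleus raw data), the package carries a synthetic
cohort generator whose defaults emulate the published study conditions, and
bundles the printed summary counts (`cytocin.reference`) as validation
inputs.

## ISCN subset

The parser covers the vocabulary attested in constitutional biomonitoring
reports: whole-chromosome gains/losses (`+22`, `-20`, `+mar`), `del`, `dup`,
`inv`, `t`, `dic`, `add`, `der`, `i`, `r`, fragile sites (`fra`),
chromatid/chromosome breaks (`chtb`/`chrb`) and the heterochromatic variants
`1qh+`, `9qh+`, `16qh+`. Mosaicism slashes, stemline shorthand and `?`
qualifiers are rejected with an error naming the offending span: for scope
control, refusing is safer than guessing. Canonical formatting inverts
parsing exactly (`parse(format(r)) == r`), which the suite checks on every
simulator-generated record.

Two decisions deserve a note:

* **Pericentric inv(9)** (one p- and one q-arm breakpoint) is categorised as
  a heteromorphism (`cv_inv9`), not a structural alteration, matching its
  treatment as a variant row in the frequency tables. Paracentric
  inversions of chromosome 9 and all inversions of other chromosomes remain
  structural. Both `inv(9)(p21q21)` and `inv(9)(p21q22)` are accepted; no
  attempt is made to decide which spelling of the recurrent inversion is
  intended.
* **`45,X` is ambiguous on its own.** The parser records the complement
  verbatim; the classifier resolves the lost homolog against the
  individual's constitutional sex (XY loses Y, XX loses an X), which is the
  only place that information exists.

## Classification and clonality

Tally categories follow the frequency-table layout: monosomies, trisomies
(marker-chromosome gains included, as the tables place them), SCAs,
chtb/chrb, fragile sites other than 9q12, the common fra(9)(q12), and the
four variant categories. A chromosome count inconsistent with the listed
events raises a warning and the explicit events are kept — the count is
treated as derived, the events as primary.

Clonality uses the standard clone definition: an identical structural
aberration or identical gain in ≥ 2 metaphases of one individual is clonal
(CCA), an identical loss needs ≥ 3, everything rarer is non-clonal (NCCA).
The source material uses CCA/NCCA language without stating thresholds; the
community convention is adopted. Breaks, fragilities and variants are
tallied per occurrence and never receive clonality calls.

Percentages are rounded half-up: 1 decimal for carrier tables, 2 decimals
for the per-pair event table, whose denominator is the **group** metaphase
total (so 138 events against 1493 group metaphases prints 9.24) — the
convention that reproduces the published cells. Published per-pair
percentages in the unexposed column are truncated rather than rounded in
several cells; validation therefore uses only cells where the two agree.

The per-pair p-values are two-sided Fisher tests on
`[events_i, group_total − events_i]` across the pair, the closest reading of
the published pairwise comparisons; the output is labelled as such in the
manifest.

## CIN

For each chromosome the modal signal count of the individual's nuclei is the
reference (computed per individual, not fixed at 2, since CIN is defined
against the cell population's mode). Ties prefer the value nearest 2, then
the smaller. CIN per chromosome is the percentage of nuclei deviating from
the mode; an individual's CIN is the unweighted mean over the six
chromosomes, classed high when ≥ 25% (boundary inclusive). Zero-signal
nuclei count as deviant by default — the scoring protocol admits intact
nuclei without an exclusion rule — with `drop_zero=True` available to treat
them as hybridization failures. Fewer than 100 nuclei triggers a warning but
not an error. The source reports an exposed CIN range starting at 22.67%
while classing all exposed individuals as high against the 25% rule; the
package applies the stated threshold strictly and accepts that individuals
in 22.67–24.99 come out low.

## Diversity

Clones are cells sharing a copy-number signature: the full 6-tuple at the
individual level, the single count at the chromosome level. H = −Σ p ln p
uses natural logarithms so that TD = e^H is the Hill number of order 1 (the
effective number of equally abundant clones). CH classes: TD < 1.5 low,
1.5 ≤ TD ≤ 2 intermediate, TD > 2 high — the published bounds leave
(1.5, 1.6) undefined and the gap is closed into the intermediate class for
continuity. Whether the published per-individual CH used full signatures or
per-chromosome marginals is not stated; both are implemented. Full-signature
diversity is the default for an individual's `DiversityResult`, but the
per-chromosome mean TD is also reported because technical noise inflates
full-signature TD (each noisy nucleus is its own "clone"), and the marginal
scale is the one on which the published class boundaries and the
exposed/unexposed CH ratio are interpretable.

## Statistics layer

Two-sided tests throughout, α = 0.05, no multiple-testing correction (none
is described for the original analysis; the manifest records how many tests
a run performed). Fisher's exact test uses the conventional two-sided rule —
the sum of hypergeometric probabilities of tables no more probable than the
observed one — and is verified in the suite against an exact-integer
enumeration oracle on all 2×2 tables with margins ≤ 15. The two-sample path
gates on Shapiro-Wilk per sample (constant samples count as non-normal):
both normal → Student's t with Bartlett's test choosing pooled vs Welch;
otherwise Mann-Whitney U (unpaired) or Wilcoxon signed-rank (paired). Every
gate decision is recorded in `gate_trace`. Kruskal-Wallis with tie
correction serves as the omnibus test across chromosomes. The correlation
matrix is plain Pearson over complete rows with |r| > 0.5 flagged —
including a 0/1-coded sex column, reproducing the published analysis; the
point-biserial caveat applies and is noted, not "fixed". Pairs involving a
constant column are flagged undefined rather than raising.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are not tuning
knobs.

**FISH.** Each individual draws an observed-CIN target t from the group's
published distribution (34.57 ± 6.03% exposed, 6.48 ± 3.13% unexposed,
clipped to [0, 55]%), spread over chromosomes by fixed instability weights
(1.25, 1.20, 0.50, 1.20, 1.25, 0.60 for chromosomes 2, 3, 8, 11, 15, 17 —
mean 1, with 8 and 17 the stable pair, as observed in both groups). Noise
defaults are p_dropout = 0.015 and p_split = 0.01 per probe per nucleus
(dropout before split, independent across probes), giving a diploid noise
floor ν ≈ 3.9%; clone-level deviant fractions are noise-corrected,
f = (t − ν)/(1 − ν), so the *observed* CIN hits the target. Per-chromosome
fractions are realised by **nested clones**: chromosomes sorted by deviant
fraction, clone k deviating on the top-k with frequency f(k) − f(k+1).
This comonotone construction gives exact marginals with ≤ 7 clones and
resembles stepwise clonal evolution; deviant copy counts alternate between
3 and 1 across clones so no single aneuploid count can overtake the mode.
Ground truth (targets and clone fractions) is recorded per individual.
Below the noise floor the observed CIN cannot fall under ν, so the
unexposed group mean sits ~0.4 points above its nominal target — a property
of any design with a technical noise floor, visible in the recovery tests'
tolerances.

**Karyotypes.** Per metaphase, each category's event count is Poisson with
the group rate; default rates are the published group event totals divided
by group metaphase totals (e.g. exposed structural rate 88/1493). Splits
the tables do not give are fixed from the published ordering: 60%/40%
monosomy/trisomy within exposed numerical alterations (80/20 unexposed),
65–70% of fragilities at 9q12, marker gains 45% of the gain category, SCA
subtype mix led by deletions then translocations, variant mix proportional
to carrier counts. Chromosomes and bands come from a fixed major-band
catalog (not a full ideogram) sufficient for recurrence analyses.
Metaphases per individual are uniform on 19–95 for the exposed model and
19–45 for the unexposed one, reflecting the screening rule that extends
analysis when alterations are found. Clonal injections copy a stated
aberration verbatim into n randomly chosen metaphases of one individual,
providing planted signal for clonality and recurrence tests.

What the generator does **not** emulate: selection or clonal evolution over
time, within-individual correlation between karyotype damage and FISH-level
aneuploidy (the two record types are drawn independently), chromosome-
specific aneuploidy preferences in the karyotype layer, inter-probe noise
correlation, and scoring-operator effects. Passing recovery tests therefore
demonstrates estimator correctness under the declared mixture model, not
fidelity of any particular biological mechanism.

## Problem sizes and numerical choices

Simulation-based checks use the cohort sizes of the study design (34 + 34
individuals, 100 nuclei) with 200 replicate seeds for estimator-recovery
and type-I-error properties, and 20 seeds for group-mean tracking — sizes
at which the Monte-Carlo error of the assessed quantities is well below the
asserted tolerances. All randomness descends from one explicitly passed
seed (no silent clock seeding); identical seed and configuration give
bit-identical output. Tie-breaks (modal count, clone-signature ordering)
are deterministic. Percent rounding uses decimal half-up, matching printed
tables, rather than banker's rounding.

## Known limitations

* Only the attested ISCN subset parses; derivative-chromosome internal
  structure is recorded as category + cited chromosomes only.
* The plug-in Shannon estimator is negatively biased at 100 cells
  (≈ (k−1)/2n nats); recovery tests bracket it rather than correcting it.
* Published p-values are not forced: where printed values are inconsistent
  with their printed counts, the package reports its own exact values.
* A published ratio of exposed-to-unexposed CIN ("33.5 times") is
  inconsistent with the published group means (≈ 5.3×) and is not
  reproduced.
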