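# Methods

## The model

Exome matching assumes that the relative amounts of amino acids (AAs) an
organism must eat mirror the relative amounts its proteome is built from.
The original procedure normalizes each protein's composition and averages
across proteins with equal weight, so a 100-residue and a 3,000-residue
protein count the same and isoforms are whatever the protein set happens to
contain. The transcriptome-weighted extension removes both simplifications:
each isoform's AA counts are weighted by its transcript abundance,

    AA_i = sum_j AA_ij * E_j,        P(AA_i) = AA_i / sum_i AA_i,

with AA_ij the count of amino acid i in isoform j and E_j the isoform's
FPKM. Protein length enters through the raw counts and expression through
E_j. The implicit assumptions: transcript level is a usable proxy for the
protein synthesis demand (translation efficiency and protein turnover are
deliberately not modelled), and dietary requirement is proportional to
synthesis demand.

Three profile builders are exposed separately because they disagree on
length- or expression-heterogeneous proteomes: `exome_profile_protein_average`
(the original equal-weight average), `exome_profile_pooled` (counts pooled
over isoforms — exactly the weighted profile with all E_j equal, included
so the effect of expression weighting can be isolated from the effect of
length weighting), and `weighted_profile` (the equations above).

Replicates are handled by building one weighted profile per replicate and
averaging the profiles, rather than averaging FPKM first; the two orders
differ only slightly, but profile-space averaging is what yields per-AA
standard deviations across replicates as error bars. FPKM values are used
raw; a within-sample renormalization would cancel in P(AA_i) for a single
replicate and changes the replicate average only at second order.

## Limiting amino acid and predicted gain

For a diet profile d and a demand profile q (both molar fractions over the
20 canonical AAs), coverage_i = 100 * d_i / q_i. Only the ten essential
AAs (F, H, I, K, L, M, R, T, V, W — those the fly cannot synthesize) can
be limiting; non-essential coverages are reported but never selected. The
predicted gain from rebalancing the diet to the demand ratio at fixed
total AA is

    gain = 100 * (100 / coverage_lim - 1),

the relative increase in the limiting AA itself; under the
single-limiting-AA model this bounds the possible improvement in any
output (e.g. fecundity) that the limiting AA caps. No multi-AA
co-limitation is modelled. Edge cases: a zero-demand AA with positive
supply gets infinite coverage (flagged, never limiting); zero on both
sides excludes the AA with a warning; ties on the minimal coverage are all
reported, with the alphabetically first as primary (deterministic, and
ties do not occur on realistic data).

Note a structural fact, asserted as a property test: for two normalized
profiles the minimum coverage over *all* AAs can never exceed 100
(pigeonhole), but the essential-restricted minimum can, if the diet
systematically over-supplies essentials.

The power analysis helper implements n = (Z*sigma/E)^2 and its algebraic
inverses, for sizing fecundity assays around a detectable difference E
with dispersion sigma.

## Permutation null

To judge whether an observed profile is an extreme example of AA usage,
expression weightings are randomly reassigned to genes: each permutation
preserves the multiset of expression values while shuffling which gene
carries which value, giving divergent but realistically-distributed
expression vectors. For each permutation a weighted profile is computed;
the null statistic is the Euclidean distance to the per-AA *median* of the
permuted profiles, and an observed profile's percentile is the percentage
of permuted profiles strictly closer to that median (ties count as
not-exceeded, matching the ">X%" reading). The median is computed from the
permuted profiles only — observed profiles never contaminate the null —
and is intentionally not renormalized: component-wise medians of
normalized profiles do not sum to one, and renormalizing would change
every distance.

Expression is isoform-level but the stated procedure permutes gene labels,
and genes own different numbers of isoforms. Default resolution
(`level="gene"`): each gene is collapsed to its total FPKM and the
expression-share-weighted average of its isoforms' count vectors (uniform
average if unexpressed), so a permutation moves a gene's whole expression
budget while preserving its internal isoform structure. `level="isoform"`
permutes FPKM across isoforms directly. Default n_perm = 20,000; the seed
is mandatory in the CLI, and results are bit-reproducible for a fixed seed
and input order. When permutations are run on replicated data the
per-isoform replicate mean is permuted by default.

Correctness is anchored two ways: exhaustively (on a 3-isoform proteome
the engine's `exhaustive=True` mode must match brute-force enumeration of
all 3! assignments distance-for-distance) and by calibration (an
"observed" profile that is itself a random permutation must have a
percentile uniform on [0, 100]; the suite checks a Kolmogorov–Smirnov
statistic over 2,000 trials × 500 permutations). The calibration uses an
independent null per trial — reusing one null across trials correlates the
percentiles and inflates the KS statistic.

## Diet formulation

Given molar fractions p and a total concentration T in grams of free-base
amino acid per litre, total moles N = T / sum_i p_i*MW_i(free) and
grams_i = N * p_i * MW_i(free). T is interpreted on the free-base basis:
dilution series of the same ratio then scale every entry linearly, and
salt counter-ions never count toward the AA mass. When salt forms are
enabled the *weighed* amount scales by MW(salt)/MW(free) — the packaged
table carries monohydrochloride weights for lysine (182.65 g/mol) and
arginine (210.66 g/mol) alongside standard free-base MWs — while molar and
free-base columns are unchanged. `stock_split` partitions a recipe into
the practical preparation blocks of holidic fly food (poorly soluble
Ile/Leu/Tyr added directly before autoclaving, Glu and Cys dosed from
their own solutions, remaining essentials/non-essentials in EAA/NEAA
stocks); mass conservation across the split is exact.

Published per-litre gram listings for the FLYAA diet serve as a rounding
cross-check only: our grams come from 3-decimal printed ratios, so the
admissible per-AA deviation is the half-ulp of the ratio (0.0005/p_i) plus
its worst-case propagation through the mean molecular weight (~1%) plus
the half-ulp of the printed gram. Tryptophan, the scarcest AA (p = 0.010),
dominates this envelope at ~6%.

## Synthetic fixtures

The generator emulates the statistical shape of whole-organism
proteome/expression inputs at adjustable scale: multi-isoform proteomes
(default ~2 isoforms per gene — 1 + Poisson(1) — near the fly's ratio of
polypeptides to protein-coding genes), protein lengths uniform on
100–1000 residues, sequences drawn residue-by-residue from a target
composition (default: the packaged FLYAA ratio), and isoform FPKM drawn
log-normal(mu = 1, sigma = 1.5) — right-skewed over several decades, as in
real tissue atlases — with log-normal multiplicative replicate noise
(sd 0.2) over 5 replicates, matching the five-transcriptome averaging
design of the reference ratios. Every fixture ships a manifest whose
per-isoform counts and ground-truth profiles are computed with independent
plain-Python arithmetic, and the builders must agree with it to 1e-12.

What the generator does *not* emulate: compositional autocorrelation along
sequences (residues are i.i.d. — harmless here because every computation
in the package depends only on counts), correlated expression between
related genes, isoform-specific expression structure beyond independent
draws, and count-based FPKM estimation noise. Passing tests therefore
demonstrate algorithmic correctness and statistical calibration, not that
biological inputs satisfy these independence assumptions.

Deterministic fixture: `worked_example()` returns the fixed three-gene
micro-dataset (sequences MW / MMMW / AAAG with FPKM 2 / 1 / 1) whose every
intermediate is documented in its docstring and stored exactly in the
manifest; it is the canonical regression anchor.

## Numerical and design choices

* Profiles are double-precision vectors in fixed alphabetical AA order;
  sum-to-one is enforced to 1e-9 at construction (1e-6 is accepted after
  long arithmetic chains, e.g. file round-trips at 9 significant digits).
* Diet-ratio columns must sum to within [0.98, 1.02] before
  renormalization; anything else is rejected as a units mistake. Printed
  tables sum to e.g. 1.001 and are renormalized silently.
* Missing FPKM for a proteome isoform is treated as 0 with a logged count;
  expression rows without a matching isoform are dropped with a logged
  count. No expression threshold or filter is applied.
* Sequence cleaning uppercases, strips `*` stops, and drops non-canonical
  letters (B, X, U, ...) with a logged count rather than failing;
  selenocysteine/pyrrolysine are not profile dimensions.
* When no gene id is parseable from a FASTA header the gene id defaults to
  the isoform id, so gene-level permutation degrades to isoform-level
  rather than erroring.
* The problem sizes used by the test suite and the acceptance script
  (40–200 genes, 500–20,000 permutations, ~2×10⁵ residues for recovery)
  were chosen as the smallest at which the checked statistical bounds are
  comfortably non-trivial; all scale linearly if larger runs are wanted.

## Known limitations

* Transcript abundance proxies protein demand: no translation efficiency,
  protein half-life, or body-reserve buffering.
* Whole-alphabet comparison only: tissue demand profiles are not
  renormalized to alphabet subsets.
* The full-organism analysis (real proteome + tissue-atlas FPKM tables)
  requires external downloads and is out of the test scope; the package
  consumes such files directly via `read_proteome` / `read_expression`
  once the user supplies them.
* FPKM columns from different sources are treated as exchangeable
  replicates; no cross-database batch correction is attempted.
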