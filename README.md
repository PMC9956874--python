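# exomatch

Predicting dietary amino-acid (AA) requirements from a genome. Many animals
are protein-limited, and in *Drosophila melanogaster* that limitation acts
through the single most limiting **essential** amino acid in the food.
*Exome matching* predicts the ideal dietary AA ratio from the AA
proportions encoded by an organism's translated exome; its
transcriptome-weighted extension additionally weights every protein isoform
by its expression level. `exomatch` implements the full computational
pipeline around this idea, for nutritionists, fly-food designers, and
anyone comparing compositional AA profiles:

* **Profiles.** From a protein FASTA, build the unweighted exome-matched
  profile (per-protein compositions averaged with equal weight), the
  pooled length-weighted profile, or the transcriptome-weighted profile

  *AA<sub>i</sub>* = Σ<sub>j</sub> *AA<sub>ij</sub>* · *E<sub>j</sub>*,  *P*(*AA<sub>i</sub>*) = *AA<sub>i</sub>* / Σ<sub>i</sub> *AA<sub>i</sub>*,

  where *AA<sub>ij</sub>* counts amino acid *i* in isoform *j* and
  *E<sub>j</sub>* is the isoform's FPKM. Replicates are combined by
  averaging per-replicate profiles.
* **Limiting-AA prediction.** Compare a diet profile against a demand
  profile: coverage<sub>i</sub> = 100 · diet<sub>i</sub>/demand<sub>i</sub>;
  the essential AA with the lowest coverage is limiting, and
  gain = 100 · (100/coverage<sub>lim</sub> − 1) is the predicted relative
  improvement from rebalancing the diet, which under the single-limiting-AA
  model bounds the potential fecundity increase. Tissue panels run this
  for many diets × tissue demand profiles at once.
* **Permutation null.** Randomly reassign expression weightings to genes
  (20,000 permutations by default), rebuild the weighted profile each time,
  and judge observed profiles by their Euclidean distance to the per-AA
  median permuted profile.
* **Diet formulation.** Convert a molar ratio plus a total AA concentration
  (g/L, free-base basis) into a weighable recipe, salt forms
  (Lys·HCl, Arg·HCl) and stock-solution splits included.
* **Synthetic fixtures.** Seeded generator for multi-isoform proteomes and
  log-normal expression tables with analytically known ground truth.

The packaged reference ratios (`exomatch.reference_diet_ratios()`) are the
published FLYAA (exome-matched), MALEAA and FEMALEAA (male/female whole-body
transcriptome-weighted) molar ratios used in holidic fly diets.

## Worked example

The three-gene micro-proteome `g1.i1 = "MW"` (FPKM 2), `g2.i1 = "MMMW"`
(FPKM 1), `g3.i1 = "AAAG"` (FPKM 1) can be followed entirely by hand
(weighted counts: M = 1·2+3·1 = 5, W = 1·2+1·1 = 3, A = 3, G = 1):

```python
>>> import exomatch as em
>>> fx = em.worked_example()
>>> pc = em.count_isoform_aas(fx.records)
>>> prof = em.weighted_profile(pc, fx.expression)
>>> {aa: round(p, 4) for aa, p in prof.proportions.items() if p > 0}
{'A': 0.25, 'G': 0.0833, 'M': 0.4167, 'W': 0.25}
```

i.e. {M: 5/12, W: 1/4, A: 1/4, G: 1/12}. Limiting-AA prediction on the
packaged ratios, feeding the exome-matched diet to males whose demand is
the male-transcriptome-weighted profile:

```python
>>> ratios = em.reference_diet_ratios()
>>> rep = em.coverage(ratios["FLYAA"], ratios["MALEAA"])
>>> rep.limiting_aa, round(rep.limiting_coverage, 1), round(rep.predicted_gain, 1)
('W', 83.3, 20.0)
```

Tryptophan covers only 83.3% of the predicted male demand (0.010 supplied
vs 0.012 required), so switching to the demand ratio could raise the
limiting AA — and at most fecundity — by 20%. Against the female demand
profile the limiting AA is lysine, again with a ≈20% predicted gain. The
same operations are available from the shell:

```sh
exomatch profile --proteome proteome.fasta --expression fpkm.tsv \
    --method weighted --replicate all -o weighted.tsv
exomatch compare --diet flyaa.tsv --demand weighted.tsv -o coverage.tsv
exomatch permute --proteome proteome.fasta --expression fpkm.tsv \
    --n 20000 --seed 1 --observed flyaa.tsv -o null/
exomatch recipe --profile flyaa.tsv --total 10.7 --stocks -o recipe.tsv
```

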