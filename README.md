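# butycore

Function-centric profiling of the colonic butyrate-producing community
from shotgun metagenome-derived gene counts.

Butyrate, a microbial fermentation product, sustains the colonic
epithelium and its depletion is linked to several non-communicable
diseases. The taxa that produce it form a polyphyletic guild running
one of four biochemical routes: the carbohydrate-fed **acetyl-CoA (Ac)
pathway** (the dominant one) and the protein-fed **glutarate (Gl)**,
**4-aminobutyrate (4A)** and **lysine (Ly)** pathways, each ending in a
terminal enzyme (butyryl-CoA:acetate CoA transferase *but*, butyrate
kinase *buk*, or alternatives). `butycore` implements the
gene-centric workflow that quantifies this guild:

1. **Genotyping** — genomes are screened for pathway genes from
   annotation tables (score cutoffs at the dominant drop below the
   lowest-scoring reference, synteny-based paralog filtering, etfA/etfB
   validated against *bcd*); a pathway is called present when at most
   one core gene is missing (*thl* exempt for Ac; a terminal enzyme is
   then required).
2. **Gene catalogue** — assembled nucleotide sequences are
   dereplicated, length-filtered (≥ 70% of the median reference
   length), clustered by complete linkage at 95% nucleotide identity,
   annotated against references (coverage ≥ 80%, cluster count ≥ 3,
   identity ≥ 75% for *but*/*buk*) and merged with references plus
   decoy sequences that absorb misattributable reads.
3. **Quantification** — read counts are decoy-filtered, pooled per
   (taxon, gene), gene-length corrected, and normalized by the mean of
   three single-copy housekeeping genes (*rplB*, *recA*, *pyrG*), so
   every abundance is a percentage of total bacteria:

   `abundance(p) = agg_{g in quant(p)} [ N_g / L_g ] / mean_h [ N_h / L_h ] x 100`

   with mean aggregation (median for 4A), *gcdB* excluded from Gl and
   terminal/bcd-etfAB genes never quantified. Taxon presence, terminal
   enzyme groups (with proportional *but*/*buk* splitting), family
   groups and taxon linkage follow the same conventions.
4. **Ecology & stability** — prevalence cores, Bray–Curtis
   dissimilarity on square-root abundances, complete-linkage community
   typing, PERMANOVA, multi-dataset Spearman co-occurrence networks
   (ρ > 0.4, P and Q < 0.05, support ≥ 3 datasets), case/control
   comparisons with FDR control and meta-analysis, and per-subject
   functional-stability statistics (fraction of taxa decreasing,
   absolute-vs-total change) against a uniform random baseline.

A synthetic-data generator (`butycore.synth`) produces every input with
known ground truth — genome tables, gene sequences, multinomial read
counts, longitudinal and case/control designs — so the whole chain is
testable end to end.

## Worked example

```python
from butycore.synth import (make_community, reference_catalogue,
                            simulate_counts, SimulationConfig)
from butycore.screen import TaxonProfileSet
from butycore.pipeline import _community_profiles
from butycore.quantify import profile_sample

community = make_community(n_taxa=20, background_fraction=0.70, seed=1)
catalogue = reference_catalogue(community, seed=2)
counts = simulate_counts(community, catalogue,
                         SimulationConfig(depth=1_000_000, seed=3))[0]
profiles = TaxonProfileSet(_community_profiles(community))
prof = profile_sample(counts, catalogue, profiles,
                      taxonomy=community.taxonomy())

print("true Ac abundance: %.2f%%" % community.true_pathway_abundance("Ac"))
for pid, ab in prof.pathway_abundance.items():
    print(f"estimated {pid}: {ab:.2f}%")
print("Ac richness:", prof.richness["Ac"])
print("enzyme groups:", {k: round(v, 2) for k, v in prof.enzyme_groups.items()})
```

prints

```
true Ac abundance: 30.00%
estimated Ac: 29.96%
estimated Gl: 6.40%
estimated 4A: 6.69%
estimated Ly: 2.74%
Ac richness: 20
enzyme groups: {'but': 18.64, 'buk': 8.65, 'alternative': 2.67}
```

The community was built with 30% of bacteria carrying the Ac pathway;
at a depth of 10⁶ reads the housekeeping-normalized estimate recovers
it to within 0.05 percentage points, all 20 producer taxa are detected,
and the enzyme groups partition the summed taxon abundances exactly.

The same stages are available from the shell:

```bash
butycore synth --n-taxa 20 --n-samples 10 --depth 100000 --seed 1 --out run/
butycore genotype run/genome_hits.tsv --out run/geno
butycore quantify run/counts.tsv --catalogue-fasta run/catalogue.fasta \
    --catalogue-manifest run/catalogue_manifest.tsv \
    --hits-tsv run/genome_hits.tsv --out run/abund
butycore run --seed 1 --out run_full/   # full pipeline with provenance
```

## Layout

- `src/butycore/pathways.py` — pathway gene rosters and aggregation rules
- `src/butycore/screen.py` — genome genotyping
- `src/butycore/catalogue.py` — gene-catalogue construction
- `src/butycore/quantify.py` — count normalization and abundance profiles
- `src/butycore/ecology.py` — cross-sample/cross-dataset statistics
- `src/butycore/stability.py` — longitudinal stability statistics
- `src/butycore/synth.py` — synthetic-data generators with ground truth
- `src/butycore/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — models, assumptions and design choices
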