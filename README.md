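# shellseq

Statistical analysis of shell-matrix-protein (SMP) gene expression in
bivalves, from unreplicated RNA-seq count data, together with a synthetic
data generator that emulates the two study designs the methods were built
for:

1. **An organ expression atlas.** Shell-matrix proteins are classically
   assumed to be secreted by the mantle. Given read counts for each gene
   across a panel of organs (mantle, gill, hemolymph, adductor muscle,
   gonads, digestive gland, labial palp), the package normalises to RPKM,
   calls a gene *expressed* in an organ when its RPKM exceeds 5, and flags
   SMP genes whose expression pattern contradicts a mantle origin: genes
   that are unexpressed in mantle yet expressed at least twofold higher in
   some other organ. Because hemolymph circulates and could deliver
   proteins to the shell surface, a stricter class additionally requires
   the gene to be unexpressed in hemolymph.

2. **A shell-damage time course.** One valve of each animal is damaged and
   mantle transcriptomes are taken on a series of post-damage dates, each
   side with a single undamaged control library. With no replicates,
   per-date differential expression uses the exact conditional test of
   Audic & Claverie (1997) for two Poisson counts given their sum. The
   multiplicity device is *recurrence*: a gene is called persistently
   damage-responsive only if it is significant in the same direction on at
   least 6 of 7 dates. The package quantifies how surprising the observed
   recurrence is against a null in which per-date calls are shuffled
   across genes (a Poisson-binomial law), and tests functional enrichment
   of the selected genes with hypergeometric tests and
   Benjamini–Hochberg correction.

The generator plants known ground truth (non-mantle-origin SMP genes,
persistently responsive genes, enriched annotation terms) so that every
stage's sensitivity and false-positive behaviour can be measured.

## Worked example

Simulate a damage time course with 2000 genes (2% persistently
up-regulated fourfold on the damaged side), call per-date differential
expression at p < 10⁻³, and select genes recurring on ≥ 6 of 7 dates:

```python
from shellseq import (TimeCourseScenario, call_de, count_recurrence,
                      select_persistent_genes, simulate_damage_timecourse)

scenario = TimeCourseScenario(n_genes=2000, seed=1)
counts, truth = simulate_damage_timecourse(scenario)
calls = call_de(counts, scenario.manifest(), alpha=1e-3)

profile = count_recurrence(calls, "left", "up")
selected = select_persistent_genes(profile, k_min=6)
injected = set(truth.genes_where("is_damage_responsive"))
print("genes up-regulated on k = 0..7 dates:", profile.histogram().astype(int))
print(f"selected {len(selected)} persistent genes "
      f"({len(set(selected) & injected)}/{len(injected)} injected recovered)")
```

Output:

```
genes up-regulated on k = 0..7 dates: [1930   15   15    0    0    0    0   40]
selected 40 persistent genes (40/40 injected recovered)
```

All 40 injected genes recur on all 7 dates; the 30 null genes that clear
the per-date threshold once or twice never approach the k ≥ 6 rule.

The atlas side works the same way — simulate, normalise, classify:

```python
from shellseq import (AtlasScenario, classify_shell_protein_origin,
                      compute_rpkm, simulate_organ_atlas)

scenario = AtlasScenario(n_genes=5000, seed=1)
counts, truth = simulate_organ_atlas(scenario)
cls = classify_shell_protein_origin(compute_rpkm(counts), truth.smp_genes())
print(cls.class_counts().to_string())
```

Output:

```
origin_class
mantle_expressed            449
non_mantle                   10
non_mantle_non_hemolymph     40
unexpressed_everywhere        1
```

## Command line

Every stage is exposed as a `shellseq` subcommand
(`simulate-atlas`, `simulate-timecourse`, `rpkm`, `classify-origin`,
`de-call`, `recurrence`, `select`, `enrich`), and `shellseq run-all
--config config.yaml` executes the whole pipeline from a YAML
configuration, writing TSV outputs plus the resolved configuration into
an output directory. Runs are deterministic: the same configuration and
seed reproduce byte-identical outputs.

## Documentation

`docs/methods.md` describes the statistical model, the generator's
assumptions, every parameter with its default, and known limitations.
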