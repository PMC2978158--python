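# orthoflux

Tools for building and interrogating draft genome-scale metabolic models of
a target species by orthology-based projection of a curated source
reconstruction — the workflow that produced the mammalian drafts and the
mouse model iMM1415 from the human reconstruction Recon 1.

The package is aimed at systems biologists who want to go from

1. a **source reconstruction** (SBML or a tabular reaction list with
   gene–protein–reaction rules), plus
2. a **homology table** (source gene → target-species genes), plus
3. a **universal reaction database** and **medium/validation definitions**,

to a working, validated constraint-based model of the target species, and
then to phenotype predictions: gene essentiality and knockout flux-shift
analyses.

## What it computes

**Flux balance analysis (FBA).** A model is a stoichiometric matrix *S*
(metabolites × reactions) with flux bounds *lᵢ ≤ vᵢ ≤ uᵢ* (mmol/gDW/hr,
global bound magnitude 1000) and a biomass objective *Z*. FBA solves

    max Z = c·v   s.t.   S·v = 0,   l ≤ v ≤ u

**Flux variability analysis (FVA)** then reports per reaction the minimum
and maximum of *vᵢ* while *Z* is held at (a fraction of) its optimum.

**Projection.** Approach A keeps a gene-associated reaction iff its GPR
rule still evaluates true when exactly the source genes with a homolog are
present (isozymes rescue), and keeps all non-gene-associated reactions;
approach B additionally drops non-gene-associated metabolic reactions,
keeping only transporters, demand/exchange and biomass. Retained rules are
rewritten into the target gene namespace (each leaf becomes an OR over its
homologs). Both compartmentalized and collapsed
(single-intracellular-compartment) variants are supported.

**Gap filling.** When a draft cannot produce biomass, a MILP finds the
minimal set of universal-database reactions to add: binary indicator *yⱼ*
per candidate, |vⱼ| ≤ M·yⱼ, steady state of the combined network, target
flux ≥ ε, minimize Σyⱼ; integer cuts enumerate alternate solutions over
repeated iterations, and mechanical filters reject solutions that reverse
a known-irreversible reaction or lack organism evidence.

**Validation & curation.** FBA producibility test batteries run each test
on a fresh copy of the model; the curation loop searches the pool of
projection-removed reactions for minimal restorations that make failing
tests pass.

**Knockout phenotypes.** Deleting a gene zeroes the bounds of reactions
whose GPR fails without it. Essential genes are those whose deletion drives
the biomass optimum to (numerically) zero. Softer phenotypes are read from
FVA: each reaction's capacity change (Δv_max) is classified
decreased/unchanged/increased, and per major metabolic subsystem the
down/up counts are tested against an even split with a 1-df chi-square,

    X² = (n_down − E)²/E + (n_up − E)²/E,   E = (n_down + n_up)/2

at Bonferroni significance α/k (default 0.05/10).

A seed-deterministic synthetic-data generator emits miniature
reconstructions with provable ground truth (planted essential genes,
blocked reactions, removable gap reactions, validation dependencies) so
every stage is testable end to end without external databases.

## Worked example

```python
import orthoflux as of

spec = of.SyntheticSpec(seed=1)
model, truth = of.generate_source_model(spec)
growth = of.solve_fba(of.apply_medium(model, truth.minimal_medium))

table = of.generate_homology_table(spec, model, retention=0.9, seed=4)
projected, report = of.project_model_A(model, table)

screen = of.essentiality_screen(model, truth.minimal_medium)
changes, tests = of.knockout_phenotype(model, truth.minimal_medium, "ess00")
```

prints (via the obvious `print` statements):

```
reactions=312 genes=142 metabolites=216
minimal-medium growth rate: 10.0
approach A: kept 306/312 reactions (gene ratio 0.89)
essential genes: ['ess00', 'ess01', 'ess02', 'ess03', 'ess04']
  Amino Acid Metabolism: down=16 up=0 p=6.33e-05
```

The growth rate equals the nutrient uptake bound (each of the ten biomass
precursors is made at the rate its nutrient enters); the essentiality
screen recovers exactly the five planted single-gene bridge enzymes; and
knocking out `ess00` significantly depresses flux capacity in its own
pathway's subsystem (16 reactions down, none up).

The same stages are scriptable from the shell:

```bash
orthoflux generate --seed 1 --out run/inputs
orthoflux project --model run/inputs/model.tsv --homology run/inputs/homology.tsv \
                  --approach A --out run/draft.tsv
orthoflux essentiality --model run/draft.tsv --medium run/inputs/minimal.tsv \
                  --out run/essentiality.tsv
```

## Packaged literature data

`orthoflux.datasets` ships the curated knockout-phenotype survey of the
predicted-essential mouse genes (17 genes with literature data, 14 lethal)
and the per-subsystem decreased/increased FVA counts for four simulated
knockouts (PGM1, FUT9, SORD, DHCR7) plus the LPL headline counts. The
statistics layer always recomputes p-values from the raw counts.

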