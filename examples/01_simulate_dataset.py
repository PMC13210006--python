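"""Generate a synthetic tillage x straw factorial dataset with planted structure.

The generator emulates an 18-sample rhizosphere study: 2 tillage levels
(NT/MT) x 3 straw-return levels (NS/HS/TS) x 3 replicates, taxa organised
into latent co-abundance modules, soil nutrients driven by the module
factors, and enzyme-gene abundances driven by designated taxa.
"""

from rhizonet.synthetic import GeneratorConfig, generate_dataset

table, meta, nutrients, genes, truth = generate_dataset(GeneratorConfig(seed=42))

print(f"community table: {table.shape[0]} samples x {table.shape[1]} taxa "
      f"({table.mode} mode)")
print(f"treatments: {sorted({meta.treatment(s) for s in meta.sample_ids})}")
print(f"nutrients: {nutrients.variables}")
print(f"enzyme genes: {genes.taxon_ids}")
n_mod = len(truth.modules())
print(f"planted structure: {n_mod} modules, "
      f"{sum(len(v) for v in truth.modules().values())} module taxa, "
      f"{len(truth.pathways)} implied microbe-gene-nutrient pathways")
# Each module's taxa share one latent factor per sample, so downstream
# network analysis should rediscover the modules from correlations alone.
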