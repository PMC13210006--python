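"""Factorial-design synthetic datasets with planted structure.

Emulates the statistical skeleton of a conservation-tillage rhizosphere
study: a 2 (tillage: NT/MT) x 3 (straw: NS/HS/TS) factorial with 3
replicates per cell (18 samples), taxa organised into latent co-abundance
modules, soil-nutrient variables linearly driven by the module factors, and
enzyme-gene abundances linearly driven by designated core taxa. Ground
truth (module membership, nutrient coefficients, gene drivers, implied
microbe-gene-nutrient pathways) is saved for recovery tests.

Abundances follow a log-normal multiplicative model: per sample, each
module draws a latent factor (treatment shift + Gaussian noise); member
taxa are loadings on that factor plus taxon-level noise on the log scale,
then exponentiated and row-normalised. This yields realistic skew and
rank-stable within-module correlations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    FeatureTable,
    NutrientTable,
    SampleMetadata,
    STRAW_LEVELS,
    TILLAGE_LEVELS,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_community",
    "generate_nutrients",
    "generate_gene_table",
    "generate_dataset",
    "planted_chain_config",
]

TREATMENTS = [f"{t}-{s}" for t in TILLAGE_LEVELS for s in STRAW_LEVELS]


def _default_treatment_effects(n_modules: int, scale: float = 1.5) -> np.ndarray:
    """Module x treatment latent-factor shifts.

    Columns follow TREATMENTS order (NT-NS, NT-HS, NT-TS, MT-NS, MT-HS,
    MT-TS). Modules cycle through four archetypes: tillage-responsive,
    straw-dose-responsive, interaction-responsive, unresponsive — mirroring
    the kinds of treatment structure a tillage x straw-return experiment
    produces.
    """
    straw_dose = np.array([0.0, 0.5, 1.0, 0.0, 0.5, 1.0])
    tillage = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
    archetypes = [
        tillage,
        straw_dose,
        tillage * straw_dose,
        np.zeros(6),
    ]
    rows = [archetypes[m % 4] * scale for m in range(n_modules)]
    return np.array(rows)


@dataclass
class GeneratorConfig:
    """Knobs for the planted-structure generator.

    Defaults reproduce the study design scale: 18 samples (2x3 factorial,
    3 replicates), 4 modules of 25 taxa plus 20 background taxa, and a
    noise-to-signal ratio of 0.3 on the log scale.
    """

    n_replicates: int = 3
    n_modules: int = 4
    taxa_per_module: int = 25
    n_background_taxa: int = 20
    module_factor_sd: float = 1.0
    taxon_noise_sd: float = 0.3
    treatment_effects: np.ndarray | None = None  # (n_modules, 6) shifts
    loading_low: float = 0.8
    loading_high: float = 1.2
    baseline_sd: float = 0.5
    background_sd: float = 1.0
    nutrient_spec: list = field(default_factory=list)
    gene_spec: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("module_factor_sd", "taxon_noise_sd", "baseline_sd", "background_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_modules > 0 and self.taxa_per_module < 2:
            raise ValueError("taxa_per_module must be >= 2")
        if self.n_modules == 0 and self.n_background_taxa == 0:
            raise ValueError("degenerate config: no modules and no background taxa")
        if self.treatment_effects is None:
            self.treatment_effects = _default_treatment_effects(self.n_modules)
        self.treatment_effects = np.asarray(self.treatment_effects, dtype=float)
        if self.n_modules and self.treatment_effects.shape != (self.n_modules, 6):
            raise ValueError("treatment_effects must have shape (n_modules, 6)")
        if not self.nutrient_spec:
            self.nutrient_spec = default_nutrient_spec(self.n_modules)
        if not self.gene_spec:
            self.gene_spec = default_gene_spec(self.n_modules, self.taxa_per_module)


def default_nutrient_spec(n_modules: int, noise_sd: float = 0.3) -> list:
    """One nutrient per module plus two module-free controls.

    Names and pool labels are drawn from the C/N/P fraction vocabulary of
    soil-nutrient panels (SOC, DOC, MBC; TN, AN, NN; TP, AP) so downstream
    grouping logic can be exercised.
    """
    catalogue = [
        ("SOC", "C"), ("TN", "N"), ("TP", "P"), ("DOC", "labile-C"),
        ("AN", "inorganic-N"), ("AP", "inorganic-P"), ("MBC", "labile-C"),
        ("NN", "inorganic-N"),
    ]
    spec = []
    for m in range(n_modules):
        name, pool = catalogue[m % len(catalogue)]
        coeffs = np.zeros(n_modules)
        coeffs[m] = 2.0 if m % 2 == 0 else -2.0
        spec.append({"name": name if m < len(catalogue) else f"{name}_{m}",
                     "pool": pool, "coeffs": coeffs, "noise_sd": noise_sd})
    spec.append({"name": "MBP", "pool": "organic-P",
                 "coeffs": np.zeros(n_modules), "noise_sd": noise_sd})
    spec.append({"name": "AHN", "pool": "organic-N",
                 "coeffs": np.zeros(n_modules), "noise_sd": noise_sd})
    return spec


def default_gene_spec(n_modules: int, taxa_per_module: int, noise_sd: float = 0.002) -> list:
    """Two enzyme genes per module, each driven by one module-member taxon.

    The first gene of each module is promoted (+), the second inhibited (-),
    exercising both direction labels in pathway screening.
    """
    cycles = ["C", "N", "P"]
    display = ["beta-glucosidase", "urease", "acid-phosphatase",
               "endo-1,4-beta-xylanase", "nitrate-reductase", "phytase"]
    spec = []
    k = 0
    for m in range(n_modules):
        for j, sign in enumerate((1.0, -1.0)):
            driver = f"M{m + 1}_T{j + 1}"  # first two member taxa of module m
            spec.append({
                "name": f"K{10000 + k:05d}",
                "display": display[k % len(display)],
                "cycle": cycles[m % 3],
                "drivers": {driver: sign * 5.0},
                "noise_sd": noise_sd,
            })
            k += 1
    return spec


@dataclass
class SyntheticTruth:
    """Ground truth saved alongside a generated dataset."""

    module_of: dict  # taxon -> module label ("module_1"... or "background")
    module_factors: pd.DataFrame  # samples x modules latent factors
    nutrient_coeffs: dict  # nutrient -> np.ndarray over modules
    gene_drivers: dict  # gene -> {taxon: signed coeff}
    pathways: set  # {(taxon, gene, nutrient)}

    def modules(self) -> dict:
        out: dict = {}
        for taxon, mod in self.module_of.items():
            if mod != "background":
                out.setdefault(mod, []).append(taxon)
        return out

    def to_json(self, path) -> None:
        payload = {
            "module_of": self.module_of,
            "nutrient_coeffs": {k: list(v) for k, v in self.nutrient_coeffs.items()},
            "gene_drivers": self.gene_drivers,
            "pathways": sorted(list(p) for p in self.pathways),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _design(n_replicates: int) -> SampleMetadata:
    rows = []
    for t in TILLAGE_LEVELS:
        for s in STRAW_LEVELS:
            for r in range(1, n_replicates + 1):
                rows.append({"sample_id": f"{t}-{s}-{r}", "tillage": t,
                             "straw": s, "replicate": r})
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleMetadata(df)


def generate_community(cfg: GeneratorConfig):
    """Generate (FeatureTable, SampleMetadata, SyntheticTruth).

    The returned table is in relative mode (rows sum to 1). The latent
    module factors live in ``truth.module_factors`` so nutrients can be
    generated from the same realisation.
    """
    rng = np.random.default_rng(cfg.seed)
    meta = _design(cfg.n_replicates)
    samples = meta.sample_ids
    n = len(samples)
    treatment_idx = [TREATMENTS.index(meta.treatment(s)) for s in samples]

    factors = np.zeros((n, cfg.n_modules))
    for m in range(cfg.n_modules):
        shifts = cfg.treatment_effects[m, treatment_idx]
        factors[:, m] = shifts + rng.normal(0.0, cfg.module_factor_sd, size=n)

    cols: dict = {}
    module_of: dict = {}
    for m in range(cfg.n_modules):
        loadings = rng.uniform(cfg.loading_low, cfg.loading_high, size=cfg.taxa_per_module)
        baselines = rng.normal(0.0, cfg.baseline_sd, size=cfg.taxa_per_module)
        noise = rng.normal(0.0, cfg.taxon_noise_sd, size=(n, cfg.taxa_per_module))
        log_ab = baselines + np.outer(factors[:, m], loadings) + noise
        for j in range(cfg.taxa_per_module):
            name = f"M{m + 1}_T{j + 1}"
            cols[name] = log_ab[:, j]
            module_of[name] = f"module_{m + 1}"
    for b in range(cfg.n_background_taxa):
        name = f"BG_T{b + 1}"
        cols[name] = rng.normal(0.0, cfg.background_sd, size=n)
        module_of[name] = "background"

    log_table = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
    abundances = np.exp(log_table)
    rel = abundances.div(abundances.sum(axis=1), axis=0)
    table = FeatureTable(rel, mode="relative")

    factors_df = pd.DataFrame(
        factors, index=rel.index,
        columns=[f"module_{m + 1}" for m in range(cfg.n_modules)],
    )
    nutrient_coeffs = {s["name"]: np.asarray(s["coeffs"], dtype=float)
                       for s in cfg.nutrient_spec}
    gene_drivers = {s["name"]: dict(s["drivers"]) for s in cfg.gene_spec}
    truth = SyntheticTruth(
        module_of=module_of,
        module_factors=factors_df,
        nutrient_coeffs=nutrient_coeffs,
        gene_drivers=gene_drivers,
        pathways=_implied_pathways(module_of, nutrient_coeffs, gene_drivers),
    )
    return table, meta, truth


def _implied_pathways(module_of, nutrient_coeffs, gene_drivers) -> set:
    """True (taxon, gene, nutrient) triples implied by nonzero couplings.

    A triple is true when the taxon drives the gene and the taxon's module
    has a nonzero coefficient on the nutrient (so gene and nutrient co-vary
    through the shared module factor).
    """
    out = set()
    for gene, drivers in gene_drivers.items():
        for taxon, coeff in drivers.items():
            if coeff == 0:
                continue
            mod = module_of.get(taxon)
            if mod is None or mod == "background":
                continue
            m_idx = int(mod.split("_")[1]) - 1
            for nutrient, coeffs in nutrient_coeffs.items():
                if m_idx < len(coeffs) and coeffs[m_idx] != 0:
                    out.add((taxon, gene, nutrient))
    return out


def generate_nutrients(factors: pd.DataFrame, cfg: GeneratorConfig,
                       pools: dict | None = None) -> NutrientTable:
    """Nutrient value = sum(coeff * module factor) + Gaussian noise."""
    rng = np.random.default_rng(cfg.seed + 1)
    n_modules = factors.shape[1]
    data = {}
    pool_map: dict = {}
    for s in cfg.nutrient_spec:
        coeffs = np.asarray(s["coeffs"], dtype=float)
        if coeffs.shape[0] != n_modules:
            raise ValueError(
                f"nutrient {s['name']!r}: coefficient vector length "
                f"{coeffs.shape[0]} != n_modules {n_modules}"
            )
        vals = factors.to_numpy() @ coeffs
        vals = vals + rng.normal(0.0, s["noise_sd"], size=len(factors))
        data[s["name"]] = vals
        pool_map.setdefault(s.get("pool", "C"), []).append(s["name"])
    table = pd.DataFrame(data, index=factors.index)
    return NutrientTable(table, pools if pools is not None else pool_map)


def generate_gene_table(t: FeatureTable, cfg: GeneratorConfig) -> FeatureTable:
    """Enzyme-gene abundances as linear functions of driver taxa.

    gene value = offset + sum(signed coeff * driver relative abundance)
    + Gaussian noise, clipped at zero. The offset keeps genes with negative
    driver coefficients non-negative: by default it is
    ``3 * noise_sd + sum(|negative coefficients|)`` (driver relative
    abundances never exceed 1), so clipping is rare and the planted
    monotone relationships survive.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    n = len(t.sample_ids)
    data = {}
    for s in cfg.gene_spec:
        drivers = s["drivers"]
        unknown = set(drivers) - set(t.taxon_ids)
        if unknown:
            raise ValueError(f"gene {s['name']!r}: unknown driver taxa {sorted(unknown)}")
        noise_sd = s["noise_sd"]
        offset = s.get("offset")
        if offset is None:
            offset = 3.0 * noise_sd + sum(abs(c) for c in drivers.values() if c < 0)
        vals = np.full(n, float(offset))
        for taxon, coeff in drivers.items():
            vals = vals + coeff * t.data[taxon].to_numpy()
        vals = vals + rng.normal(0.0, noise_sd, size=n)
        data[s["name"]] = np.clip(vals, 0.0, None)
    df = pd.DataFrame(data, index=t.data.index)
    return FeatureTable(df, mode="counts")


def planted_chain_config(seed: int = 0, n_replicates: int = 9, n_modules: int = 4,
                         taxa_per_module: int = 5, n_background_taxa: int = 60,
                         taxon_noise_sd: float = 0.2) -> GeneratorConfig:
    """Regime with identifiable microbe -> gene -> nutrient chains.

    Correlation screening cannot tell a gene's driver apart from the
    driver's module-mates (they are exchangeable proxies of the same latent
    factor), so in this regime every gene is driven by a whole module (all
    members, equal signed coefficients) and every nutrient by exactly one
    module; the implied truth is then the full member x gene x nutrient
    join and is recoverable. Module factors are independent of the
    treatment design (no shifts), a large stable background pool keeps
    compositional closure mild, and 9 replicates per cell (54 samples)
    make the loose |r| > 0.6 screen selective.
    """
    gene_spec = []
    cycles = ["C", "N", "P"]
    for m in range(n_modules):
        for gi, sign in enumerate((1.0, -1.0)):
            gene_spec.append({
                "name": f"K{20000 + 2 * m + gi:05d}",
                "display": f"enzyme-{2 * m + gi}",
                "cycle": cycles[m % 3],
                "drivers": {f"M{m + 1}_T{j + 1}": sign * 5.0
                            for j in range(taxa_per_module)},
                "noise_sd": 0.0005,
            })
    nutrient_spec = []
    for m in range(n_modules):
        coeffs = np.zeros(n_modules)
        coeffs[m] = 2.0
        nutrient_spec.append({"name": f"NUT{m + 1}", "pool": "C",
                              "coeffs": coeffs, "noise_sd": 0.2})
    return GeneratorConfig(
        seed=seed, n_replicates=n_replicates, n_modules=n_modules,
        taxa_per_module=taxa_per_module, n_background_taxa=n_background_taxa,
        background_sd=0.3, taxon_noise_sd=taxon_noise_sd,
        treatment_effects=np.zeros((n_modules, 6)),
        nutrient_spec=nutrient_spec, gene_spec=gene_spec,
    )


def generate_dataset(cfg: GeneratorConfig):
    """Full bundle: (community table, metadata, nutrients, genes, truth)."""
    table, meta, truth = generate_community(cfg)
    nutrients = generate_nutrients(truth.module_factors, cfg)
    genes = generate_gene_table(table, cfg)
    return table, meta, nutrients, genes, truth
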