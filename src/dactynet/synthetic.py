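"""Synthetic orchid–fungus community generator with planted structure.

Emulates the statistical shape of a multi-species orchid mycorrhizal
amplicon study: 14 orchid species spread over five habitat classes and one
to three populations each (three root samples per population), a pool of
mycorrhizal OTUs organised in habitat blocks (an OTU of block h associates
with species of habitat h with probability ``p_within`` and with other
species with probability ``p_between``), a minority of habitat-indifferent
generalist OTUs, negative-binomial read counts with log-normal OTU size
effects, plus deliberately injected nuisance columns: global singleton/
doubleton OTUs and non-mycorrhizal taxa, which exercise the filtering
stage. The planted block structure, indicator OTUs and nuisance ids are
returned as ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import (
    DataValidationError,
    Habitat,
    OtuTable,
    Ploidy,
    SampleMetadata,
    TaxonomyRecord,
)

__all__ = ["SimConfig", "GroundTruth", "simulate", "paperlike_preset"]

#: The fourteen study species: (name, habitat, ploidy, genome formula).
DACTYLORHIZA_SPECIES: tuple[tuple[str, str, str, str], ...] = (
    ("D_sambucina", "mediterranean", "2x", "SS"),
    ("D_romana", "mediterranean", "2x", "SS"),
    ("D_insularis", "mediterranean", "3x", "SSS"),
    ("D_markusii", "mediterranean", "2x", "SS"),
    ("D_sphagnicola", "peat_bog", "4x", "FmFmII"),
    ("D_maculata", "peat_bog", "4x", "FmFm"),
    ("D_fuchsii", "wetland", "2x", "FF"),
    ("D_majalis", "wetland", "4x", "FFII"),
    ("D_viridis", "wetland", "2x", "VV"),
    ("D_elata", "wetland", "4x", "FmFmII"),
    ("D_praetermissa", "coastal", "4x", "FFII"),
    ("D_incarnata", "coastal", "2x", "II"),
    ("D_alpestris", "alpine_boreal", "4x", "FFII"),
    ("D_lapponica", "alpine_boreal", "4x", "FFII"),
)

#: Mycorrhizal family/clade labels with their approximate OTU-pool weights
#: (Tulasnellaceae-dominated, as in real orchid root communities).
_FAMILY_WEIGHTS = (
    ("Tulasnellaceae", 31),
    ("Ceratobasidiaceae", 33),
    ("Sebacinales_A", 9),
    ("Sebacinales_B", 23),
    ("Thelephoraceae", 19),
)

#: Saprotrophic / doubtfully mycorrhizal genera used for junk spike-ins.
_JUNK_GENERA = (
    "Mycena",
    "Armillaria",
    "Clavulina",
    "Coprinus",
    "Cortinarius",
    "Inocybe",
    "Marasmius",
    "Psathyrella",
    "Atractiella",
)

_HABITAT_ORDER = [h.value for h in Habitat]


@dataclass
class SimConfig:
    """Study-design and noise parameters of the generator.

    Defaults mirror the study design the analyses target: 14 species
    allocated 4/2/4/2/2 over the five habitat classes, three samples per
    population, ~115 mycorrhizal OTUs, ~800 reads per sample.
    """

    n_species: int = 14
    habitat_allocation: dict[str, int] = field(
        default_factory=lambda: {
            "mediterranean": 4,
            "peat_bog": 2,
            "wetland": 4,
            "coastal": 2,
            "alpine_boreal": 2,
        }
    )
    populations_per_species: int | tuple[int, ...] = 2
    samples_per_population: int = 3
    n_otus_mycorrhizal: int = 115
    n_otus_junk: int = 60
    p_within: float = 0.5
    p_between: float = 0.02
    generalist_fraction: float = 0.1
    p_generalist: float = 0.4
    read_depth: float = 800.0
    dispersion: float = 0.5
    rare_otu_rate: float = 30.0
    population_retention: float = 0.7
    n_planted_indicators: int = 3
    indicator_habitat: str = "peat_bog"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_between < self.p_within <= 1.0):
            raise DataValidationError("need 0 <= p_between < p_within <= 1")
        if sum(self.habitat_allocation.values()) != self.n_species:
            raise DataValidationError("habitat allocation must sum to n_species")
        if isinstance(self.populations_per_species, tuple):
            if len(self.populations_per_species) != self.n_species:
                raise DataValidationError(
                    "per-species population counts must have length n_species"
                )
            counts = self.populations_per_species
        else:
            counts = (self.populations_per_species,) * self.n_species
        if any(c < 1 for c in counts):
            raise DataValidationError("each species needs >= 1 population")
        if self.samples_per_population < 1:
            raise DataValidationError("samples_per_population must be >= 1")
        if not (0.0 <= self.generalist_fraction <= 1.0):
            raise DataValidationError("generalist_fraction must be in [0, 1]")
        if self.rare_otu_rate < 0:
            raise DataValidationError("rare_otu_rate must be >= 0")
        if self.n_planted_indicators < 0:
            raise DataValidationError("n_planted_indicators must be >= 0")
        if self.indicator_habitat not in self.habitat_allocation:
            raise DataValidationError("indicator_habitat not in habitat allocation")

    def population_counts(self) -> tuple[int, ...]:
        if isinstance(self.populations_per_species, tuple):
            return self.populations_per_species
        return (self.populations_per_species,) * self.n_species


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    otu_block: dict[str, str | None]  # mycorrhizal OTU -> habitat block (None = generalist)
    module_partition: dict[str, str]  # node (species or block OTU) -> habitat
    planted_indicators: list[str]
    rare_otu_ids: list[str]
    junk_otu_ids: list[str]
    expected_depth: dict[str, float]
    #: the species–OTU links actually drawn (species -> set of mycorrhizal
    #: OTU ids), before read-count sampling; the reference network for
    #: planted-module recovery tests
    planted_prevalence: dict[str, set[str]] = field(default_factory=dict)


def paperlike_preset(seed: int = 0) -> SimConfig:
    """Configuration calibrated to the study scale.

    Ten species get three populations and four get two (38 populations,
    114 samples in total); ~115 mycorrhizal OTUs in five habitat blocks.
    """
    return SimConfig(
        populations_per_species=(3,) * 10 + (2,) * 4,
        seed=seed,
    )


def _species_table(cfg: SimConfig) -> list[tuple[str, str, str, str]]:
    default_alloc = {
        "mediterranean": 4,
        "peat_bog": 2,
        "wetland": 4,
        "coastal": 2,
        "alpine_boreal": 2,
    }
    if cfg.n_species == 14 and cfg.habitat_allocation == default_alloc:
        return list(DACTYLORHIZA_SPECIES)
    table = []
    ploidies = ["2x", "4x", "2x", "4x", "3x"]
    i = 0
    for h in _HABITAT_ORDER:
        for _ in range(cfg.habitat_allocation.get(h, 0)):
            table.append((f"sp{i + 1:02d}", h, ploidies[i % len(ploidies)], "XX"))
            i += 1
    return table


def simulate(
    cfg: SimConfig,
) -> tuple[OtuTable, list[SampleMetadata], list[TaxonomyRecord], GroundTruth]:
    """Draw one synthetic dataset; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    species = _species_table(cfg)
    sp_names = [s[0] for s in species]
    sp_habitat = {s[0]: s[1] for s in species}
    habitats_used = [h for h in _HABITAT_ORDER if cfg.habitat_allocation.get(h, 0) > 0]

    # ---- sampling design -------------------------------------------------
    meta: list[SampleMetadata] = []
    samples_of_pop: dict[str, list[int]] = {}
    pops_of_species: dict[str, list[str]] = {}
    sample_ids: list[str] = []
    pop_counts = cfg.population_counts()
    for (name, hab, plo, gen), n_pop in zip(species, pop_counts):
        pops_of_species[name] = []
        for p in range(n_pop):
            pop_id = f"{name}_p{p + 1}"
            pops_of_species[name].append(pop_id)
            samples_of_pop[pop_id] = []
            for s in range(cfg.samples_per_population):
                sid = f"{pop_id}_s{s + 1}"
                samples_of_pop[pop_id].append(len(sample_ids))
                sample_ids.append(sid)
                meta.append(
                    SampleMetadata(
                        sample_id=sid,
                        species=name,
                        population_id=pop_id,
                        habitat=Habitat(hab),
                        ploidy=Ploidy(plo),
                        genome=gen,
                    )
                )

    # ---- mycorrhizal OTU pool: blocks, generalists, planted indicators ---
    n_myc = cfg.n_otus_mycorrhizal
    n_gen = int(round(cfg.generalist_fraction * n_myc))
    n_block = n_myc - n_gen
    block_of: list[str | None] = []
    for j in range(n_block):
        block_of.append(habitats_used[j % len(habitats_used)])
    block_of.extend([None] * n_gen)
    otu_ids = [f"OTU{j + 1}" for j in range(n_myc)]

    planted: list[str] = []
    ind_candidates = [
        j for j, b in enumerate(block_of) if b == cfg.indicator_habitat
    ][: cfg.n_planted_indicators]
    planted = [otu_ids[j] for j in ind_candidates]
    if len(planted) < cfg.n_planted_indicators:
        raise DataValidationError("not enough block OTUs to plant indicators")

    incidence = np.zeros((len(sp_names), n_myc), dtype=np.int8)
    for j in range(n_myc):
        b = block_of[j]
        if otu_ids[j] in planted:
            for i, sp in enumerate(sp_names):
                incidence[i, j] = 1 if sp_habitat[sp] == b else 0
            continue
        for i, sp in enumerate(sp_names):
            if b is None:
                p = cfg.p_generalist
            else:
                p = cfg.p_within if sp_habitat[sp] == b else cfg.p_between
            incidence[i, j] = 1 if rng.random() < p else 0
        if incidence[:, j].sum() == 0:
            if b is None:
                cand = list(range(len(sp_names)))
            else:
                cand = [i for i, sp in enumerate(sp_names) if sp_habitat[sp] == b]
            incidence[rng.choice(cand), j] = 1

    # log-normal OTU size effects; planted indicators get a strong effect
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=n_myc)
    for j in ind_candidates:
        weights[j] *= 4.0

    # ---- per-population occurrence and per-sample counts -----------------
    n_samples = len(sample_ids)
    counts = np.zeros((n_samples, n_myc), dtype=np.int64)
    shape = cfg.dispersion
    for i, sp in enumerate(sp_names):
        linked = np.nonzero(incidence[i])[0]
        for pop_id in pops_of_species[sp]:
            present = np.array(
                [
                    (otu_ids[j] in planted and block_of[j] == sp_habitat[sp])
                    or rng.random() < cfg.population_retention
                    for j in linked
                ]
            )
            pres_idx = linked[present] if present.size else linked[:0]
            if pres_idx.size == 0 and linked.size:
                pres_idx = linked[[int(np.argmax(weights[linked]))]]
            if pres_idx.size == 0:
                continue
            w = weights[pres_idx]
            p_rel = w / w.sum()
            for srow in samples_of_pop[pop_id]:
                mu = cfg.read_depth * p_rel
                counts[srow, pres_idx] = rng.negative_binomial(
                    shape, shape / (shape + mu)
                )

    # guarantee planted (non-rare) OTUs clear the singleton/doubleton filter:
    # totals below 3 are topped up in a random sample of a linked species
    totals = counts.sum(axis=0)
    for j in range(n_myc):
        if totals[j] < 3:
            linked_sp = np.nonzero(incidence[:, j])[0]
            sp = sp_names[int(rng.choice(linked_sp))]
            pop = pops_of_species[sp][int(rng.integers(len(pops_of_species[sp])))]
            srow = samples_of_pop[pop][int(rng.integers(len(samples_of_pop[pop])))]
            counts[srow, j] += 3 - totals[j]

    taxonomy: list[TaxonomyRecord] = []
    fam_labels = [f for f, _ in _FAMILY_WEIGHTS]
    fam_probs = np.array([w for _, w in _FAMILY_WEIGHTS], dtype=float)
    fam_probs /= fam_probs.sum()
    for j in range(n_myc):
        taxonomy.append(
            TaxonomyRecord(
                otu_id=otu_ids[j],
                family_or_clade=fam_labels[int(rng.choice(len(fam_labels), p=fam_probs))],
                percent_identity=float(rng.uniform(91.0, 99.9)),
            )
        )

    # ---- junk (non-mycorrhizal) spike-ins --------------------------------
    junk_ids: list[str] = []
    junk_cols = []
    next_id = n_myc + 1
    for _ in range(cfg.n_otus_junk):
        oid = f"OTU{next_id}"
        next_id += 1
        junk_ids.append(oid)
        col = np.zeros(n_samples, dtype=np.int64)
        hits = rng.choice(n_samples, size=int(rng.integers(1, 6)), replace=False)
        col[hits] = rng.integers(1, 20, size=hits.size)
        if col.sum() < 3:
            col[hits[0]] += 3 - col.sum()
        junk_cols.append(col)
        if rng.random() < 0.2:
            # whitelist family but identity at or below the >90% cutoff
            taxonomy.append(
                TaxonomyRecord(
                    otu_id=oid,
                    family_or_clade=fam_labels[
                        int(rng.choice(len(fam_labels), p=fam_probs))
                    ],
                    percent_identity=float(rng.uniform(75.0, 90.0)),
                )
            )
        else:
            taxonomy.append(
                TaxonomyRecord(
                    otu_id=oid,
                    family_or_clade=str(rng.choice(_JUNK_GENERA)),
                    percent_identity=float(rng.uniform(80.0, 99.0)),
                )
            )

    # ---- rare OTUs: injected global singletons/doubletons ----------------
    rare_ids: list[str] = []
    rare_cols = []
    n_rare = int(rng.poisson(cfg.rare_otu_rate)) if cfg.rare_otu_rate > 0 else 0
    for _ in range(n_rare):
        oid = f"OTU{next_id}"
        next_id += 1
        rare_ids.append(oid)
        col = np.zeros(n_samples, dtype=np.int64)
        total = int(rng.integers(1, 3))
        for _r in range(total):
            col[int(rng.integers(n_samples))] += 1
        rare_cols.append(col)
        taxonomy.append(
            TaxonomyRecord(
                otu_id=oid,
                family_or_clade=fam_labels[int(rng.choice(len(fam_labels), p=fam_probs))],
                percent_identity=float(rng.uniform(91.0, 99.9)),
            )
        )

    all_ids = otu_ids + junk_ids + rare_ids
    blocks = [counts]
    if junk_cols:
        blocks.append(np.stack(junk_cols, axis=1))
    if rare_cols:
        blocks.append(np.stack(rare_cols, axis=1))
    full = np.concatenate(blocks, axis=1)
    table = OtuTable(sample_ids, all_ids, full)

    module_partition = {sp: sp_habitat[sp] for sp in sp_names}
    module_partition.update(
        {otu_ids[j]: b for j, b in enumerate(block_of) if b is not None}
    )
    truth = GroundTruth(
        otu_block={otu_ids[j]: block_of[j] for j in range(n_myc)},
        module_partition=module_partition,
        planted_indicators=planted,
        rare_otu_ids=rare_ids,
        junk_otu_ids=junk_ids,
        expected_depth={s: cfg.read_depth for s in sample_ids},
        planted_prevalence={
            sp: {otu_ids[j] for j in np.nonzero(incidence[i])[0]}
            for i, sp in enumerate(sp_names)
        },
    )
    return table, meta, taxonomy, truth
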