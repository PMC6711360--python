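"""Synthetic waterbird gut-community generator.

Emulates the post-OTU-calling state of a four-species waterbird gut survey:
great cormorant, little egret, black-crowned night heron and black-headed
gull, with 7/11/8/5 individuals respectively and three intestinal sections
per individual. Each host species has a fixed mean genus composition built
from the prevalences reported for these birds (e.g. *Catellicoccus* at
58.86% of the gull community, Fusobacteria at 48.6% of the night-heron
community); individuals vary around the species mean by a Dirichlet draw,
sections resample the same individual composition (no section effect), and
reads are a multinomial draw at a log-normally distributed library size.

The generator also emits the matching taxonomy table (OTU -> genus ->
phylum), sample metadata and the fixed four-taxon host phylogeny, so the
entire downstream pipeline can run with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CountTable, SampleInfo

SPECIES = ("cormorant", "egret", "night_heron", "gull")

#: Host phylogeny: herons (egret + night heron) are sisters, the cormorant
#: joins them, and the gull is the outgroup.
HOST_TREE_NEWICK = "(((egret:1,night_heron:1):1,cormorant:2):1,gull:3):0;"

# Named dominant genera per species: genus -> (mean fraction, phylum).
# The "Clostridiaceae_unclassified" family-level bin is reported only as a
# range (8.18-14.06%) across species; the midpoint 11.12% is the default.
_NAMED_GENERA: dict[str, dict[str, tuple[float, str]]] = {
    "cormorant": {
        "Fusobacterium": (0.3243, "Fusobacteria"),
        "Clostridium_sensu_stricto": (0.0869, "Firmicutes"),
        "Campylobacter": (0.0816, "Proteobacteria"),
        "Clostridiaceae_unclassified": (0.1112, "Firmicutes"),
    },
    "egret": {
        "Fusobacterium": (0.1981, "Fusobacteria"),
        "Cetobacterium": (0.1067, "Fusobacteria"),
        "Clostridium_sensu_stricto": (0.0672, "Firmicutes"),
        "Clostridiaceae_unclassified": (0.1112, "Firmicutes"),
        "Helicobacter": (0.0720, "Proteobacteria"),
    },
    "night_heron": {
        "Fusobacterium": (0.2730, "Fusobacteria"),
        "Cetobacterium": (0.1333, "Fusobacteria"),
        "Clostridium_sensu_stricto": (0.0672, "Firmicutes"),
        "Clostridiaceae_unclassified": (0.1112, "Firmicutes"),
        "Helicobacter": (0.1110, "Proteobacteria"),
    },
    "gull": {
        "Catellicoccus": (0.5886, "Firmicutes"),
        "Lactobacillus": (0.0645, "Firmicutes"),
        "Clostridium_sensu_stricto": (0.0475, "Firmicutes"),
        "Clostridiaceae_unclassified": (0.1112, "Firmicutes"),
    },
}

# Phylum totals per species. The dominant-phylum values (cormorant
# Fusobacteria 39.4%, night-heron Fusobacteria 48.6%, egret Firmicutes
# 40.0%, gull Firmicutes 90.3% / Proteobacteria 9.2% / Fusobacteria 0.3%)
# are the reported ones; the remaining mass is distributed over the other
# dominant phyla so each species sums to 1, with minor phyla kept below 1%.
_PHYLUM_TOTALS: dict[str, dict[str, float]] = {
    "cormorant": {"Fusobacteria": 0.394, "Firmicutes": 0.340,
                  "Proteobacteria": 0.256, "Spirochaetae": 0.006,
                  "Bacteroidetes": 0.004},
    "egret": {"Firmicutes": 0.400, "Fusobacteria": 0.340,
              "Proteobacteria": 0.250, "Spirochaetae": 0.006,
              "Bacteroidetes": 0.004},
    "night_heron": {"Fusobacteria": 0.486, "Firmicutes": 0.280,
                    "Proteobacteria": 0.224, "Spirochaetae": 0.006,
                    "Bacteroidetes": 0.004},
    "gull": {"Firmicutes": 0.903, "Proteobacteria": 0.092,
             "Fusobacteria": 0.003, "Spirochaetae": 0.001,
             "Bacteroidetes": 0.001},
}

_N_INDIVIDUALS = {"cormorant": 7, "egret": 11, "night_heron": 8, "gull": 5}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesProfile:
    """Mean genus-level composition of one host species."""

    species_name: str
    genus_means: dict[str, float]  # genus -> mean fraction, sums to 1
    genus_phylum: dict[str, str]   # genus -> phylum

    def __post_init__(self) -> None:
        total = sum(self.genus_means.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"{self.species_name}: genus means sum to {total}, not 1"
            )
        if any(v < 0 for v in self.genus_means.values()):
            raise ConfigurationError(f"{self.species_name}: negative abundance")
        missing = set(self.genus_means) - set(self.genus_phylum)
        if missing:
            raise ConfigurationError(
                f"{self.species_name}: genera without phylum: {sorted(missing)}"
            )

    def phylum_totals(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for genus, mean in self.genus_means.items():
            out[self.genus_phylum[genus]] = out.get(self.genus_phylum[genus], 0.0) + mean
        return out


@dataclass
class GeneratorConfig:
    """Simulation parameters for the synthetic survey.

    ``individual_concentration`` is the Dirichlet concentration governing
    between-individual compositional variation (higher = individuals closer
    to the species mean). Library sizes are log-normal around ``depth_mean``
    truncated below at ``depth_min``, except for a ``depth_shallow_fraction``
    of samples drawn uniformly below ``depth_min`` to exercise the
    minimum-depth filter.
    """

    profiles: list[SpeciesProfile] = field(default_factory=list)
    n_individuals: dict[str, int] = field(default_factory=lambda: dict(_N_INDIVIDUALS))
    sections_per_individual: int = 3
    otus_per_genus: int = 4
    individual_concentration: float = 50.0
    depth_mean: int = 50_000
    depth_min: int = 20_000
    depth_shallow_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.profiles:
            self.profiles = build_species_profiles()
        if any(n <= 0 for n in self.n_individuals.values()):
            raise ConfigurationError("n_individuals must be positive")
        if self.sections_per_individual <= 0 or self.otus_per_genus <= 0:
            raise ConfigurationError("counts must be positive")
        if self.individual_concentration <= 0:
            raise ConfigurationError("individual_concentration must be positive")
        if self.depth_min < 20_000:
            raise ConfigurationError("depth_min below the 20,000-read floor")
        if not 0 <= self.depth_shallow_fraction < 1:
            raise ConfigurationError("depth_shallow_fraction must be in [0, 1)")


def build_species_profiles(
    named_genera: dict[str, dict[str, tuple[float, str]]] | None = None,
    phylum_totals: dict[str, dict[str, float]] | None = None,
    n_background_specific: int = 6,
    n_background_shared: int = 2,
) -> list[SpeciesProfile]:
    """Construct the four default species profiles.

    Named dominant genera take their reported mean prevalences; the
    remaining mass of each phylum is split evenly over background genera —
    ``n_background_specific`` genera unique to the species plus
    ``n_background_shared`` genera shared by all species — so the phylum
    aggregates equal the configured phylum totals exactly.
    """
    named_genera = named_genera if named_genera is not None else _NAMED_GENERA
    phylum_totals = phylum_totals if phylum_totals is not None else _PHYLUM_TOTALS
    profiles = []
    for species, named in named_genera.items():
        totals = phylum_totals[species]
        means: dict[str, float] = {}
        phyla: dict[str, str] = {}
        named_mass: dict[str, float] = {}
        for genus, (mean, phylum) in named.items():
            if phylum not in totals:
                raise ConfigurationError(
                    f"{species}: genus {genus} in phylum {phylum} with no total"
                )
            means[genus] = mean
            phyla[genus] = phylum
            named_mass[phylum] = named_mass.get(phylum, 0.0) + mean
        for phylum, total in totals.items():
            remainder = total - named_mass.get(phylum, 0.0)
            if remainder < -1e-12:
                raise ConfigurationError(
                    f"{species}: named genera exceed the {phylum} total "
                    f"({named_mass[phylum]:.4f} > {total:.4f})"
                )
            bg = [f"{phylum}_bg_{species}_{i}" for i in range(1, n_background_specific + 1)]
            bg += [f"{phylum}_shared_{i}" for i in range(1, n_background_shared + 1)]
            share = max(remainder, 0.0) / len(bg)
            for genus in bg:
                means[genus] = share
                phyla[genus] = phylum
        # normalise away accumulated float error (totals sum to 1 by design)
        total = sum(means.values())
        means = {g: v / total for g, v in means.items()}
        profiles.append(SpeciesProfile(species, means, phyla))
    return profiles


def _geometric_weights(k: int, ratio: float = 0.5) -> np.ndarray:
    w = ratio ** np.arange(k)
    return w / w.sum()


def otu_ids_for_genus(genus: str, otus_per_genus: int) -> list[str]:
    return [f"Otu_{genus}_{i}" for i in range(1, otus_per_genus + 1)]


def simulate_individual_composition(
    profile: SpeciesProfile,
    concentration: float,
    rng: np.random.Generator,
    otus_per_genus: int = 4,
) -> pd.Series:
    """One individual's OTU-level composition.

    Genus fractions are a Dirichlet draw with mean equal to the species
    profile (alpha = concentration * mean); each genus is then expanded to
    ``otus_per_genus`` OTUs by a fixed geometric (ratio 0.5) within-genus
    split. Returns fractions indexed by OTU ID, summing to 1.
    """
    if concentration <= 0:
        raise ConfigurationError("concentration must be positive")
    genera = list(profile.genus_means)
    if not genera:
        raise ConfigurationError("empty profile")
    means = np.array([profile.genus_means[g] for g in genera])
    positive = means > 0
    fractions = np.zeros(len(genera))
    if np.isinf(concentration):
        fractions = means
    else:
        fractions[positive] = rng.dirichlet(concentration * means[positive])
    weights = _geometric_weights(otus_per_genus)
    index, values = [], []
    for genus, frac in zip(genera, fractions):
        index.extend(otu_ids_for_genus(genus, otus_per_genus))
        values.extend(frac * weights)
    return pd.Series(values, index=index)


def _draw_depths(rng: np.random.Generator, n: int, cfg: GeneratorConfig) -> np.ndarray:
    """Log-normal library sizes truncated at depth_min, with a designated
    shallow fraction below the threshold."""
    sigma = 0.35
    mu = np.log(cfg.depth_mean) - sigma**2 / 2
    depths = np.maximum(rng.lognormal(mu, sigma, size=n), cfg.depth_min)
    n_shallow = int(round(cfg.depth_shallow_fraction * n))
    if n_shallow:
        idx = rng.choice(n, size=n_shallow, replace=False)
        depths[idx] = rng.integers(5_000, cfg.depth_min, size=n_shallow)
    return depths.astype(np.int64)


def simulate_count_table(
    config: GeneratorConfig | None = None,
) -> tuple[CountTable, SampleInfo, pd.DataFrame]:
    """Generate the full synthetic survey: counts, metadata and taxonomy.

    One multinomial draw per section sample from its individual's OTU
    composition; sample IDs encode species, individual and section
    (``gull_03_middle``). Reproducible bit-for-bit under ``config.seed``.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    profiles = {p.species_name: p for p in cfg.profiles}

    otu_index: list[str] = []
    tax_rows: list[tuple[str, str, str]] = []
    seen = set()
    for profile in cfg.profiles:
        for genus in profile.genus_means:
            if genus in seen:
                continue
            seen.add(genus)
            for otu in otu_ids_for_genus(genus, cfg.otus_per_genus):
                otu_index.append(otu)
                tax_rows.append((otu, genus, profile.genus_phylum[genus]))
    taxonomy = pd.DataFrame(tax_rows, columns=["otu", "genus", "phylum"]).set_index("otu")

    sample_ids, rows, meta = [], [], []
    n_samples = sum(cfg.n_individuals[s] for s in cfg.n_individuals) * cfg.sections_per_individual
    depths = _draw_depths(rng, n_samples, cfg)
    k = 0
    for species, n_ind in cfg.n_individuals.items():
        profile = profiles[species]
        for ind in range(1, n_ind + 1):
            comp = simulate_individual_composition(
                profile, cfg.individual_concentration, rng, cfg.otus_per_genus
            ).reindex(otu_index, fill_value=0.0)
            individual = f"{species}_{ind:02d}"
            p = comp.to_numpy()
            p = p / p.sum()
            for section in _section_names(cfg.sections_per_individual):
                counts = rng.multinomial(depths[k], p)
                sample_ids.append(f"{individual}_{section}")
                rows.append(counts)
                meta.append((species, individual, section))
                k += 1
    table = CountTable(
        pd.DataFrame(np.asarray(rows, dtype=np.int64), index=sample_ids, columns=otu_index)
    )
    info = SampleInfo(
        pd.DataFrame(meta, columns=["species", "individual", "section"], index=sample_ids)
    )
    return table, info, taxonomy


def _section_names(n: int) -> list[str]:
    from .community import SECTIONS

    if n <= len(SECTIONS):
        return list(SECTIONS[:n])
    raise ConfigurationError(f"at most {len(SECTIONS)} sections supported")


def host_phylogeny_fixture():
    """The fixed rooted host phylogeny ((egret, night_heron), cormorant), gull)."""
    import dendropy

    return dendropy.Tree.get(data=HOST_TREE_NEWICK, schema="newick",
                             preserve_underscores=True)
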