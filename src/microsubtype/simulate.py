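"""Synthetic stool-cohort generator with planted subtype structure.

Emulates the structure of the subtyping study: 914 stool samples split
376 CRC / 363 advanced adenoma (AA) / 175 normal controls (NC), four latent
gut-microbial subtypes of sizes 519/57/157/181 whose per-subtype disease
compositions follow the published subtype table, and one signature genus
per subtype (*Escherichia-Shigella* -> A, *Streptococcus* -> B,
*Blautia* -> C, *Bacteroides* -> D).

Per sample the model is Dirichlet-multinomial: a baseline genus
concentration vector (overdispersion controlled by a precision scalar) with
the subtype's signature genera multiplied by a fold-boost, an optional mild
extra boost of CRC-associated genera in CRC samples so differential and
classifier stages carry signal, then multinomial sequencing counts at fixed
depth.  Disease labels are assigned by exact largest-remainder quotas inside
each subtype (shuffled by the seed) so cohort disease margins are exact by
construction while still converging to the per-subtype probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import (
    AbundanceTable,
    SampleMetadata,
    TaxonTraitTable,
    parse_lineage,
)

# ---------------------------------------------------------------------------
# default genus panel: (genus, lineage, baseline proportion)
# Trait annotations further below are illustrative defaults for testing the
# machinery, not a curated literature review; real analyses should supply
# their own table.

_L = {
    "Bacteroidetes": "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales",
    "Proteobacteria": "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales",
    "Clostridia": "Bacteria;Firmicutes;Clostridia;Eubacteriales",
    "Bacilli": "Bacteria;Firmicutes;Bacilli;Lactobacillales",
    "Actinobacteria": "Bacteria;Actinobacteria;Actinomycetia;Bifidobacteriales",
    "Fusobacteria": "Bacteria;Fusobacteria;Fusobacteriia;Fusobacteriales",
    "Verrucomicrobia": "Bacteria;Verrucomicrobia;Verrucomicrobiae;Verrucomicrobiales",
    "Negativicutes": "Bacteria;Firmicutes;Negativicutes;Veillonellales",
    "Erysipelotrichia": "Bacteria;Firmicutes;Erysipelotrichia;Erysipelotrichales",
    "Desulfovibrionia": "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfovibrionales",
}

DEFAULT_PANEL: list[tuple[str, str, float]] = [
    ("Bacteroides", f"{_L['Bacteroidetes']};Bacteroidaceae;Bacteroides", 0.170),
    ("Prevotella", f"{_L['Bacteroidetes']};Prevotellaceae;Prevotella", 0.055),
    ("Parabacteroides", f"{_L['Bacteroidetes']};Tannerellaceae;Parabacteroides", 0.028),
    ("Alistipes", f"{_L['Bacteroidetes']};Rikenellaceae;Alistipes", 0.028),
    ("Escherichia-Shigella", f"{_L['Proteobacteria']};Enterobacteriaceae;Escherichia-Shigella", 0.040),
    ("Klebsiella", f"{_L['Proteobacteria']};Enterobacteriaceae;Klebsiella", 0.010),
    ("Sutterella", "Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;Sutterellaceae;Sutterella", 0.010),
    ("Desulfovibrio", f"{_L['Desulfovibrionia']};Desulfovibrionaceae;Desulfovibrio", 0.007),
    ("Faecalibacterium", f"{_L['Clostridia']};Oscillospiraceae;Faecalibacterium", 0.090),
    ("Blautia", f"{_L['Clostridia']};Lachnospiraceae;Blautia", 0.070),
    ("Ruminococcus", f"{_L['Clostridia']};Oscillospiraceae;Ruminococcus", 0.040),
    ("Roseburia", f"{_L['Clostridia']};Lachnospiraceae;Roseburia", 0.030),
    ("Subdoligranulum", f"{_L['Clostridia']};Oscillospiraceae;Subdoligranulum", 0.025),
    ("Agathobacter", f"{_L['Clostridia']};Lachnospiraceae;Agathobacter", 0.025),
    ("Eubacterium_hallii_group", f"{_L['Clostridia']};Lachnospiraceae;Eubacterium_hallii_group", 0.022),
    ("Dorea", f"{_L['Clostridia']};Lachnospiraceae;Dorea", 0.020),
    ("Anaerostipes", f"{_L['Clostridia']};Lachnospiraceae;Anaerostipes", 0.020),
    ("Coprococcus", f"{_L['Clostridia']};Lachnospiraceae;Coprococcus", 0.020),
    ("Romboutsia", f"{_L['Clostridia']};Peptostreptococcaceae;Romboutsia", 0.020),
    ("Clostridium_sensu_stricto_1", f"{_L['Clostridia']};Clostridiaceae;Clostridium_sensu_stricto_1", 0.020),
    ("Lachnoclostridium", f"{_L['Clostridia']};Lachnospiraceae;Lachnoclostridium", 0.015),
    ("Oscillibacter", f"{_L['Clostridia']};Oscillospiraceae;Oscillibacter", 0.010),
    ("Streptococcus", f"{_L['Bacilli']};Streptococcaceae;Streptococcus", 0.030),
    ("Lactobacillus", f"{_L['Bacilli']};Lactobacillaceae;Lactobacillus", 0.015),
    ("Enterococcus", f"{_L['Bacilli']};Enterococcaceae;Enterococcus", 0.008),
    ("Veillonella", f"{_L['Negativicutes']};Veillonellaceae;Veillonella", 0.010),
    ("Megamonas", f"{_L['Negativicutes']};Selenomonadaceae;Megamonas", 0.015),
    ("Phascolarctobacterium", f"{_L['Negativicutes']};Acidaminococcaceae;Phascolarctobacterium", 0.015),
    ("Holdemania", f"{_L['Erysipelotrichia']};Erysipelotrichaceae;Holdemania", 0.005),
    ("Solobacterium", f"{_L['Erysipelotrichia']};Erysipelotrichaceae;Solobacterium", 0.005),
    ("Eubacterium_fissicatena_group", f"{_L['Clostridia']};Lachnospiraceae;Eubacterium_fissicatena_group", 0.005),
    ("Bifidobacterium", f"{_L['Actinobacteria']};Bifidobacteriaceae;Bifidobacterium", 0.050),
    ("Collinsella", "Bacteria;Actinobacteria;Coriobacteriia;Coriobacteriales;Coriobacteriaceae;Collinsella", 0.015),
    ("Actinomyces", "Bacteria;Actinobacteria;Actinomycetia;Actinomycetales;Actinomycetaceae;Actinomyces", 0.008),
    ("Rothia", "Bacteria;Actinobacteria;Actinomycetia;Micrococcales;Micrococcaceae;Rothia", 0.007),
    ("Fusobacterium", f"{_L['Fusobacteria']};Fusobacteriaceae;Fusobacterium", 0.010),
    ("Akkermansia", f"{_L['Verrucomicrobia']};Akkermansiaceae;Akkermansia", 0.020),
]

#: signature genus of each planted subtype
SIGNATURE_TAXA = {
    "A": ["Escherichia-Shigella"],
    "B": ["Streptococcus"],
    "C": ["Blautia"],
    "D": ["Bacteroides"],
}

#: published per-subtype (CRC, AA, NC) counts; margins sum to 376/363/175
SUBTYPE_DISEASE_COUNTS = {
    "A": (223, 197, 99),
    "B": (25, 27, 5),
    "C": (59, 81, 17),
    "D": (69, 58, 54),
}

_TRAITS: dict[str, tuple[str, str, str, str, str]] = {
    # genus: (gram, oxygen, role, crc_assoc, biofilm)
    "Bacteroides": ("negative", "obligate_anaerobe", "neutral", "related", "no"),
    "Prevotella": ("negative", "obligate_anaerobe", "neutral", "none", "no"),
    "Parabacteroides": ("negative", "obligate_anaerobe", "neutral", "none", "no"),
    "Alistipes": ("negative", "obligate_anaerobe", "neutral", "none", "no"),
    "Escherichia-Shigella": ("negative", "facultative_anaerobe", "harmful", "positive", "yes"),
    "Klebsiella": ("negative", "facultative_anaerobe", "harmful", "positive", "yes"),
    "Sutterella": ("negative", "obligate_anaerobe", "neutral", "negative", "no"),
    "Desulfovibrio": ("negative", "obligate_anaerobe", "harmful", "related", "no"),
    "Faecalibacterium": ("positive", "obligate_anaerobe", "beneficial", "negative", "no"),
    "Blautia": ("positive", "obligate_anaerobe", "beneficial", "related", "no"),
    "Ruminococcus": ("positive", "obligate_anaerobe", "neutral", "none", "no"),
    "Roseburia": ("positive", "obligate_anaerobe", "beneficial", "negative", "no"),
    "Subdoligranulum": ("positive", "obligate_anaerobe", "neutral", "none", "no"),
    "Agathobacter": ("positive", "obligate_anaerobe", "beneficial", "none", "no"),
    "Eubacterium_hallii_group": ("positive", "obligate_anaerobe", "beneficial", "none", "no"),
    "Dorea": ("positive", "obligate_anaerobe", "neutral", "none", "no"),
    "Anaerostipes": ("positive", "obligate_anaerobe", "beneficial", "none", "no"),
    "Coprococcus": ("positive", "obligate_anaerobe", "beneficial", "negative", "no"),
    "Romboutsia": ("positive", "obligate_anaerobe", "neutral", "none", "no"),
    "Clostridium_sensu_stricto_1": ("positive", "obligate_anaerobe", "neutral", "none", "no"),
    "Lachnoclostridium": ("positive", "obligate_anaerobe", "neutral", "related", "no"),
    "Oscillibacter": ("negative", "obligate_anaerobe", "neutral", "related", "no"),
    "Streptococcus": ("positive", "facultative_anaerobe", "harmful", "positive", "yes"),
    "Lactobacillus": ("positive", "facultative_anaerobe", "beneficial", "related", "yes"),
    "Enterococcus": ("positive", "facultative_anaerobe", "harmful", "related", "yes"),
    "Veillonella": ("negative", "obligate_anaerobe", "harmful", "positive", "yes"),
    "Megamonas": ("negative", "obligate_anaerobe", "neutral", "none", "no"),
    "Phascolarctobacterium": ("negative", "obligate_anaerobe", "neutral", "none", "no"),
    "Holdemania": ("positive", "obligate_anaerobe", "neutral", "related", "no"),
    "Solobacterium": ("positive", "obligate_anaerobe", "harmful", "positive", "no"),
    "Eubacterium_fissicatena_group": ("positive", "obligate_anaerobe", "neutral", "none", "no"),
    "Bifidobacterium": ("positive", "obligate_anaerobe", "beneficial", "negative", "no"),
    "Collinsella": ("positive", "obligate_anaerobe", "neutral", "related", "no"),
    "Actinomyces": ("positive", "facultative_anaerobe", "harmful", "related", "yes"),
    "Rothia": ("positive", "aerobe", "neutral", "related", "yes"),
    "Fusobacterium": ("negative", "obligate_anaerobe", "harmful", "positive", "yes"),
    "Akkermansia": ("negative", "obligate_anaerobe", "beneficial", "negative", "no"),
}


@dataclass
class SubtypeSpec:
    name: str
    n_samples: int
    signature_taxa: list[str]
    signature_boost: float
    disease_probs: tuple[float, float, float]  # (pCRC, pAA, pNC)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"subtype {self.name}: n_samples must be >= 1")
        if abs(sum(self.disease_probs) - 1.0) > 1e-9:
            raise ValueError(f"subtype {self.name}: disease_probs must sum to 1")


@dataclass
class CohortDesign:
    taxa: list[str]
    lineages: dict[str, str]
    base_props: np.ndarray            # baseline composition, sums to 1
    precision: float                  # Dirichlet total concentration (overdispersion)
    depth: int                        # multinomial sequencing depth per sample
    subtypes: list[SubtypeSpec]
    crc_boost: float = 2.0            # extra fold on CRC-associated taxa in CRC samples
    crc_boost_taxa: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.taxa) == 0:
            raise ValueError("empty taxon panel")
        self.base_props = np.asarray(self.base_props, dtype=float)
        if self.base_props.shape != (len(self.taxa),):
            raise ValueError("base_props must align with taxa")
        if (self.base_props <= 0).any():
            raise ValueError("base concentrations must be positive")
        self.base_props = self.base_props / self.base_props.sum()
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.precision <= 0:
            raise ValueError("precision must be positive")

    @property
    def n_samples(self) -> int:
        return sum(s.n_samples for s in self.subtypes)

    @property
    def concentration(self) -> np.ndarray:
        return self.base_props * self.precision


def _largest_remainder(total: int, props: np.ndarray) -> np.ndarray:
    """Integer quotas summing to ``total`` with proportions ``props``."""
    props = np.asarray(props, dtype=float)
    props = props / props.sum()
    raw = props * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def default_design(
    scale: float = 1.0,
    signature_boost: float = 50.0,
    depth: int = 10_000,
    precision: float = 40.0,
    crc_boost: float = 2.0,
    seed: int = 0,
) -> CohortDesign:
    """Study-structured design: 914 samples, four subtypes, exact margins.

    At ``scale=1`` subtype sizes are (519, 57, 157, 181) and per-subtype
    disease counts follow the published subtype composition, so cohort
    disease margins are exactly (376 CRC, 363 AA, 175 NC).  Other scales
    shrink every count by largest-remainder rounding.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    taxa = [g for g, _, _ in DEFAULT_PANEL]
    lineages = {g: lin for g, lin, _ in DEFAULT_PANEL}
    props = np.array([p for _, _, p in DEFAULT_PANEL])
    subtypes = []
    for name in ("A", "B", "C", "D"):
        crc, aa, nc = SUBTYPE_DISEASE_COUNTS[name]
        total = crc + aa + nc
        n = max(1, int(round(total * scale)))
        subtypes.append(
            SubtypeSpec(
                name=name,
                n_samples=n,
                signature_taxa=list(SIGNATURE_TAXA[name]),
                signature_boost=signature_boost,
                disease_probs=(crc / total, aa / total, nc / total),
            )
        )
    crc_taxa = [g for g, t in _TRAITS.items() if t[3] == "positive"]
    return CohortDesign(
        taxa=taxa,
        lineages=lineages,
        base_props=props,
        precision=precision,
        depth=depth,
        subtypes=subtypes,
        crc_boost=crc_boost,
        crc_boost_taxa=crc_taxa,
        seed=seed,
    )


def balanced_design(
    n_per_subtype: int = 60,
    signature_boost: float = 50.0,
    depth: int = 10_000,
    precision: float | None = None,
    seed: int = 0,
) -> CohortDesign:
    """Exchangeable planted-K design: four equal subtypes, uniform baseline.

    Equal sizes and a symmetric baseline make the four planted clusters
    geometrically exchangeable, the standard setting for testing cluster-
    number recovery (coarser partitions have no privileged stable merge).
    Disease probabilities still follow the published per-subtype rows.
    """
    design = default_design(
        signature_boost=signature_boost, depth=depth, seed=seed
    )
    m = len(design.taxa)
    design.base_props = np.full(m, 1.0 / m)
    design.precision = float(precision) if precision is not None else float(m)
    design.crc_boost = 1.0
    for spec in design.subtypes:
        spec.n_samples = n_per_subtype
    return design


def generate_cohort(
    design: CohortDesign, seed: int | None = None
) -> tuple[AbundanceTable, list[SampleMetadata], pd.Series]:
    """Draw a cohort: counts table, metadata, and true subtype labels.

    Deterministic given (design, seed).  Disease labels inside each subtype
    are exact largest-remainder quotas of the subtype's disease
    probabilities, shuffled by the seed; sample order is shuffled globally.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    taxa = design.taxa
    idx = {t: i for i, t in enumerate(taxa)}
    crc_idx = [idx[t] for t in design.crc_boost_taxa if t in idx]

    rows, diseases, subtype_labels = [], [], []
    for spec in design.subtypes:
        quotas = _largest_remainder(spec.n_samples, np.array(spec.disease_probs))
        labels = np.repeat(["CRC", "AA", "NC"], quotas)
        rng.shuffle(labels)
        conc = design.concentration.copy()
        for t in spec.signature_taxa:
            if t not in idx:
                raise ValueError(f"signature taxon {t!r} not in panel")
            conc[idx[t]] *= spec.signature_boost
        for disease in labels:
            c = conc
            if disease == "CRC" and design.crc_boost != 1.0 and crc_idx:
                c = conc.copy()
                c[crc_idx] *= design.crc_boost
            comp = rng.dirichlet(c)
            rows.append(rng.multinomial(design.depth, comp))
            diseases.append(disease)
            subtype_labels.append(spec.name)

    n = len(rows)
    order = rng.permutation(n)
    ids = [f"S{i + 1:04d}" for i in range(n)]
    counts = pd.DataFrame(
        np.asarray(rows, dtype=float)[order], index=ids, columns=taxa
    )
    diseases = [diseases[i] for i in order]
    subtype_labels = [subtype_labels[i] for i in order]

    # light clinical covariates so association screens have material
    age = np.round(rng.normal(58, 12, size=n) + 3 * (np.array(diseases) == "CRC")).clip(18, 95)
    gender = np.where(rng.random(n) < 0.6, "Male", "Female")
    chol = np.round(rng.normal(4.6, 1.0, size=n), 3)
    ffa = np.round(rng.normal(430, 215, size=n), 1)
    meta = [
        SampleMetadata(
            ids[i],
            diseases[i],
            {
                "age": float(age[i]),
                "gender": str(gender[i]),
                "total_cholesterol": float(chol[i]),
                "free_fatty_acids": float(ffa[i]),
            },
        )
        for i in range(n)
    ]
    taxonomy = {t: parse_lineage(design.lineages.get(t, "")) for t in taxa}
    table = AbundanceTable(counts, taxonomy, is_relative=False)
    truth = pd.Series(subtype_labels, index=ids, name="subtype")
    return table, meta, truth


def default_trait_table(taxa: list[str] | None = None) -> TaxonTraitTable:
    """Illustrative trait annotations for the default panel.

    Unlisted taxa look up as unknown.  These assignments exist to exercise
    the characteristic scores and are not a literature-curated resource.
    """
    records = {}
    for genus, (gram, oxygen, role, crc, biofilm) in _TRAITS.items():
        if taxa is not None and genus not in taxa:
            continue
        records[genus] = {
            "gram": gram,
            "oxygen": oxygen,
            "role": role,
            "crc_assoc": crc,
            "biofilm": biofilm,
        }
    return TaxonTraitTable(records)
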