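"""Simulation configuration: study conditions for the synthetic family.

Branch lengths of the species tree are in expected substitutions per codon
site (the codon model is normalised to one substitution per codon per unit).
Birth/loss rates are events per lineage per branch-length unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

DEFAULT_SPECIES_TREE = "((A:0.20,B:0.20)AB:0.10,(C:0.20,D:0.20)CD:0.10)ROOT;"

MECHANISMS = ("tandem", "segmental", "te_ltr", "te_helitron", "te_cacta", "retro")

TE_CLASS_OF = {"te_ltr": "LTR", "te_helitron": "Helitron", "te_cacta": "CACTA"}


@dataclass
class SimulationConfig:
    species_tree: str = DEFAULT_SPECIES_TREE
    #: events per lineage per branch-length unit
    birth_rates: dict[str, float] = field(default_factory=lambda: {
        "tandem": 3.0, "segmental": 1.5, "te_ltr": 0.7,
        "te_helitron": 0.45, "te_cacta": 0.45, "retro": 0.7,
    })
    loss_rate: float = 0.0

    # codon model for sequence evolution
    kappa: float = 2.0
    omega_classes: tuple[tuple[float, float], ...] = (
        (0.70, 0.10), (0.25, 0.50), (0.05, 1.00),
    )  # (proportion, omega) per site class — a purifying family profile

    # seed (ancestral) gene
    n_codons: int = 300
    n_exons: int = 4
    domain_span: tuple[int, int] = (50, 200)   # codon columns encoding the domain
    domain_profile_id: str = "PF00862"
    family_name: str = "SuSy"

    # genome scaffold
    chroms_per_species: int = 2
    filler_genes_per_chrom: int = 40
    filler_cds_codons: int = 220
    intergenic_bp: int = 3000
    intron_bp: int = 150
    gc_content: float = 0.40
    genome_class: str = "standard"

    # TE structural signature parameters
    ltr_length: int = 300
    ltr_tsd_len: int = 5
    te_pad_bp: int = 350
    cacta_tir_len: int = 15
    hairpin_arm: int = 11
    hairpin_loop: int = 4

    # TE fragment-type proportions (types 1-4)
    fragment_type_probs: tuple[float, float, float, float] = (0.4, 0.2, 0.2, 0.2)

    # expression
    n_tissues: int = 16
    n_replicates: int = 3
    divergence_prob: float = 0.5
    effect_size: float = 2.0          # additive shift on the log2 scale
    noise_sd: float = 0.5

    max_family_size: int = 10_000

    def __post_init__(self):
        for mech, r in self.birth_rates.items():
            if mech not in MECHANISMS:
                raise ValueError(f"unknown mechanism {mech!r}")
            if r < 0:
                raise ValueError("birth rates must be >= 0")
        if self.loss_rate < 0:
            raise ValueError("loss rate must be >= 0")
        total = sum(p for p, _ in self.omega_classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("omega-class proportions must sum to 1")
        if any(w < 0 for _, w in self.omega_classes):
            raise ValueError("omega values must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "omega_classes" in raw:
            raw["omega_classes"] = tuple(tuple(x) for x in raw["omega_classes"])
        if "fragment_type_probs" in raw:
            raw["fragment_type_probs"] = tuple(raw["fragment_type_probs"])
        if "domain_span" in raw:
            raw["domain_span"] = tuple(raw["domain_span"])
        return cls(**raw)
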