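"""Expression simulation and dataset emission in standard formats."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..formats_io import write_fasta, write_gff3
from .config import SimulationConfig
from .genome import plant_te_structures
from .history import TruthLog, simulate_family_history
from .sequences import evolve_codon_sequences, make_seed_alignment

_LOG_OFFSET = 6.0  # raw = 2**(x + offset) - 1 keeps values positive and
                   # makes log2(raw + 1) exactly linear in the planted signal


def simulate_expression(truth: TruthLog, config: SimulationConfig,
                        seed: int) -> tuple[pd.DataFrame, dict[str, str]]:
    """Expression matrix for family genes with planted per-tissue divergence.

    Each duplication child copies its anchor parent's per-tissue baseline;
    with probability ``divergence_prob`` an additive shift of
    ``effect_size`` (log2 units) is planted in 1–3 random tissues. Replicate
    noise is Gaussian with SD ``noise_sd``. Truth records the planted
    divergent tissue set per (parent, child) pair.
    """
    rng = np.random.default_rng([seed, 3])
    tissues = [f"tissue{t + 1:02d}" for t in range(config.n_tissues)]
    samples = [f"{t}_r{k + 1}" for t in tissues for k in range(config.n_replicates)]
    groups = {s: s.rsplit("_r", 1)[0] for s in samples}

    order = sorted(truth.genes, key=lambda g: (truth.genes[g]["origin_event"], g))
    baselines: dict[str, np.ndarray] = {}
    pairs = []
    for gid in order:
        rec = truth.genes[gid]
        parent = rec.get("anchor_parent", "")
        if parent and parent in baselines:
            base = baselines[parent].copy()
            divergent: list[str] = []
            if rng.random() < config.divergence_prob:
                k = int(rng.integers(1, 4))
                chosen = rng.choice(config.n_tissues, size=k, replace=False)
                for t in sorted(chosen):
                    base[t] += config.effect_size * (1 if rng.random() < 0.5 else -1)
                    divergent.append(tissues[t])
            pairs.append({"gene_a": parent, "gene_b": gid,
                          "divergent_tissues": sorted(divergent)})
        else:
            base = rng.normal(0.0, 1.0, size=config.n_tissues)
        baselines[gid] = base

    rows = []
    for gid in sorted(baselines):
        x = np.repeat(baselines[gid], config.n_replicates)
        x = x + rng.normal(0.0, config.noise_sd, size=x.size)
        raw = np.maximum(0.0, 2.0 ** (x + _LOG_OFFSET) - 1.0)
        rows.append(raw)
    matrix = pd.DataFrame(rows, index=sorted(baselines), columns=samples)
    matrix.index.name = "gene_id"
    truth.expression_truth = {"tissues": tissues, "pairs": pairs,
                              "n_replicates": config.n_replicates}
    return matrix, groups


def emit_dataset(config: SimulationConfig, out_dir, seed: int,
                 force: bool = False) -> TruthLog:
    """Run the full generator and write the dataset to ``out_dir``.

    Files: genome.fasta, annotation.gff3, cds.fasta, proteins.fasta,
    expression.tsv (+ expression_groups.tsv), species_tree.nwk,
    seeds/<profile>.fasta, truth.json, manifest.json. Re-running with the
    same seed reproduces every file byte for byte.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    (out / "seeds").mkdir(parents=True, exist_ok=True)

    truth = simulate_family_history(config, seed)
    evolve_codon_sequences(truth, config, seed)
    genomes = plant_te_structures(truth, config, seed)
    matrix, groups = simulate_expression(truth, config, seed)

    chrom_seqs = {}
    gff_rows = []
    cds = {}
    proteins = {}
    for sp in sorted(genomes):
        g = genomes[sp]
        chrom_seqs.update(g.chrom_seqs)
        gff_rows.extend(g.gff_rows)
        cds.update(g.cds)
        proteins.update(g.proteins)

    write_fasta(dict(sorted(chrom_seqs.items())), out / "genome.fasta")
    write_gff3(gff_rows, {c: len(s) for c, s in sorted(chrom_seqs.items())},
               out / "annotation.gff3")
    write_fasta(dict(sorted(cds.items())), out / "cds.fasta")
    write_fasta(dict(sorted(proteins.items())), out / "proteins.fasta")
    matrix.to_csv(out / "expression.tsv", sep="\t")
    pd.Series(groups, name="tissue").rename_axis("sample").to_csv(
        out / "expression_groups.tsv", sep="\t")
    (out / "species_tree.nwk").write_text(config.species_tree + "\n")
    write_fasta(make_seed_alignment(config, seed),
                out / "seeds" / f"{config.domain_profile_id}.fasta")

    config_dict = dataclasses.asdict(config)
    truth_doc = {
        "seed": seed,
        "config": config_dict,
        "species": truth.species,
        "genes": truth.genes,
        "events": truth.events,
        "mrca_counts": truth.mrca_counts,
        "te_elements": truth.te_elements,
        "site_omegas": truth.site_omegas,
        "gene_tree": truth.gene_tree_newick(),
        "expression": truth.expression_truth,
        "family": config.family_name,
    }
    (out / "truth.json").write_text(json.dumps(truth_doc, indent=1, sort_keys=True,
                                               default=list) + "\n")
    manifest = {"seed": seed,
                "config_sha256": hashlib.sha256(
                    json.dumps(config_dict, sort_keys=True, default=list).encode()
                ).hexdigest()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return truth
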