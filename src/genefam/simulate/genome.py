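"""Materialise simulated genomes: chromosome sequences, GFF3 gene models,
and TE elements wrapping TE-carried gene copies.

Each species gets ``chroms_per_species`` chromosomes populated with filler
genes at regular spacing (the decoy/anchor background) into which family
genes are inserted according to their origin mechanism:

* ancestral — a random slot;
* tandem — 1–3 gene slots downstream of the anchor parent (same chromosome);
* segmental — the parent plus 5 flanking filler genes are copied as a block
  to a different chromosome (the copies are the collinear anchors);
* TE — the copy (whole gene or an in-frame CDS fragment, per fragment type)
  is wrapped in a class-specific element and inserted on another chromosome;
* retrogene — an intronless full-CDS copy inserted on another chromosome.

Intergenic sequence is i.i.d. at the configured GC content: detectors need
decoys, not a realistic repeat landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import codons as C
from .config import SimulationConfig
from .history import TruthLog

_COMP = str.maketrans("ACGT", "TGCA")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _random_dna(rng, n: int, gc: float) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    return "".join(rng.choice(["A", "C", "G", "T"],
                              size=n, p=[p_at, p_gc, p_gc, p_at]))


def _random_cds(rng, n_codons: int) -> str:
    idx = rng.integers(0, 61, size=n_codons)
    return "".join(C.SENSE_CODONS[i] for i in idx)


# fragment-type CDS windows as fractions of the parent CDS (codon units)
_FRAGMENT_WINDOWS = {2: (0.45, 1.0), 3: (0.0, 0.50), 4: (0.25, 0.70)}


@dataclass
class _GeneSpec:
    gene_id: str
    cds: str
    n_exons: int
    strand: str = "+"
    te_class: str = ""
    fragment_type: int = 0


@dataclass
class _Unit:
    gene: _GeneSpec
    body: str = ""
    features: list = field(default_factory=list)   # (type, rel_start, rel_end)
    te_record: dict | None = None


@dataclass
class SpeciesGenome:
    species: str
    chrom_seqs: dict[str, str]
    gff_rows: list[dict]
    cds: dict[str, str]
    proteins: dict[str, str]
    te_elements: list[dict]


def _gene_body(spec: _GeneSpec, rng, intron_bp: int, gc: float):
    """Genomic body and relative (1-based) exon coordinates for one gene."""
    cds = spec.cds
    n_ex = max(1, spec.n_exons)
    cuts = [round(len(cds) * k / n_ex) for k in range(n_ex + 1)]
    chunks = [cds[cuts[k]:cuts[k + 1]] for k in range(n_ex)]
    introns = [_random_dna(rng, intron_bp, gc) for _ in range(n_ex - 1)]
    parts = []
    exons = []
    pos = 0
    for k, chunk in enumerate(chunks):
        exons.append((pos + 1, pos + len(chunk)))
        parts.append(chunk)
        pos += len(chunk)
        if k < n_ex - 1:
            parts.append(introns[k])
            pos += len(introns[k])
    body = "".join(parts)
    if spec.strand == "-":
        L = len(body)
        body = _rc(body)
        exons = sorted((L - e + 1, L - s + 1) for s, e in exons)
    return body, exons


def _build_unit(spec: _GeneSpec, rng, config: SimulationConfig) -> _Unit:
    body, exons = _gene_body(spec, rng, config.intron_bp, config.gc_content)
    unit = _Unit(gene=spec)
    if not spec.te_class:
        unit.body = body
        unit.features = [("gene", 1, len(body))] + [("exon", s, e) for s, e in exons]
        return unit

    pad = config.te_pad_bp
    gc = config.gc_content
    if spec.te_class == "LTR":
        ltr = "TG" + _random_dna(rng, config.ltr_length - 4, gc) + "CA"
        tsd = _random_dna(rng, config.ltr_tsd_len, gc)
        left = tsd + ltr + _random_dna(rng, pad, gc)
        right = _random_dna(rng, pad, gc) + ltr + tsd
        elem_start, elem_end = len(tsd) + 1, len(left) + len(body) + len(right) - len(tsd)
    elif spec.te_class == "Helitron":
        arm = _random_dna(rng, config.hairpin_arm, gc)
        hp5 = arm + _random_dna(rng, config.hairpin_loop, gc) + _rc(arm)
        arm3 = _random_dna(rng, config.hairpin_arm, gc)
        hp3 = arm3 + _random_dna(rng, config.hairpin_loop, gc) + _rc(arm3)
        left = "A" + "TC" + hp5 + _random_dna(rng, pad, gc)
        right = _random_dna(rng, pad, gc) + hp3 + "CTAG" + "T"
        elem_start, elem_end = 2, len(left) + len(body) + len(right) - 1
    elif spec.te_class == "CACTA":
        tir = "CACTA" + _random_dna(rng, config.cacta_tir_len - 5, gc)
        tsd = _random_dna(rng, 3, gc)
        left = tsd + tir + _random_dna(rng, pad, gc)
        right = _random_dna(rng, pad, gc) + _rc(tir) + tsd
        elem_start, elem_end = len(tsd) + 1, len(left) + len(body) + len(right) - len(tsd)
    else:
        raise ValueError(f"unknown TE class {spec.te_class!r}")

    unit.body = left + body + right
    off = len(left)
    unit.features = [("gene", off + 1, off + len(body))] + [
        ("exon", off + s, off + e) for s, e in exons]
    unit.te_record = {"class": spec.te_class, "rel_start": elem_start,
                      "rel_end": elem_end,
                      "tsd": tsd if spec.te_class in ("LTR", "CACTA") else "",
                      "fragment_type": spec.fragment_type}
    return unit


def plant_te_structures(truth: TruthLog, config: SimulationConfig,
                        seed: int) -> dict[str, SpeciesGenome]:
    """Build every species genome, planting all family genes and their TE
    structural signatures; coordinates are recorded in the truth log."""
    if not truth.cds:
        raise ValueError("evolve_codon_sequences must run before genome building")
    rng = np.random.default_rng([seed, 2])
    genomes = {}
    for sp in truth.species:
        genomes[sp] = _build_species(sp, truth, config, rng)
    truth.te_elements = [e for g in genomes.values() for e in g.te_elements]
    return genomes


def _build_species(sp: str, truth: TruthLog, config: SimulationConfig,
                   rng) -> SpeciesGenome:
    chrom_names = [f"{sp}_chr{i + 1}" for i in range(config.chroms_per_species)]
    units: dict[str, list[_Unit]] = {c: [] for c in chrom_names}

    # filler background
    for c in chrom_names:
        for k in range(config.filler_genes_per_chrom):
            spec = _GeneSpec(gene_id=f"{sp}_f{c[-1]}_{k + 1:03d}",
                             cds=_random_cds(rng, config.filler_cds_codons),
                             n_exons=1,
                             strand="+" if rng.random() < 0.5 else "-")
            units[c].append(_build_unit(spec, rng, config))

    members = sorted((g for g, r in truth.genes.items() if r["species"] == sp),
                     key=lambda g: (truth.genes[g]["origin_event"], g))
    member_set = set(members)
    placed: dict[str, tuple[str, int]] = {}  # gene -> (chrom, unit index)

    def far_index(chrom, width: int = 12) -> int:
        """Insertion slot at least ``width`` gene units from any family gene
        already on ``chrom`` (keeps planted mechanism labels unambiguous)."""
        fam_idx = [i for i, u in enumerate(units[chrom])
                   if u.gene.gene_id in member_set]
        slots = [i for i in range(len(units[chrom]) + 1)
                 if all(abs(i - f) > width for f in fam_idx)]
        if not slots:
            slots = list(range(len(units[chrom]) + 1))
        return slots[int(rng.integers(0, len(slots)))]

    def locate(gene_id):
        if gene_id in placed:
            chrom, idx = placed[gene_id]
            # indexes shift as units are inserted; refresh by search
            for c in chrom_names:
                for i, u in enumerate(units[c]):
                    if u.gene.gene_id == gene_id:
                        return c, i
        return None

    def insert(chrom, idx, unit):
        units[chrom].insert(idx, unit)
        placed[unit.gene.gene_id] = (chrom, idx)

    for gid in members:
        rec = truth.genes[gid]
        mech = rec["origin_mech"]
        cds = truth.cds[gid]
        anchor = locate(rec.get("anchor_parent", ""))
        if mech == "tandem" and anchor is not None:
            chrom, idx = anchor
            spec = _GeneSpec(gene_id=gid, cds=cds, n_exons=config.n_exons)
            insert(chrom, idx + int(rng.integers(1, 4)), _build_unit(spec, rng, config))
        elif mech == "segmental" and anchor is not None:
            chrom, idx = anchor
            flank = 5
            lo = max(0, idx - flank)
            hi = min(len(units[chrom]), idx + flank + 1)
            block = []
            for u in units[chrom][lo:hi]:
                if u.gene.gene_id == rec["anchor_parent"]:
                    spec = _GeneSpec(gene_id=gid, cds=cds, n_exons=config.n_exons)
                elif u.gene.gene_id in member_set:
                    continue  # never silently duplicate another family gene
                else:
                    spec = _GeneSpec(gene_id=f"{u.gene.gene_id}_s{rec['origin_event']}",
                                     cds=u.gene.cds, n_exons=u.gene.n_exons,
                                     strand=u.gene.strand)
                block.append(_build_unit(spec, rng, config))
            dest = _other_chrom(chrom_names, chrom, rng)
            at = far_index(dest)
            for j, u in enumerate(block):
                insert(dest, at + j, u)
        elif mech.startswith("te_") or rec.get("te_class"):
            frag = rec.get("fragment_type", 1) or 1
            gene_cds, n_ex = cds, config.n_exons
            if frag in _FRAGMENT_WINDOWS:
                f1, f2 = _FRAGMENT_WINDOWS[frag]
                nc = len(cds) // 3
                gene_cds = cds[3 * int(f1 * nc):3 * int(f2 * nc)]
                n_ex = 1
                truth.genes[gid]["fragment_span"] = (int(f1 * nc), int(f2 * nc))
            spec = _GeneSpec(gene_id=gid, cds=gene_cds, n_exons=n_ex,
                             te_class=rec["te_class"], fragment_type=frag)
            src = anchor[0] if anchor is not None else chrom_names[0]
            dest = _other_chrom(chrom_names, src, rng)
            insert(dest, far_index(dest), _build_unit(spec, rng, config))
        elif mech == "retro":
            spec = _GeneSpec(gene_id=gid, cds=cds, n_exons=1)
            src = anchor[0] if anchor is not None else chrom_names[0]
            dest = _other_chrom(chrom_names, src, rng)
            insert(dest, far_index(dest), _build_unit(spec, rng, config))
        else:  # ancestral, or an orphaned mechanism child (anchor lost)
            spec = _GeneSpec(gene_id=gid, cds=cds, n_exons=config.n_exons)
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            insert(chrom, far_index(chrom), _build_unit(spec, rng, config))

    return _assemble(sp, chrom_names, units, truth, config, rng)


def _other_chrom(chrom_names, chrom, rng):
    others = [c for c in chrom_names if c != chrom]
    if not others:
        return chrom
    return others[int(rng.integers(0, len(others)))]


def _assemble(sp, chrom_names, units, truth: TruthLog, config, rng) -> SpeciesGenome:
    chrom_seqs = {}
    gff_rows = []
    cds_out = {}
    prot_out = {}
    te_elements = []
    for chrom in chrom_names:
        parts = []
        pos = 0  # 0-based length so far
        for unit in units[chrom]:
            spacer = _random_dna(rng, config.intergenic_bp, config.gc_content)
            parts.append(spacer)
            pos += len(spacer)
            offset = pos  # body starts at 0-based `offset`
            parts.append(unit.body)
            pos += len(unit.body)
            gid = unit.gene.gene_id
            feats = {"exon": []}
            gene_span = None
            for ftype, s, e in unit.features:
                abs_s, abs_e = offset + s, offset + e
                if ftype == "gene":
                    gene_span = (abs_s, abs_e)
                else:
                    feats["exon"].append((abs_s, abs_e))
            strand = unit.gene.strand
            gff_rows.append({"seqid": chrom, "source": "genefam_sim", "type": "gene",
                             "start": gene_span[0], "end": gene_span[1], "score": ".",
                             "strand": strand, "phase": ".", "attributes": f"ID={gid}"})
            gff_rows.append({"seqid": chrom, "source": "genefam_sim", "type": "mRNA",
                             "start": gene_span[0], "end": gene_span[1], "score": ".",
                             "strand": strand, "phase": ".",
                             "attributes": f"ID={gid}.t1;Parent={gid}"})
            exon_list = sorted(feats["exon"])
            tx_order = exon_list if strand == "+" else exon_list[::-1]
            cum = 0
            phases = {}
            for s, e in tx_order:
                phases[(s, e)] = (3 - cum % 3) % 3
                cum += e - s + 1
            for s, e in exon_list:
                gff_rows.append({"seqid": chrom, "source": "genefam_sim", "type": "exon",
                                 "start": s, "end": e, "score": ".", "strand": strand,
                                 "phase": ".", "attributes": f"Parent={gid}.t1"})
                gff_rows.append({"seqid": chrom, "source": "genefam_sim", "type": "CDS",
                                 "start": s, "end": e, "score": ".", "strand": strand,
                                 "phase": str(phases[(s, e)]),
                                 "attributes": f"Parent={gid}.t1"})
            cds_out[gid] = unit.gene.cds
            prot = "".join(C.translate_codon(unit.gene.cds[i:i + 3])
                           for i in range(0, len(unit.gene.cds) - len(unit.gene.cds) % 3, 3))
            prot_out[gid] = prot
            if unit.te_record is not None:
                rec = dict(unit.te_record)
                rec.update({"gene": gid, "species": sp, "chromosome": chrom,
                            "start": offset + rec.pop("rel_start"),
                            "end": offset + rec.pop("rel_end")})
                te_elements.append(rec)
        tail = _random_dna(rng, config.intergenic_bp, config.gc_content)
        parts.append(tail)
        chrom_seqs[chrom] = "".join(parts)
    gff_rows.sort(key=lambda r: (r["seqid"], r["start"],
                                 {"gene": 0, "mRNA": 1, "exon": 2, "CDS": 3}[r["type"]],
                                 r["attributes"]))
    return SpeciesGenome(species=sp, chrom_seqs=chrom_seqs, gff_rows=gff_rows,
                         cds=cds_out, proteins=prot_out, te_elements=te_elements)
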