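"""Readers/writers for the external formats and the core genome containers.

Coordinates are 1-based inclusive everywhere (GFF3 convention); any half-open
arithmetic is confined to private helpers. All randomised operations in the
package take explicit integer seeds; this module owns no random state.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("genefam")

GENOME_CLASSES = ("compact", "standard")

#: tandem-pair distance windows by genome class (bp): compact genomes
#: (algae, Arabidopsis-sized) use 100 kb, all others 350 kb
TANDEM_WINDOW_BP = {"compact": 100_000, "standard": 350_000}


@dataclass
class GeneModel:
    """A gene locus represented by its single (longest-CDS) transcript."""

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_seq: str = ""
    protein_seq: str = ""
    rank: int = 0
    partial: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class GenomeAnnotation:
    """Gene models plus chromosome sizes, with per-chromosome gene ranks."""

    genes: dict[str, GeneModel]
    chrom_lengths: dict[str, int]
    genome_class: str = "standard"

    def __post_init__(self):
        if self.genome_class not in GENOME_CLASSES:
            raise ValueError(f"genome_class must be one of {GENOME_CLASSES}")
        for g in self.genes.values():
            L = self.chrom_lengths.get(g.chromosome)
            if L is not None and g.end > L:
                raise ValueError(
                    f"gene {g.gene_id} extends to {g.end} beyond {g.chromosome} length {L}"
                )
        self._assign_ranks()

    def _assign_ranks(self):
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes.values():
            by_chrom.setdefault(g.chromosome, []).append(g)
        for chrom_genes in by_chrom.values():
            chrom_genes.sort(key=lambda g: (g.start, g.gene_id))
            for i, g in enumerate(chrom_genes, start=1):
                g.rank = i

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        out = [g for g in self.genes.values() if g.chromosome == chromosome]
        return sorted(out, key=lambda g: g.rank)

    @property
    def tandem_window_bp(self) -> int:
        return TANDEM_WINDOW_BP[self.genome_class]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values.

    ``sample_groups`` maps each sample (column) to its tissue label.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str]

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.sample_groups)
        if missing:
            raise ValueError(f"samples without tissue label: {sorted(missing)}")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")

    def tissues(self) -> list[str]:
        seen = []
        for s in self.values.columns:
            t = self.sample_groups[s]
            if t not in seen:
                seen.append(t)
        return seen

    def samples_for(self, tissue: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == tissue]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 60):
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = ("seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes")


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff3_records(gff3_path):
    """Yield GFF3 feature rows as dicts; skip comments and pragmas."""
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{gff3_path}:{lineno}: expected 9 columns, got {len(fields)}")
            rec = dict(zip(_GFF_COLS, fields))
            rec["start"] = int(rec["start"])
            rec["end"] = int(rec["end"])
            rec["attrs"] = _parse_attributes(rec["attributes"])
            yield rec


def read_gff3_fasta(
    gff3_path,
    genome_fasta,
    cds_fasta=None,
    protein_fasta=None,
    genome_class: str = "standard",
) -> GenomeAnnotation:
    """Build a :class:`GenomeAnnotation` from GFF3 gene models and sequence files.

    One locus is represented by its longest-CDS transcript; alternative
    isoforms are collapsed. When ``cds_fasta`` is absent the CDS is spliced
    out of the genome (exon concatenation, reverse-complemented on the minus
    strand). Genes whose CDS length is not a multiple of 3 are flagged
    ``partial`` and retained, but excluded from codon-level analyses.
    """
    genome = read_fasta(genome_fasta)
    cds_by_id = read_fasta(cds_fasta) if cds_fasta else {}
    prot_by_id = read_fasta(protein_fasta) if protein_fasta else {}

    gene_rows: dict[str, dict] = {}
    tx_parent: dict[str, str] = {}
    tx_cds: dict[str, list[dict]] = {}
    tx_exons: dict[str, list[dict]] = {}

    for rec in _read_gff3_records(gff3_path):
        ftype = rec["type"]
        attrs = rec["attrs"]
        if ftype == "gene":
            gene_rows[attrs["ID"]] = rec
        elif ftype in ("mRNA", "transcript"):
            tx_parent[attrs["ID"]] = attrs.get("Parent", attrs["ID"])
        elif ftype == "CDS":
            tx_cds.setdefault(attrs.get("Parent", ""), []).append(rec)
        elif ftype == "exon":
            tx_exons.setdefault(attrs.get("Parent", ""), []).append(rec)

    # orphan CDS/exon features whose Parent is a gene directly
    for tid in list(tx_cds) + list(tx_exons):
        if tid not in tx_parent and tid in gene_rows:
            tx_parent[tid] = tid

    genes: dict[str, GeneModel] = {}
    for gid, grec in gene_rows.items():
        chrom = grec["seqid"]
        if chrom not in genome:
            raise ValueError(f"gene {gid}: unknown chromosome {chrom}")
        if grec["end"] > len(genome[chrom]) or grec["start"] < 1:
            raise ValueError(
                f"gene {gid}: coordinates {grec['start']}-{grec['end']} outside "
                f"{chrom} (length {len(genome[chrom])})"
            )
        transcripts = [t for t, p in tx_parent.items() if p == gid]
        if not transcripts:
            transcripts = [gid]

        def _cds_len(tid):
            return sum(r["end"] - r["start"] + 1 for r in tx_cds.get(tid, []))

        best_tx = max(transcripts, key=lambda t: (_cds_len(t), t))
        cds_parts = sorted(tx_cds.get(best_tx, []), key=lambda r: r["start"])
        exon_parts = sorted(tx_exons.get(best_tx, []), key=lambda r: r["start"])
        exons = [(r["start"], r["end"]) for r in (exon_parts or cds_parts)]
        strand = grec["strand"]

        cds_seq = cds_by_id.get(gid, cds_by_id.get(best_tx, ""))
        if not cds_seq and cds_parts:
            chunks = [genome[chrom][r["start"] - 1:r["end"]] for r in cds_parts]
            cds_seq = "".join(chunks)
            if strand == "-":
                cds_seq = revcomp(cds_seq)

        partial = bool(cds_seq) and len(cds_seq) % 3 != 0
        if partial:
            logger.warning("gene %s: CDS length %d not divisible by 3; flagged partial",
                           gid, len(cds_seq))
        protein = prot_by_id.get(gid, prot_by_id.get(best_tx, ""))
        if not protein and cds_seq and not partial:
            protein = str(Seq(cds_seq).translate()).rstrip("*")

        genes[gid] = GeneModel(
            gene_id=gid, chromosome=chrom, strand=strand,
            start=grec["start"], end=grec["end"], exons=exons,
            cds_seq=cds_seq, protein_seq=protein, partial=partial,
        )

    chrom_lengths = {c: len(s) for c, s in genome.items()}
    return GenomeAnnotation(genes=genes, chrom_lengths=chrom_lengths,
                            genome_class=genome_class)


def write_gff3(annotation_rows: list[dict], chrom_lengths: dict[str, int], path):
    """Write GFF3 rows (dicts with the 9 standard keys) with sequence-region pragmas."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(chrom_lengths):
            fh.write(f"##sequence-region {chrom} 1 {chrom_lengths[chrom]}\n")
        for r in annotation_rows:
            fh.write("\t".join(str(r[c]) for c in _GFF_COLS) + "\n")


# ---------------------------------------------------------------------------
# domtblout (HMMER domain-table dialect)

@dataclass
class DomainHitRecord:
    """One profile-vs-protein domain hit (domtblout row subset)."""

    gene_id: str
    profile_id: str
    bit_score: float
    e_value: float
    prot_start: int
    prot_end: int
    profile_coverage: float

    def __post_init__(self):
        if self.prot_start > self.prot_end:
            raise ValueError(f"{self.gene_id}/{self.profile_id}: start > end")
        if self.e_value < 0:
            raise ValueError("negative E-value")


def read_domtbl(path) -> tuple[list[DomainHitRecord], int]:
    """Parse a whitespace-delimited domtblout dialect.

    Columns used: target(gene) [0], query/profile accession [4] (falling back
    to query name [3] when accession is '-'), i-Evalue [12], bit score [13],
    hmm from/to [15,16], env from/to [19,20], and qlen [5] for coverage.
    Malformed rows are skipped with a logged warning; returns (hits, n_skipped).
    """
    hits: list[DomainHitRecord] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            try:
                profile = f[4] if f[4] != "-" else f[3]
                qlen = int(f[5])
                hmm_from, hmm_to = int(f[15]), int(f[16])
                cov = (hmm_to - hmm_from + 1) / qlen if qlen > 0 else 0.0
                hits.append(DomainHitRecord(
                    gene_id=f[0], profile_id=profile,
                    bit_score=float(f[13]), e_value=float(f[12]),
                    prot_start=int(f[19]), prot_end=int(f[20]),
                    profile_coverage=min(cov, 1.0),
                ))
            except (IndexError, ValueError) as exc:
                skipped += 1
                logger.warning("skipping malformed domtbl row: %s (%s)", line.strip()[:60], exc)
    return hits, skipped


def write_domtbl(hits: list[DomainHitRecord], path):
    """Write hits back out in the same domtblout dialect read_domtbl consumes."""
    with open(path, "w") as fh:
        fh.write("# target_name acc tlen query_name acc qlen E-value score bias "
                 "n of c-Evalue i-Evalue score bias hmm_from hmm_to ali_from ali_to "
                 "env_from env_to acc description\n")
        for h in hits:
            qlen = 1000  # placeholder total profile length basis
            hmm_to = max(1, round(h.profile_coverage * qlen))
            row = [h.gene_id, "-", "0", h.profile_id, h.profile_id, str(qlen),
                   f"{h.e_value:.3g}", f"{h.bit_score:.1f}", "0.0", "1", "1",
                   f"{h.e_value:.3g}", f"{h.e_value:.3g}", f"{h.bit_score:.1f}", "0.0",
                   "1", str(hmm_to), str(h.prot_start), str(h.prot_end),
                   str(h.prot_start), str(h.prot_end), "0.9", "-"]
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# tabular results

def write_tables(objects, path, sort_by: str | None = None):
    """Write a result collection as TSV with stable column and row order.

    Accepts a DataFrame, a list of dataclass instances, or a list of dicts.
    Rows are sorted by ``sort_by`` (default: first column) so identical
    inputs produce byte-identical files.
    """
    if isinstance(objects, pd.DataFrame):
        df = objects.copy()
    else:
        rows = [dataclasses.asdict(o) if dataclasses.is_dataclass(o) else dict(o)
                for o in objects]
        if rows:
            df = pd.DataFrame(rows, columns=list(rows[0].keys()))
        else:
            df = pd.DataFrame()
    if not df.empty:
        key = sort_by or df.columns[0]
        df = df.sort_values(by=key, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_expression_tsv(matrix_path, groups_path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a sample→tissue two-column TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0].to_dict()
    return ExpressionMatrix(values=values, sample_groups={str(k): str(v) for k, v in groups.items()})
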