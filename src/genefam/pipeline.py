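"""End-to-end orchestration: census → duplication mechanisms → phylogeny and
ancestral copy counts → Ka/Ks and sitewise selection → expression divergence.

The pipeline consumes a dataset directory in the layout the simulator emits
(genome.fasta, annotation.gff3, cds.fasta, proteins.fasta, seeds/,
species_tree.nwk, optional expression.tsv + expression_groups.tsv); each
stage is a plain function over the library modules and can be run or skipped
independently. Species membership of a gene is carried by its chromosome
name prefix (``<species>_chr...``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from . import census as census_mod
from . import dupmech, expression, phylo, selection, te
from .formats_io import (ExpressionMatrix, GenomeAnnotation, read_expression_tsv,
                         read_fasta, read_gff3_fasta, write_tables)

logger = logging.getLogger("genefam")


@dataclass
class PipelineReport:
    census: pd.DataFrame = field(default_factory=pd.DataFrame)
    census_counts: pd.DataFrame = field(default_factory=pd.DataFrame)
    mechanisms: pd.DataFrame = field(default_factory=pd.DataFrame)
    mechanism_percent: pd.DataFrame = field(default_factory=pd.DataFrame)
    mrca: pd.DataFrame = field(default_factory=pd.DataFrame)
    kaks: pd.DataFrame = field(default_factory=pd.DataFrame)
    kaks_hist: pd.DataFrame = field(default_factory=pd.DataFrame)
    kaks_means: pd.DataFrame = field(default_factory=pd.DataFrame)
    sitewise: pd.DataFrame = field(default_factory=pd.DataFrame)
    divergence: pd.DataFrame = field(default_factory=pd.DataFrame)
    gene_tree_newick: str = ""


def species_of_gene(gene, annotation: GenomeAnnotation) -> str:
    return gene.chromosome.split("_chr")[0]


def run_census(annotation: GenomeAnnotation, seeds_dir, seed: int = 0,
               e_init: float = 1.0, e_confirm: float = 0.01,
               min_coverage: float = 0.7,
               expression_evidence: set[str] = frozenset()) -> pd.DataFrame:
    """Profile scan + family assignment for every seed alignment in a dir."""
    proteins = {g.gene_id: g.protein_seq for g in annotation.genes.values()
                if g.protein_seq}
    hits = []
    for path in sorted(Path(seeds_dir).glob("*.fasta")):
        aln = read_fasta(path)
        profile = census_mod.build_domain_profile(aln, profile_id=path.stem)
        hits.extend(census_mod.scan_proteins(profile, proteins, e_init=e_init,
                                             seed=seed))
    assignments = census_mod.assign_families(hits, e_confirm=e_confirm)
    assignments = census_mod.flag_partial_members(
        assignments, expression_evidence=expression_evidence,
        min_coverage=min_coverage)
    rows = [{"gene_id": a.gene_id,
             "species": species_of_gene(annotation.genes[a.gene_id], annotation),
             "family": a.family, "status": a.status,
             "best_e": a.best_e, "coverage": a.best_coverage}
            for a in assignments if a.gene_id in annotation.genes]
    return pd.DataFrame(rows, columns=["gene_id", "species", "family",
                                       "status", "best_e", "coverage"])


def _shared_kmer_count(a: str, b: str, k: int = 6) -> int:
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    return len(ka & kb)


def find_anchor_pairs(annotation: GenomeAnnotation, family_genes: list[str],
                      flank_bp: int = dupmech.SEGMENTAL_FLANK_BP,
                      max_e: float = 0.01) -> list[tuple[str, str, float]]:
    """Homologous gene pairs (E <= max_e) between 50 kb windows around family
    genes, restricted to different chromosomes; candidates are prefiltered by
    shared protein 6-mers before alignment."""
    fam = [annotation.genes[g] for g in family_genes if g in annotation.genes]
    windows: dict[str, list] = {}
    for g in fam:
        lo, hi = g.start - flank_bp, g.end + flank_bp
        for other in annotation.genes_on(g.chromosome):
            if other.end >= lo and other.start <= hi and other.protein_seq:
                windows.setdefault(other.gene_id, []).append(g.gene_id)
    cand = sorted(windows)
    pairs = []
    for i, ga in enumerate(cand):
        a = annotation.genes[ga]
        for gb in cand[i + 1:]:
            b = annotation.genes[gb]
            if a.chromosome == b.chromosome:
                continue
            if _shared_kmer_count(a.protein_seq, b.protein_seq) < 5:
                continue
            sim = dupmech.local_align_proteins(a.protein_seq, b.protein_seq, ga, gb)
            if sim.e_value <= max_e:
                pairs.append((ga, gb, sim.score))
    return pairs


def run_te_stage(annotation: GenomeAnnotation, genome: dict[str, str],
                 family_genes: list[str], flank_bp: int = 50_000
                 ) -> tuple[list[str], pd.DataFrame]:
    """Scan 50 kb windows around family genes for TE structures; a family
    gene inside a detected element is TE-carried, and its fragment is typed
    against its closest full-length family paralog."""
    te_genes = []
    rows = []
    fam = [annotation.genes[g] for g in sorted(set(family_genes))
           if g in annotation.genes]
    full_len = [g for g in fam if g.n_exons > 1 and g.cds_seq]
    for g in fam:
        chrom_seq = genome[g.chromosome]
        lo = max(0, g.start - 1 - flank_bp)
        hi = min(len(chrom_seq), g.end + flank_bp)
        window = chrom_seq[lo:hi]
        for cls in ("LTR", "Helitron", "CACTA"):
            for elem in te.detect_te_elements(window, cls):
                e_start, e_end = elem.start + lo, elem.end + lo  # 1-based abs
                if e_start <= g.start and g.end <= e_end:
                    te_genes.append(g.gene_id)
                    frag = 0
                    parent = _closest_paralog(g, full_len)
                    if parent is not None:
                        try:
                            frag = te.classify_te_carried_fragment(
                                g.cds_seq, parent.cds_seq)
                        except ValueError:
                            frag = 0
                    rows.append({"gene_id": g.gene_id, "te_class": cls,
                                 "element_start": e_start, "element_end": e_end,
                                 "tsd": elem.tsd, "fragment_type": frag,
                                 "parent_id": parent.gene_id if parent else ""})
    df = pd.DataFrame(rows, columns=["gene_id", "te_class", "element_start",
                                     "element_end", "tsd", "fragment_type",
                                     "parent_id"])
    return sorted(set(te_genes)), df


def _closest_paralog(gene, candidates):
    best = None
    for c in candidates:
        if c.gene_id == gene.gene_id:
            continue
        sim = dupmech.local_align_proteins(gene.protein_seq, c.protein_seq,
                                           gene.gene_id, c.gene_id)
        key = (sim.identity, sim.query_coverage, c.gene_id)
        if best is None or key > best[0]:
            best = (key, c)
    return best[1] if best else None


def run_mechanism_stage(annotation: GenomeAnnotation, genome: dict[str, str],
                        census_df: pd.DataFrame):
    """Per-species duplication-mechanism classification for all families."""
    members = census_df[(census_df["family"] != "none")
                        & (census_df["status"] == "full")]
    all_summaries = []
    evidence = {"tandem_arrays": [], "blocks": [], "te": pd.DataFrame(),
                "retro": []}
    te_tables = []
    for species, sp_df in members.groupby("species"):
        fam_by_gene = dict(zip(sp_df["gene_id"], sp_df["family"]))
        gene_ids = sorted(fam_by_gene)
        arrays = []
        for family, f_df in sp_df.groupby("family"):
            arrays.extend(dupmech.detect_tandem_arrays(
                list(f_df["gene_id"]), annotation))
        anchors = find_anchor_pairs(annotation, gene_ids)
        blocks = dupmech.chain_collinear_blocks(anchors, annotation, annotation)
        seg = dupmech.classify_segmental(gene_ids, blocks, annotation)
        te_genes, te_df = run_te_stage(annotation, genome, gene_ids)
        retro = dupmech.detect_retrogenes(gene_ids, annotation)
        summary = dupmech.summarize_mechanisms(
            fam_by_gene, tandem_arrays=arrays, segmental_genes=seg,
            te_genes=te_genes, retro_calls=retro)
        summary.insert(1, "species", species)
        all_summaries.append(summary)
        te_tables.append(te_df)
        evidence["tandem_arrays"].extend(arrays)
        evidence["blocks"].extend(blocks)
        evidence["retro"].extend(retro)
    mech = (pd.concat(all_summaries, ignore_index=True) if all_summaries
            else pd.DataFrame(columns=["gene_id", "species", "family", "mechanisms"]))
    evidence["te"] = (pd.concat(te_tables, ignore_index=True) if te_tables
                      else pd.DataFrame())
    return mech, evidence


def run_phylo_stage(annotation: GenomeAnnotation, census_df: pd.DataFrame,
                    species_tree: dendropy.Tree, family: str,
                    n_boot: int = 100, seed: int = 0):
    """NJ gene tree with bootstrap, duplication-minimising rooting, LCA
    reconciliation, and MRCA copy counts at every internal species node."""
    fam = census_df[(census_df["family"] == family)
                    & (census_df["status"] == "full")]
    seqs = {}
    for gid in fam["gene_id"]:
        g = annotation.genes[gid]
        if g.protein_seq:
            seqs[gid] = g.protein_seq
    lengths = pd.Series({k: len(v) for k, v in seqs.items()})
    if lengths.empty:
        return None
    modal = lengths.mode().iloc[0]
    aln = {k: v for k, v in seqs.items() if len(v) == modal}
    if len(aln) < 3:
        return None
    tree = phylo.bootstrap_support(aln, n_reps=n_boot, seed=seed)
    species_of = {gid: species_of_gene(annotation.genes[gid], annotation)
                  for gid in aln}
    rooted = phylo.root_minimizing_duplications(tree, species_tree, species_of)
    rec = phylo.reconcile_lca(rooted, species_tree, species_of)
    rows = []
    for node in species_tree.preorder_internal_node_iter():
        label = phylo._species_label(node)
        rows.append({"family": family, "species_node": label,
                     "mrca_copies": phylo.mrca_copy_count(rec, node)})
    return {"tree": tree, "reconciled": rec,
            "mrca": pd.DataFrame(rows, columns=["family", "species_node",
                                                "mrca_copies"])}


def run_kaks_stage(annotation: GenomeAnnotation, mech: pd.DataFrame,
                   evidence: dict, groups: dict[str, str] | None = None,
                   method: str = "NG86") -> pd.DataFrame:
    """Ka/Ks for recently expanded pairs (tandem-evidence pairs plus
    retrogene parent/child pairs) that pass the overlap/identity filter."""
    pairs = []
    for arr in evidence.get("tandem_arrays", []):
        pairs.extend(arr.evidence)
    for call in evidence.get("retro", []):
        pairs.append((call.retro_id, call.parent_id))
    rows = []
    for ga, gb in sorted(set(tuple(sorted(p)) for p in pairs)):
        a, b = annotation.genes[ga], annotation.genes[gb]
        if a.partial or b.partial or not a.cds_seq or not b.cds_seq:
            continue
        try:
            aln = selection.backtranslate(
                _pair_protein_alignment(a.protein_seq, b.protein_seq, ga, gb),
                {ga: a.cds_seq, gb: b.cds_seq})
        except ValueError:
            continue
        filt = selection.filter_pair_alignment(aln)
        if not filt.accepted:
            continue
        try:
            res = selection.kaks_pair(aln, method=method)
        except ValueError:
            continue
        grp = (groups or {}).get(species_of_gene(a, annotation),
                                 species_of_gene(a, annotation))
        rows.append({"gene_a": ga, "gene_b": gb, "group": grp,
                     "ka": res.ka, "ks": res.ks, "ratio": res.ratio,
                     "S": res.S, "N": res.N, "method": res.method})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "group", "ka", "ks",
                                       "ratio", "S", "N", "method"])


def _pair_protein_alignment(pa: str, pb: str, ida: str, idb: str) -> dict[str, str]:
    """Global-ish protein alignment of a pair for back-translation (equal
    lengths pass through unchanged)."""
    if len(pa) == len(pb):
        return {ida: pa, idb: pb}
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = dupmech._MATRIX
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    aligner.open_end_gap_score = -12.0
    aligner.extend_end_gap_score = -1.0
    aln = aligner.align(pa, pb)[0]
    return {ida: aln[0], idb: aln[1]}


def summarize_kaks_distribution(kaks: pd.DataFrame, bin_width: float = 0.1,
                                alpha: float = 0.05):
    """Per-group Ka/Ks histograms over [0, 2] plus an overflow bin, group
    means, and a two-group mean comparison (Welch t-test)."""
    hist_rows = []
    mean_rows = []
    edges = np.arange(0.0, 2.0 + bin_width / 2, bin_width)
    for group, df in kaks.groupby("group"):
        defined = df[np.isfinite(df["ratio"])]
        undefined = len(df) - len(defined)
        if df.empty:
            logger.warning("group %s has no Ka/Ks results; omitted", group)
            continue
        counts, _ = np.histogram(defined["ratio"].clip(upper=1.999), bins=edges)
        overflow = int((defined["ratio"] >= 2.0).sum())
        for lo, c in zip(edges[:-1], counts):
            hist_rows.append({"group": group, "bin_lo": round(float(lo), 3),
                              "bin_hi": round(float(lo + bin_width), 3),
                              "count": int(c)})
        hist_rows.append({"group": group, "bin_lo": 2.0, "bin_hi": float("inf"),
                          "count": overflow})
        mean_rows.append({"group": group, "n": len(defined),
                          "n_undefined_ratio": undefined,
                          "mean_ka": float(df["ka"].mean()),
                          "mean_ks": float(df["ks"].mean()),
                          "mean_ratio": float(defined["ratio"].mean())
                          if len(defined) else float("nan")})
    hist = pd.DataFrame(hist_rows, columns=["group", "bin_lo", "bin_hi", "count"])
    means = pd.DataFrame(mean_rows, columns=["group", "n", "n_undefined_ratio",
                                             "mean_ka", "mean_ks", "mean_ratio"])
    if len(means) >= 2:
        g1, g2 = means["group"].iloc[0], means["group"].iloc[1]
        x = kaks[(kaks["group"] == g1) & np.isfinite(kaks["ratio"])]["ratio"]
        y = kaks[(kaks["group"] == g2) & np.isfinite(kaks["ratio"])]["ratio"]
        if len(x) >= 2 and len(y) >= 2:
            t, p = stats.ttest_ind(x, y, equal_var=False)
            means.attrs["comparison"] = {"groups": (g1, g2), "t": float(t),
                                         "p": float(p),
                                         "significant": bool(p < alpha)}
    return hist, means


def run_expression_stage(matrix: ExpressionMatrix, pairs: list[tuple[str, str]],
                         alpha: float = 0.05) -> pd.DataFrame:
    rows = []
    for ga, gb in pairs:
        if ga not in matrix.values.index or gb not in matrix.values.index:
            continue
        res = expression.paralog_divergence_test(ga, gb, matrix, alpha=alpha)
        rows.append({"gene_a": ga, "gene_b": gb,
                     "n_divergent_tissues": len(res.divergent_tissues),
                     "divergent_tissues": ",".join(sorted(res.divergent_tissues)),
                     "is_divergent": res.is_divergent})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "n_divergent_tissues",
                                       "divergent_tissues", "is_divergent"])


def run_pipeline(dataset_dir, out_dir=None, seed: int = 0, n_boot: int = 50,
                 run_sitewise: bool = False, groups: dict[str, str] | None = None
                 ) -> PipelineReport:
    """Full pipeline over a dataset directory (simulator layout).

    Expression and sitewise stages are optional: they run only when their
    inputs exist (expression.tsv) / are requested (``run_sitewise``).
    """
    d = Path(dataset_dir)
    for required in ("annotation.gff3", "genome.fasta"):
        if not (d / required).exists():
            raise FileNotFoundError(
                f"{required} missing from {d}; produce it with the simulator "
                "(emit_dataset) or point at a dataset directory")
    annotation = read_gff3_fasta(d / "annotation.gff3", d / "genome.fasta",
                                 cds_fasta=d / "cds.fasta" if (d / "cds.fasta").exists() else None,
                                 protein_fasta=d / "proteins.fasta" if (d / "proteins.fasta").exists() else None)
    genome = read_fasta(d / "genome.fasta")
    species_tree = None
    if (d / "species_tree.nwk").exists():
        species_tree = dendropy.Tree.get(path=str(d / "species_tree.nwk"),
                                         schema="newick")

    report = PipelineReport()
    census_df = run_census(annotation, d / "seeds", seed=seed)
    report.census = census_df
    members = census_df[(census_df["family"] != "none")
                        & (census_df["status"] == "full")]
    report.census_counts = (members.groupby(["species", "family"])
                            .size().rename("n_genes").reset_index())

    mech, evidence = run_mechanism_stage(annotation, genome, census_df)
    report.mechanisms = mech
    report.mechanism_percent = dupmech.mechanism_percentages(
        mech[["gene_id", "family", "mechanisms"]])

    if species_tree is not None:
        mrca_frames = []
        for family in sorted(members["family"].unique()):
            out = run_phylo_stage(annotation, census_df, species_tree, family,
                                  n_boot=n_boot, seed=seed)
            if out is not None:
                mrca_frames.append(out["mrca"])
                report.gene_tree_newick = out["tree"].as_string(schema="newick")
        if mrca_frames:
            report.mrca = pd.concat(mrca_frames, ignore_index=True)

    report.kaks = run_kaks_stage(annotation, mech, evidence, groups=groups)
    if not report.kaks.empty:
        report.kaks_hist, report.kaks_means = summarize_kaks_distribution(report.kaks)

    if run_sitewise and species_tree is not None and not members.empty:
        report.sitewise = _run_sitewise_stage(annotation, members)

    if (d / "expression.tsv").exists() and (d / "expression_groups.tsv").exists():
        matrix = read_expression_tsv(d / "expression.tsv", d / "expression_groups.tsv")
        pairs = [(r["gene_a"], r["gene_b"]) for _, r in report.kaks.iterrows()]
        report.divergence = run_expression_stage(matrix, pairs)

    if out_dir is not None:
        _write_report(report, out_dir)
    return report


def _run_sitewise_stage(annotation, members, max_seqs: int = 6) -> pd.DataFrame:
    rows = []
    for family, f_df in members.groupby("family"):
        seqs = {}
        for gid in sorted(f_df["gene_id"])[:max_seqs]:
            g = annotation.genes[gid]
            if g.cds_seq and not g.partial:
                seqs[gid] = g.cds_seq
        lengths = {len(s) for s in seqs.values()}
        if len(seqs) < 3 or len(lengths) != 1:
            continue
        prots = {k: "".join(selection.C.translate_codon(v[i:i + 3])
                            for i in range(0, len(v), 3)).rstrip("*")
                 for k, v in seqs.items()}
        aln = selection.CodonAlignment(ids=sorted(seqs),
                                       rows=[seqs[k][:3 * len(prots[k])]
                                             for k in sorted(seqs)])
        tree = phylo.nj_tree(phylo.protein_distance_matrix(prots))
        for r in selection.sitewise_selection_scan(aln, tree):
            rows.append({"family": family, "site": r.site,
                         "omega": r.omega_hat, "lrt": r.lrt_stat,
                         "p_value": r.p_value, "class": r.classification})
    return pd.DataFrame(rows, columns=["family", "site", "omega", "lrt",
                                       "p_value", "class"])


def _write_report(report: PipelineReport, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "census.tsv": report.census,
        "census_counts.tsv": report.census_counts,
        "mechanisms.tsv": report.mechanisms,
        "mechanism_percent.tsv": report.mechanism_percent,
        "mrca_counts.tsv": report.mrca,
        "kaks.tsv": report.kaks,
        "kaks_hist.tsv": report.kaks_hist,
        "kaks_means.tsv": report.kaks_means,
        "sitewise.tsv": report.sitewise,
        "expression_divergence.tsv": report.divergence,
    }
    for name, df in tables.items():
        if df is not None and not df.empty:
            write_tables(df, out / name)
    lines = ["# genefam pipeline report", ""]
    if not report.census_counts.empty:
        lines += ["## Family census (genes per species)", "",
                  report.census_counts.to_string(index=False), ""]
    if not report.mechanism_percent.empty:
        lines += ["## Expansion mechanisms (% of family members)", "",
                  report.mechanism_percent.to_string(index=False), ""]
    if not report.mrca.empty:
        lines += ["## Ancestral (MRCA) copy counts", "",
                  report.mrca.to_string(index=False), ""]
    if not report.kaks_means.empty:
        lines += ["## Ka/Ks group means", "",
                  report.kaks_means.to_string(index=False), ""]
    if not report.divergence.empty:
        n_div = int(report.divergence["is_divergent"].sum())
        lines += ["## Expression divergence", "",
                  f"{n_div}/{len(report.divergence)} tested pairs divergent "
                  "in >= 1 tissue", ""]
    (out / "report.md").write_text("\n".join(lines))
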