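"""File-level pipeline stages: each stage reads the previous stage's
artifacts from the output directory and writes its own as TSV/FASTA, so
stages can be re-run individually and compose into the full analysis."""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import yaml

from . import biotype as bt
from . import de as de_mod
from . import kmers, network, report, triplex
from .genome_io import (
    Annotation,
    CountMatrix,
    Genome,
    extract_promoters,
    load_count_table,
    parse_annotation,
    read_fasta,
    write_count_table,
    write_fasta,
    write_gff3,
    write_promoters_fasta,
)
from .identify import LncRNA, TranscriptAlignment, run_cascade
from .simulate import SimulationConfig, TriplexPlant, simulate_truth_bundle

DEFAULTS: dict = {
    "identify": {"min_identity": 0.95, "min_coverage": 0.75, "min_length": 200,
                 "min_samples": 10, "min_reads": 10},
    "biotype": {"window": 5000},
    "kmer": {"k": 4, "n_clusters": 10, "log_transform": False},
    "de": {"contrast": ["temperature", "30", "20"],
           "padj_threshold": 0.01, "lfc_threshold": 2.0},
    "coexpression": {"min_module_size": 30, "merge_cor": 0.9,
                     "cut_height_quantile": 0.99, "power": None},
    "triplex": {"min_len": 20, "max_error_rate": 0.05, "repeat_filter": True,
                "duplicate_cutoff": 5, "rho_min": 0.8, "p_max": 0.05},
}


def load_config(path: str | os.PathLike | None) -> dict:
    cfg = {k: dict(v) for k, v in DEFAULTS.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for stage, block in user.items():
            cfg.setdefault(stage, {}).update(block or {})
    return cfg


# ---------------------------------------------------------------------------
# Alignment table I/O


def write_alignments_tsv(alignments: list[TranscriptAlignment], path) -> None:
    rows = [
        (a.transcript_id, a.scaffold, a.strand,
         ",".join(f"{s}-{e}" for s, e in a.blocks),
         a.identity, a.query_coverage, a.sequence)
        for a in alignments
    ]
    pd.DataFrame(
        rows, columns=["transcript_id", "scaffold", "strand", "blocks",
                       "identity", "query_coverage", "sequence"]
    ).to_csv(path, sep="\t", index=False)


def read_alignments_tsv(path) -> list[TranscriptAlignment]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        blocks = tuple(
            tuple(int(x) for x in b.split("-")) for b in str(row.blocks).split(",")
        )
        out.append(
            TranscriptAlignment(row.transcript_id, row.scaffold, row.strand, blocks,
                                float(row.identity), float(row.query_coverage),
                                str(row.sequence))
        )
    return out


def write_lncrnas(lncrnas: list[LncRNA], outdir: Path) -> None:
    write_fasta({l.id: l.sequence for l in lncrnas}, outdir / "lncrnas.fasta")
    with open(outdir / "lncrnas.bed", "w") as fh:
        for l in sorted(lncrnas, key=lambda l: (l.scaffold, l.span[0], l.id)):
            s, e = l.span
            sizes = ",".join(str(be - bs) for bs, be in l.blocks)
            starts = ",".join(str(bs - s) for bs, _ in l.blocks)
            fh.write(
                f"{l.scaffold}\t{s}\t{e}\t{l.id}\t0\t{l.strand}\t{s}\t{e}\t0\t"
                f"{len(l.blocks)}\t{sizes},\t{starts},\n"
            )
    meta = pd.DataFrame(
        [(l.id, l.scaffold, l.strand, l.span[0], l.span[1], l.spliced_length,
          l.intron_count, round(l.gc_fraction, 4), l.support_samples)
         for l in lncrnas],
        columns=["lncrna_id", "scaffold", "strand", "start", "end",
                 "spliced_length", "intron_count", "gc_fraction", "support_samples"],
    )
    meta.to_csv(outdir / "lncrnas.tsv", sep="\t", index=False)


def read_lncrnas(outdir: Path) -> list[LncRNA]:
    seqs = read_fasta(outdir / "lncrnas.fasta")
    meta = pd.read_csv(outdir / "lncrnas.tsv", sep="\t")
    bed: dict[str, tuple] = {}
    with open(outdir / "lncrnas.bed") as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            s = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            bed[f[3]] = tuple((s + st, s + st + sz) for st, sz in zip(starts, sizes))
    out = []
    for row in meta.itertuples(index=False):
        out.append(
            LncRNA(row.lncrna_id, row.scaffold, row.strand, bed[row.lncrna_id],
                   seqs[row.lncrna_id], int(row.support_samples),
                   int(row.intron_count), float(row.gc_fraction))
        )
    return out


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(outdir: Path, seed: int, sim_overrides: dict | None = None) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    overrides = dict(sim_overrides or {})
    if "triplex_plants" in overrides:
        overrides["triplex_plants"] = tuple(
            TriplexPlant(float(r), str(m)) for r, m in overrides["triplex_plants"]
        )
    if "biotype_mix" in overrides:
        overrides["biotype_mix"] = dict(overrides["biotype_mix"])
    bundle = simulate_truth_bundle(SimulationConfig(seed=seed, **overrides))
    bundle.genome.to_fasta(outdir / "genome.fasta")
    write_gff3(bundle.annotation, outdir / "annotation.gff3")
    write_alignments_tsv(bundle.alignments, outdir / "alignments.tsv")
    write_count_table(bundle.counts, outdir / "counts.tsv", outdir / "samples.tsv")
    bundle.de_truth.to_csv(outdir / "truth_de.tsv", sep="\t")
    bundle.module_truth.to_frame().to_csv(outdir / "truth_modules.tsv", sep="\t")
    bundle.triplex_truth.to_csv(outdir / "truth_triplex.tsv", sep="\t", index=False)
    bundle.biotype_truth().rename("biotype").to_frame().to_csv(
        outdir / "truth_biotypes.tsv", sep="\t"
    )


def _load_inputs(outdir: Path):
    genome = Genome.from_fasta(outdir / "genome.fasta")
    annotation = parse_annotation(outdir / "annotation.gff3", genome)
    counts = load_count_table(outdir / "counts.tsv", outdir / "samples.tsv")
    return genome, annotation, counts


def stage_identify(outdir: Path, params: dict) -> None:
    genome, annotation, counts = _load_inputs(outdir)
    alignments = read_alignments_tsv(outdir / "alignments.tsv")
    lncrnas, attrition = run_cascade(alignments, annotation, counts, **params)
    write_lncrnas(lncrnas, outdir)
    attrition.to_csv(outdir / "attrition.tsv", sep="\t", index=False)


def stage_biotype(outdir: Path, params: dict) -> None:
    genome, annotation, counts = _load_inputs(outdir)
    lncrnas = read_lncrnas(outdir)
    assignments = bt.classify_all(lncrnas, annotation, window=params["window"])
    pd.DataFrame(
        [(a.lncrna_id, a.gene_id or "", a.distance_bp, a.label, a.mixed_ends)
         for a in assignments],
        columns=["lncrna_id", "gene_id", "distance_bp", "label", "mixed_ends"],
    ).to_csv(outdir / "biotypes.tsv", sep="\t", index=False)
    bt.summarize_biotypes(assignments).to_csv(outdir / "biotype_summary.tsv", sep="\t")
    normalized, _ = de_mod.normalize_counts(counts)
    bt.pair_expression_correlation(assignments, normalized).to_csv(
        outdir / "pair_correlations.tsv", sep="\t", index=False
    )


def stage_kmer(outdir: Path, params: dict) -> None:
    lncrnas = read_lncrnas(outdir)
    kp = kmers.KmerParams(**params)
    profiles = kmers.kmer_profile({l.id: l.sequence for l in lncrnas}, kp)
    adjacency = kmers.profile_adjacency(profiles)
    clusters = kmers.cluster_profiles(adjacency, kp)
    clusters.rename("cluster").to_frame().to_csv(outdir / "kmer_clusters.tsv", sep="\t")


def stage_de(outdir: Path, params: dict) -> None:
    _, _, counts = _load_inputs(outdir)
    contrast = tuple(str(x) for x in params["contrast"])
    pre_norm, _ = de_mod.normalize_counts(counts)
    outliers = de_mod.flag_outlier_samples(
        pre_norm, counts.metadata, ["temperature", "phase"]
    )
    pd.Series(outliers, name="outlier_sample").to_csv(
        outdir / "outlier_samples.tsv", sep="\t", index=False
    )
    if outliers:
        keep = [s for s in counts.samples if s not in outliers]
        counts = CountMatrix(counts.counts[keep], counts.metadata.loc[keep])
    res = de_mod.test_differential_expression(
        counts, contrast,
        padj_threshold=params["padj_threshold"], lfc_threshold=params["lfc_threshold"],
    )
    res.to_csv(outdir / "de_results.tsv", sep="\t", index_label="feature_id")
    normalized, sf = de_mod.normalize_counts(counts)
    normalized.to_csv(outdir / "normalized.tsv", sep="\t", index_label="feature_id")
    sf.to_frame().to_csv(outdir / "size_factors.tsv", sep="\t", index_label="sample")


def stage_coexpress(outdir: Path, params: dict) -> None:
    _, _, counts = _load_inputs(outdir)
    normalized = pd.read_csv(outdir / "normalized.tsv", sep="\t", index_col=0)
    expressed = normalized[normalized.std(axis=1) > 0]
    if params.get("power"):
        net_params = network.NetworkParams(power=int(params["power"]))
    else:
        net_params = network.pick_soft_threshold(expressed)
    net_params.min_module_size = params["min_module_size"]
    net_params.merge_cor = params["merge_cor"]
    net_params.cut_height_quantile = params["cut_height_quantile"]
    _, tom = network.build_network(expressed, net_params)
    assignment = network.detect_modules(tom, net_params)
    trait_cols = [c for c in ("temperature", "phase") if c in counts.metadata.columns]
    eigengenes, merged, trait_cor = network.module_eigengenes(
        expressed, assignment, net_params,
        traits=counts.metadata[trait_cols] if trait_cols else None,
    )
    merged.rename("module").to_frame().to_csv(outdir / "modules.tsv", sep="\t")
    eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t", index_label="sample")
    if trait_cor is not None:
        trait_cor.to_csv(outdir / "module_trait.tsv", sep="\t", index=False)


def stage_triplex(outdir: Path, params: dict) -> None:
    genome, annotation, counts = _load_inputs(outdir)
    lncrnas = read_lncrnas(outdir)
    promoters = extract_promoters(annotation, genome)
    write_promoters_fasta(promoters, outdir / "promoters.fasta")
    tp = triplex.TriplexParams(
        min_len=params["min_len"], max_error_rate=params["max_error_rate"],
        repeat_filter=params["repeat_filter"], duplicate_cutoff=params["duplicate_cutoff"],
    )
    seqs = {l.id: l.sequence for l in lncrnas}
    hits = triplex.find_all_hits(seqs, promoters, tp)
    pd.DataFrame(
        [(h.lncrna_id, h.gene_id, h.tfo_offset, h.tts_offset, h.length,
          h.mismatches, h.motif, h.orientation, h.tts_strand) for h in hits],
        columns=["lncrna_id", "gene_id", "tfo_offset", "tts_offset", "length",
                 "mismatches", "motif", "orientation", "tts_strand"],
    ).to_csv(outdir / "triplex_hits.tsv", sep="\t", index=False)

    graph = triplex.InteractionGraph.from_hits(hits)
    de_results = pd.read_csv(outdir / "de_results.tsv", sep="\t", index_col=0)
    de_gene_ids = {
        g for g in de_results.index[de_results["status"] != "ns"]
        if g in annotation.genes
    }
    summary = triplex.interaction_summary(graph, len(annotation), de_gene_ids)
    summary.to_frame("value").to_csv(outdir / "interaction_summary.tsv", sep="\t")
    normalized = pd.read_csv(outdir / "normalized.tsv", sep="\t", index_col=0)
    correlated, corr_summary = triplex.correlate_interaction_expression(
        graph, de_results, normalized, rho_min=params["rho_min"], p_max=params["p_max"]
    )
    correlated.to_csv(outdir / "correlated_interactions.tsv", sep="\t", index=False)
    corr_summary.to_frame("value").to_csv(outdir / "correlation_summary.tsv", sep="\t")
    groups = triplex.group_target_genes(correlated)
    groups.to_csv(outdir / "target_gene_groups.tsv", sep="\t", index=False)


def stage_report(outdir: Path) -> None:
    genome, annotation, _ = _load_inputs(outdir)
    lncrnas = read_lncrnas(outdir)
    sections: dict[str, object] = {}
    if lncrnas:
        from .identify import summarize_features

        sections["feature_summary"] = summarize_features(
            lncrnas, annotation, genome
        ).to_frame()
    for name, fname in [
        ("biotype_summary", "biotype_summary.tsv"),
        ("attrition", "attrition.tsv"),
        ("interaction_summary", "interaction_summary.tsv"),
        ("correlation_summary", "correlation_summary.tsv"),
    ]:
        path = outdir / fname
        if path.exists():
            sections[name] = pd.read_csv(path, sep="\t")
        else:
            sections[name] = f"[missing artifact: {fname}]"
    de_path = outdir / "de_results.tsv"
    if de_path.exists():
        de_results = pd.read_csv(de_path, sep="\t", index_col=0)
        classes = pd.Series(
            ["gene" if f in annotation.genes else "lncRNA" for f in de_results.index],
            index=de_results.index,
        )
        sections["de_counts"] = report.de_count_table(de_results, classes)
    mod_path = outdir / "modules.tsv"
    if mod_path.exists():
        modules = pd.read_csv(mod_path, sep="\t", index_col=0)["module"]
        trait_path = outdir / "module_trait.tsv"
        trait = pd.read_csv(trait_path, sep="\t") if trait_path.exists() else None
        classes = pd.Series(
            ["gene" if f in annotation.genes else "lncRNA" for f in modules.index],
            index=modules.index,
        )
        km_path = outdir / "kmer_clusters.tsv"
        km = (pd.read_csv(km_path, sep="\t", index_col=0)["cluster"]
              if km_path.exists() else None)
        sections["module_table"] = report.module_table(modules, trait, classes, km)
    with open(outdir / "report.txt", "w") as fh:
        for name, obj in sections.items():
            fh.write(f"## {name}\n")
            fh.write(obj.to_string() if hasattr(obj, "to_string") else str(obj))
            fh.write("\n\n")


STAGES = ("identify", "biotype", "kmer", "de", "coexpress", "triplex", "report")


def run_pipeline(outdir: Path, config: dict) -> None:
    """Run identify -> biotype -> kmer -> de -> coexpress -> triplex -> report."""
    for inp in ("genome.fasta", "annotation.gff3", "alignments.tsv",
                "counts.tsv", "samples.tsv"):
        if not (outdir / inp).exists():
            raise FileNotFoundError(f"missing pipeline input: {outdir / inp}")
    stage_identify(outdir, config["identify"])
    stage_biotype(outdir, config["biotype"])
    stage_kmer(outdir, config["kmer"])
    stage_de(outdir, config["de"])
    stage_coexpress(outdir, config["coexpression"])
    stage_triplex(outdir, config["triplex"])
    stage_report(outdir)
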