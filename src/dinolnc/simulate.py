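"""Synthetic genome / transcriptome generator with planted ground truth.

Emulates the salient features of dinoflagellate genome data: multi-scaffold
genomes with strand-biased unidirectional gene blocks, intron-rich genes
against intron-poor and G+C-poorer lncRNA loci, negative-binomial counts
with planted fold-changes and co-expression modules, and promoters carrying
planted purine-rich triplex target sites.  Every planted structure is
recorded as truth so each pipeline stage can be scored exactly.

Guarantees by construction (enforced, not merely sampled):

- planted lncRNA loci never overlap gene exons, and their transcripts are
  classified non-coding by the intrinsic consensus scorer;
- planted biotype geometries avoid the ambiguous mixed-ends configurations
  unless explicitly requested;
- expression support is clamped so planted lncRNAs meet, and low-support
  decoys miss, the >= 10 samples x >= 10 reads rule;
- planted TFO/TTS pairs survive low-complexity masking, and their mismatch
  positions are spaced so a 10% error plant exceeds the 5% budget in every
  window of minimum triplex length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import gc_fraction, revcomp
from .coding import score_coding_potential
from .genome_io import Annotation, CountMatrix, GeneModel, Genome
from .identify import TranscriptAlignment
from .triplex import mask_low_complexity

BIOTYPES = (
    "sense_genic",
    "antisense_genic",
    "sense_intergenic",
    "antisense_intergenic_divergent",
    "antisense_intergenic_convergent",
    "distant",
)

_PLANT_TFO_MAP = {
    # tract (purine strand) base -> TFO base, and whether the TFO string is
    # written reversed into the lncRNA (antiparallel orientation)
    "pyrimidine": ({"A": "T", "G": "C"}, False),
    "purine": ({"A": "A", "G": "G"}, True),
    "mixed": ({"A": "T", "G": "G"}, False),
}
_PLANT_MISMATCH_CHAR = {"pyrimidine": "A", "purine": "C", "mixed": "C"}


@dataclass(frozen=True)
class TriplexPlant:
    mismatch_rate: float = 0.0
    motif: str = "pyrimidine"


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome layout
    n_scaffolds: int = 3
    scaffold_length: int | None = None  # None: sized to content
    n_genes: int = 80
    gene_intron_rate: float = 4.0
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (350, 800)
    intergenic_gap: tuple[int, int] = (1500, 4000)
    strand_flip_prob: float = 0.2  # unidirectional blocks of ~5 genes
    gc_gene: float = 0.55
    gc_lncrna: float = 0.49
    gc_intergenic: float = 0.45
    # lncRNA plants
    lncrna_length: tuple[int, int] = (300, 700)
    lncrna_intron_prob: float = 0.25
    lncrna_intron_length: tuple[int, int] = (200, 400)
    biotype_mix: dict[str, int] = field(
        default_factory=lambda: {
            "sense_genic": 6,
            "antisense_genic": 4,
            "sense_intergenic": 8,
            "antisense_intergenic_divergent": 4,
            "antisense_intergenic_convergent": 4,
            "distant": 8,
        }
    )
    allow_mixed_ends: bool = False
    # cascade decoys
    n_coding_decoys: int = 5
    n_exonic_decoys: int = 5
    n_lowquality_decoys: int = 5
    n_redundant_decoys: int = 5
    n_lowsupport_decoys: int = 5
    # expression design
    temperatures: tuple[int, int] = (20, 30)
    phases: tuple[str, ...] = ("exponential", "stationary")
    replicates: int = 3
    count_mean_log: float = 4.5  # natural-log scale of log-normal baselines
    count_mean_sd: float = 1.0
    dispersion: float = 0.1
    n_de_genes: int = 10
    de_log2fc: float = 3.0
    n_phase_de: int = 30
    phase_log2fc: float = 2.0
    module_sizes: tuple[int, ...] = (35, 35)
    module_loading: float = 1.0
    module_trait_strength: float = 0.9  # module 1 eigengene tracks temperature
    support_min_samples: int = 10
    support_min_reads: int = 10
    # triplex plants
    triplex_plants: tuple[TriplexPlant, ...] = tuple(
        TriplexPlant(0.0, m) for m in ("pyrimidine", "purine", "mixed")
    ) * 2
    tract_length: int = 30
    couple_targets_to_de: bool = True
    coupling_sd: float = 0.7
    coupling_base_boost: float = 2.5  # ln-scale mean bump for coupled pairs

    def __post_init__(self) -> None:
        if sum(self.biotype_mix.values()) < 1:
            raise ValueError("biotype_mix must plant at least one lncRNA")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


# ---------------------------------------------------------------------------
# Truth containers


@dataclass
class LncLocus:
    lnc_id: str
    scaffold: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    transcript: str  # strand-oriented spliced sequence
    biotype: str
    host_gene: str | None
    role: str  # lncrna | coding_decoy | exonic_decoy | lowquality_decoy |
    #            redundant_decoy | lowsupport_decoy

    @property
    def span(self) -> tuple[int, int]:
        return (self.blocks[0][0], self.blocks[-1][1])


@dataclass
class TruthBundle:
    config: SimulationConfig
    genome: Genome
    annotation: Annotation
    loci: dict[str, LncLocus]
    alignments: list[TranscriptAlignment]
    counts: CountMatrix
    de_truth: pd.DataFrame  # feature_id, true_log2fc
    module_truth: pd.Series  # feature_id -> module label (0 = none)
    triplex_truth: pd.DataFrame

    @property
    def planted_lncrna_ids(self) -> list[str]:
        return sorted(l.lnc_id for l in self.loci.values() if l.role == "lncrna")

    def biotype_truth(self) -> pd.Series:
        return pd.Series(
            {l.lnc_id: l.biotype for l in self.loci.values() if l.role == "lncrna"}
        )

    def lncrna_sequences(self) -> dict[str, str]:
        return {i: self.loci[i].transcript for i in self.planted_lncrna_ids}


# ---------------------------------------------------------------------------
# Sequence helpers


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _orf_spans(seq: str) -> list[tuple[int, int]]:
    stops = {"TAA", "TAG", "TGA"}
    spans = []
    n = len(seq)
    for frame in range(3):
        open_from = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if open_from is None:
                if codon == "ATG":
                    open_from = i
            elif codon in stops:
                spans.append((open_from, i + 3))
                open_from = None
        if open_from is not None:
            spans.append((open_from, frame + ((n - frame) // 3) * 3))
    return spans


def _make_noncoding(seq: str, rng: np.random.Generator, max_iter: int = 50) -> str:
    """Disrupt ORFs until the intrinsic consensus scorer calls non-coding.

    Stop-codon insertion into the longest ORF can occasionally unmask an
    ORF in another frame; after ``max_iter`` disruptions the sequence is
    redrawn from the same base composition and the loop restarts.
    """
    gc = gc_fraction(seq)
    for _restart in range(20):
        s = list(seq)
        for _ in range(max_iter):
            cp = score_coding_potential("".join(s))
            if cp.is_noncoding:
                return "".join(s)
            spans = _orf_spans("".join(s))
            if spans:
                start, end = max(spans, key=lambda x: x[1] - x[0])
                mid = start + 3 * (((end - start) // 3) // 2)
                s[mid : mid + 3] = "TAA"
            else:  # Fickett-driven call: reshuffle the composition bias away
                perm = rng.permutation(len(s))
                s = [s[i] for i in perm]
        seq = _random_seq(rng, len(seq), gc)
    raise RuntimeError("could not render sequence non-coding")


def _coding_sequence(rng: np.random.Generator, n: int, gc: float) -> str:
    """A transcript dominated by one long uninterrupted ORF."""
    stops = {"TAA", "TAG", "TGA"}
    n_codons = max((n - 6) // 3, 10)
    codons = []
    while len(codons) < n_codons:
        c = _random_seq(rng, 3, gc)
        if c not in stops:
            codons.append(c)
    seq = "ATG" + "".join(codons) + "TAA"
    if len(seq) < n:
        seq += _random_seq(rng, n - len(seq), gc)
    return seq[: max(n, len(seq))] if len(seq) <= n else seq


# ---------------------------------------------------------------------------
# Genome + annotation + lncRNA loci


class _ScaffoldPlan:
    def __init__(self) -> None:
        self.cursor = 0
        self.genes: list[GeneModel] = []
        self.loci: list[LncLocus] = []
        self.writes: list[tuple[int, str]] = []  # (position, sequence)

    def advance(self, n: int) -> int:
        pos = self.cursor
        self.cursor += n
        return pos


def _plan_gene(
    plan: _ScaffoldPlan,
    scaffold: str,
    gene_id: str,
    strand: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    big_intron: int | None = None,
) -> GeneModel:
    n_exons = 1 + int(rng.poisson(cfg.gene_intron_rate))
    n_exons = max(n_exons, 2 if big_intron else 1)
    exons = []
    pos = plan.cursor
    big_at = int(rng.integers(0, n_exons - 1)) if big_intron else -1
    for i in range(n_exons):
        xlen = int(rng.integers(*cfg.exon_length))
        exons.append((pos, pos + xlen))
        plan.writes.append((pos, _random_seq(rng, xlen, cfg.gc_gene)))
        pos += xlen
        if i < n_exons - 1:
            ilen = big_intron if i == big_at else int(rng.integers(*cfg.intron_length))
            pos += ilen
    plan.cursor = pos
    gene = GeneModel(gene_id, scaffold, strand, tuple(exons), tuple(exons))
    plan.genes.append(gene)
    return gene


def _lnc_blocks(
    start: int, cfg: SimulationConfig, rng: np.random.Generator, length: int,
    allow_intron: bool = True,
) -> tuple[tuple[tuple[int, int], ...], int]:
    """Block structure for a lncRNA of spliced `length` starting at `start`."""
    if allow_intron and rng.random() < cfg.lncrna_intron_prob:
        x1 = length // 2
        ilen = int(rng.integers(*cfg.lncrna_intron_length))
        blocks = ((start, start + x1), (start + x1 + ilen, start + length + ilen))
        return blocks, length + ilen
    return ((start, start + length),), length


def _place_lnc(
    plan: _ScaffoldPlan,
    scaffold: str,
    lnc_id: str,
    strand: str,
    biotype: str,
    host: str | None,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    role: str = "lncrna",
    start: int | None = None,
    allow_intron: bool = True,
) -> LncLocus:
    length = int(rng.integers(*cfg.lncrna_length))
    transcript = _make_noncoding(_random_seq(rng, length, cfg.gc_lncrna), rng)
    pos = plan.cursor if start is None else start
    blocks, genomic_len = _lnc_blocks(pos, cfg, rng, len(transcript), allow_intron)
    if start is None:
        plan.cursor += genomic_len
    locus = LncLocus(lnc_id, scaffold, strand, blocks, transcript, biotype, host, role)
    plan.loci.append(locus)
    _write_locus(plan, locus)
    return locus


def _write_locus(plan: _ScaffoldPlan, locus: LncLocus) -> None:
    genomic = locus.transcript if locus.strand == "+" else revcomp(locus.transcript)
    offset = 0
    for (s, e) in locus.blocks:
        plan.writes.append((s, genomic[offset : offset + (e - s)]))
        offset += e - s


def simulate_genome_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[Genome, Annotation, dict[str, LncLocus]]:
    """Genome + annotation with planted lncRNA loci of each requested biotype."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cfg = config

    # assign biotype plants and decoy loci round-robin over host genes
    plants: list[str] = []
    for label in BIOTYPES:
        plants.extend([label] * cfg.biotype_mix.get(label, 0))
    genic = [b for b in plants if b.endswith("genic") and "intergenic" not in b]
    intergenic = [b for b in plants if b not in genic and b != "distant"]
    n_distant = plants.count("distant")

    genes_per_scaffold = [
        cfg.n_genes // cfg.n_scaffolds + (1 if i < cfg.n_genes % cfg.n_scaffolds else 0)
        for i in range(cfg.n_scaffolds)
    ]
    plans: dict[str, _ScaffoldPlan] = {}
    gene_counter = 0
    lnc_counter = 0
    genic_iter = iter(genic)
    intergenic_iter = iter(intergenic)
    distant_left = n_distant
    own_locus_decoys = (
        ["coding_decoy"] * cfg.n_coding_decoys
        + ["lowquality_decoy"] * cfg.n_lowquality_decoys
        + ["lowsupport_decoy"] * cfg.n_lowsupport_decoys
    )
    decoy_iter = iter(own_locus_decoys)

    for si in range(cfg.n_scaffolds):
        scaffold = f"scaffold_{si + 1}"
        plan = _ScaffoldPlan()
        plans[scaffold] = plan
        plan.advance(int(rng.integers(1200, 2000)))
        strand = "+" if rng.random() < 0.5 else "-"
        for gi in range(genes_per_scaffold[si]):
            if rng.random() < cfg.strand_flip_prob:
                strand = "+" if strand == "-" else "-"
            gene_counter += 1
            gene_id = f"gene_{gene_counter:04d}"

            genic_label = next(genic_iter, None)
            big_intron = None
            if genic_label is not None:
                big_intron = cfg.lncrna_length[1] + cfg.lncrna_intron_length[1] + 200

            inter_label = next(intergenic_iter, None)
            left_attach = None
            if inter_label == "antisense_intergenic_divergent":
                left_attach = ("-", inter_label) if strand == "+" else None
            elif inter_label == "antisense_intergenic_convergent":
                left_attach = ("+", inter_label) if strand == "-" else None
            # attachments that go on the right-hand side of the gene
            right_attach = None
            if inter_label == "sense_intergenic":
                right_attach = (strand, inter_label)
            elif inter_label == "antisense_intergenic_divergent" and strand == "-":
                right_attach = ("+", inter_label)
            elif inter_label == "antisense_intergenic_convergent" and strand == "+":
                right_attach = ("-", inter_label)

            if left_attach is not None:
                # clear the previous gene by > 5 kb so the host stays nearest
                plan.advance(int(rng.integers(5600, 7000)))
                lnc_counter += 1
                lstrand, label = left_attach
                _place_lnc(plan, scaffold, f"lnc_{lnc_counter:04d}", lstrand, label,
                           gene_id, cfg, rng)
                plan.advance(int(rng.integers(1100, 1600)))  # gap, room for promoter
            gene = _plan_gene(plan, scaffold, gene_id, strand, cfg, rng, big_intron)

            if genic_label is not None:
                # biggest intron hosts the genic lncRNA
                introns = [
                    (e1, s2) for (_, e1), (s2, _) in zip(gene.exons, gene.exons[1:])
                ]
                s, e = max(introns, key=lambda iv: iv[1] - iv[0])
                lnc_counter += 1
                lstrand = strand if genic_label == "sense_genic" else (
                    "+" if strand == "-" else "-"
                )
                _place_lnc(
                    plan, scaffold, f"lnc_{lnc_counter:04d}", lstrand, genic_label,
                    gene_id, cfg, rng, start=s + 50, allow_intron=False,
                )

            if right_attach is not None:
                plan.advance(int(rng.integers(1100, 1600)))
                lnc_counter += 1
                lstrand, label = right_attach
                _place_lnc(plan, scaffold, f"lnc_{lnc_counter:04d}", lstrand, label,
                           gene_id, cfg, rng)
                plan.advance(int(rng.integers(5600, 7000)))
            else:
                plan.advance(int(rng.integers(*cfg.intergenic_gap)))

        # distant lncRNAs and own-locus decoys at the scaffold tail, > 5 kb from genes
        share = distant_left // (cfg.n_scaffolds - si) if cfg.n_scaffolds > si else 0
        for _ in range(share):
            plan.advance(int(rng.integers(5600, 7000)))
            lnc_counter += 1
            lstrand = "+" if rng.random() < 0.5 else "-"
            _place_lnc(plan, scaffold, f"lnc_{lnc_counter:04d}", lstrand, "distant",
                       None, cfg, rng)
            distant_left -= 1
        while True:
            role = next(decoy_iter, None) if si == cfg.n_scaffolds - 1 or rng.random() < 0.4 else None
            if role is None:
                break
            plan.advance(int(rng.integers(5600, 7000)))
            lnc_counter += 1
            did = f"{role.split('_')[0]}_{lnc_counter:04d}"
            if role == "coding_decoy":
                length = int(rng.integers(*cfg.lncrna_length))
                transcript = _coding_sequence(rng, length, cfg.gc_gene)
                pos = plan.advance(len(transcript))
                locus = LncLocus(did, scaffold, "+", ((pos, pos + len(transcript)),),
                                 transcript, "none", None, role)
                plan.loci.append(locus)
                _write_locus(plan, locus)
            else:
                _place_lnc(plan, scaffold, did, "+", "none", None, cfg, rng, role=role)
        plan.advance(int(rng.integers(5600, 7000)))

    # redundant decoys: shorter same-strand candidates inside planted spans
    # (hosts taken from the tail of the list; triplex plants draw from the
    # head, so the copied sub-sequences stay untouched)
    planted = [l for p in plans.values() for l in p.loci if l.role == "lncrna"]
    singles = [l for l in planted if len(l.blocks) == 1]
    for i in range(cfg.n_redundant_decoys):
        host = singles[len(singles) - 1 - (i % len(singles))]
        s, e = host.span
        sub_len = max((e - s) // 2, 210)
        # choose a sub-window whose transcript is itself non-coding, so the
        # decoy survives every stage until the redundancy collapse
        offsets = [20 + 10 * j for j in range(max((e - s - sub_len - 20) // 10, 1))]
        sub_off = offsets[0]
        for off in offsets:
            if host.strand == "+":
                sub_seq = host.transcript[off : off + sub_len]
            else:
                rel = (e - s) - (off + sub_len)
                sub_seq = host.transcript[rel : rel + sub_len]
            if score_coding_potential(sub_seq).is_noncoding:
                sub_off = off
                break
        sub_start = s + sub_off
        plan = plans[host.scaffold]
        lnc_counter += 1
        locus = LncLocus(
            f"redundant_{lnc_counter:04d}", host.scaffold, host.strand,
            ((sub_start, sub_start + sub_len),), "", host.biotype, host.host_gene,
            "redundant_decoy",
        )
        plan.loci.append(locus)

    # assemble sequences
    records: dict[str, str] = {}
    for scaffold, plan in plans.items():
        total = plan.cursor + int(rng.integers(500, 1000))
        if cfg.scaffold_length is not None:
            if total > cfg.scaffold_length:
                raise ValueError(
                    f"{scaffold}: content ({total} bp) exceeds scaffold_length"
                )
            total = cfg.scaffold_length
        arr = np.array(list(_random_seq(rng, total, cfg.gc_intergenic)))
        for pos, seq in plan.writes:
            arr[pos : pos + len(seq)] = list(seq)
        records[scaffold] = "".join(arr)

    # fill redundant-decoy transcripts from the assembled genome
    loci: dict[str, LncLocus] = {}
    for scaffold, plan in plans.items():
        for locus in plan.loci:
            if locus.role == "redundant_decoy":
                s, e = locus.span
                seq = records[scaffold][s:e]
                locus.transcript = seq if locus.strand == "+" else revcomp(seq)
            loci[locus.lnc_id] = locus

    genome = Genome(records)
    annotation = Annotation(g for p in plans.values() for g in p.genes)
    return genome, annotation, loci


# ---------------------------------------------------------------------------
# Counts


def sample_metadata(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for t in config.temperatures:
        for ph in config.phases:
            for r in range(1, config.replicates + 1):
                rows.append((f"T{t}_{ph[:4]}_r{r}", t, ph, r))
    return pd.DataFrame(
        rows, columns=["sample", "temperature", "phase", "replicate"]
    ).set_index("sample")


def simulate_counts(
    config: SimulationConfig,
    features: list[str],
    rng: np.random.Generator | None = None,
    de_features: dict[str, float] | None = None,
    phase_de_features: dict[str, float] | None = None,
    module_features: dict[str, int] | None = None,
    coupling: dict[str, tuple[int, float]] | None = None,
    supported: set[str] | None = None,
    unsupported: set[str] | None = None,
) -> tuple[CountMatrix, pd.DataFrame, pd.Series]:
    """NB counts with planted fold-changes, modules and coupled pairs.

    ``de_features`` maps feature -> true log2 fold-change applied to the
    warm-temperature samples; ``module_features`` maps feature -> module
    label sharing a latent per-sample factor (loading ``module_loading``);
    ``coupling`` maps feature -> (pair id, sign) for anti-/co-regulated
    pairs sharing a per-sample factor of sd ``coupling_sd``.  Support
    clamping guarantees the >= min_reads in >= / < min_samples contract for
    the listed feature sets.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    cfg = config
    meta = sample_metadata(cfg)
    n_samples = len(meta)
    hot = (meta["temperature"] == max(cfg.temperatures)).to_numpy()

    de_features = de_features or {}
    phase_de_features = phase_de_features or {}
    module_features = module_features or {}
    coupling = coupling or {}
    supported = supported or set()
    unsupported = unsupported or set()

    stationary = (meta["phase"] == "stationary").to_numpy() if "phase" in meta else np.zeros(n_samples, bool)

    # the first two modules track temperature in opposite directions (heat
    # up- and down-regulated programmes), keeping library sizes balanced;
    # further modules follow condition-independent latents
    modules = sorted(set(module_features.values()))
    z_mod = {}
    for mi, m in enumerate(modules):
        noise = rng.normal(0, 1, n_samples)
        s = cfg.module_trait_strength
        if mi < 2 and s > 0:
            sign = 1.0 if mi == 0 else -1.0
            z_mod[m] = sign * (hot * 2.0 - 1.0) * s + noise * np.sqrt(max(1 - s**2, 0.05))
        else:
            z_mod[m] = noise
    # coupled pairs share one latent carrying the full heat-stress response:
    # the target gene follows +z, its regulator lncRNA -z, so the pair is
    # strongly anti-correlated both between and within temperature groups
    pair_ids = sorted({p for (p, _) in coupling.values()})
    z_pair = {
        p: hot * cfg.de_log2fc * np.log(2) + rng.normal(0, cfg.coupling_sd, n_samples)
        for p in pair_ids
    }

    base = rng.normal(cfg.count_mean_log, cfg.count_mean_sd, len(features))
    for i, fid in enumerate(features):
        if fid in coupling:  # coupled regulator/target pairs are well expressed
            base[i] = max(base[i], cfg.count_mean_log) + cfg.coupling_base_boost
    counts = np.zeros((len(features), n_samples), dtype=int)
    log2 = np.log(2.0)
    for i, fid in enumerate(features):
        log_mu = np.full(n_samples, base[i])
        if fid in de_features:
            log_mu = log_mu + de_features[fid] * log2 * hot
        if fid in phase_de_features:
            log_mu = log_mu + phase_de_features[fid] * log2 * stationary
        if fid in module_features:
            log_mu = log_mu + cfg.module_loading * z_mod[module_features[fid]]
        if fid in coupling:
            p, sign = coupling[fid]
            log_mu = log_mu + sign * z_pair[p]
        mu = np.exp(log_mu)
        r = 1.0 / cfg.dispersion
        p_nb = r / (r + mu)
        counts[i] = rng.negative_binomial(r, p_nb)

    df = pd.DataFrame(counts, index=features, columns=meta.index)
    for fid in supported:
        row = df.loc[fid].to_numpy()
        lacking = cfg.support_min_samples - int((row >= cfg.support_min_reads).sum())
        if lacking > 0:
            weak = np.argsort(row)[::-1]
            for j in weak:
                if row[j] < cfg.support_min_reads:
                    row[j] = cfg.support_min_reads
                    lacking -= 1
                    if lacking == 0:
                        break
            df.loc[fid] = row
    for fid in unsupported:
        row = df.loc[fid].to_numpy()
        allowed = cfg.support_min_samples - 2
        strong = np.flatnonzero(row >= cfg.support_min_reads)
        for j in strong[allowed:]:
            row[j] = cfg.support_min_reads - 1
        df.loc[fid] = row

    cm = CountMatrix(df, meta)
    de_truth = pd.DataFrame(
        {"feature_id": list(features),
         "true_log2fc": [de_features.get(f, 0.0) for f in features]}
    ).set_index("feature_id")
    module_truth = pd.Series(
        [module_features.get(f, 0) for f in features], index=features, name="module"
    )
    return cm, de_truth, module_truth


# ---------------------------------------------------------------------------
# Triplex plants


def _random_purine_tract(rng: np.random.Generator, length: int) -> str:
    for _ in range(200):
        tract = "".join(rng.choice(["A", "G"], size=length, p=[0.55, 0.45]))
        if "N" in mask_low_complexity(tract):
            continue
        if tract.count("G") / length < 0.15:
            continue
        return tract
    raise RuntimeError("could not draw an unmaskable purine tract")


def _mismatch_positions(length: int, rate: float) -> list[int]:
    nm = int(rate * length)
    return [int((i + 0.5) * length / nm) for i in range(nm)] if nm else []


def plant_triplex_pairs(
    config: SimulationConfig,
    genome: Genome,
    annotation: Annotation,
    loci: dict[str, LncLocus],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Write purine tracts into promoters and Hoogsteen TFOs into lncRNAs.

    Mutates ``genome.records`` and the lncRNA transcripts in ``loci`` in
    place; returns the truth table (lncRNA, gene, motif, rate, offsets).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    cfg = config
    L = cfg.tract_length

    occupied: dict[str, list[tuple[int, int]]] = {}
    for g in annotation:
        for iv in g.exons:
            occupied.setdefault(g.scaffold, []).append(iv)
    for l in loci.values():
        occupied.setdefault(l.scaffold, []).append(l.span)

    def free(scaffold: str, s: int, e: int) -> bool:
        return all(not (s < e2 and s2 < e) for s2, e2 in occupied.get(scaffold, []))

    # candidate target genes: full 1 kb promoter entirely in background sequence
    targets = []
    for g in sorted(annotation, key=lambda g: g.gene_id):
        if g.strand == "+":
            ps, pe = g.cds[0][0] - 1000, g.cds[0][0]
        else:
            ps, pe = g.cds[-1][1], g.cds[-1][1] + 1000
        if ps < 0 or pe > len(genome[g.scaffold]):
            continue
        if free(g.scaffold, ps, pe):
            targets.append((g, ps, pe))
    hosts = [l for l in loci.values()
             if l.role == "lncrna" and len(l.blocks) == 1
             and len(l.transcript) >= L + 20]
    if not targets or not hosts:
        raise ValueError("no eligible promoters or host lncRNAs for triplex plants")

    rows = []
    records = dict(genome.records)
    for pi, plant in enumerate(cfg.triplex_plants):
        gene, ps, pe = targets[pi % len(targets)]
        host = hosts[pi % len(hosts)]
        t_off = int(rng.integers(5, len(host.transcript) - L - 5))
        for _attempt in range(50):
            tract = _random_purine_tract(rng, L)
            tfo_map, antiparallel = _PLANT_TFO_MAP[plant.motif]
            tfo = "".join(tfo_map[b] for b in tract)
            if antiparallel:
                tfo = tfo[::-1]
            for pos in _mismatch_positions(L, plant.mismatch_rate):
                tfo = tfo[:pos] + _PLANT_MISMATCH_CHAR[plant.motif] + tfo[pos + 1 :]
            trial = host.transcript[:t_off] + tfo + host.transcript[t_off + L :]
            # the TFO must survive repeat masking and must not join ORF
            # fragments into a coding-looking transcript
            if ("N" not in mask_low_complexity(trial)[t_off : t_off + L]
                    and score_coding_potential(trial).is_noncoding):
                break
            t_off = int(rng.integers(5, len(host.transcript) - L - 5))
        else:
            raise RuntimeError("could not place an unmaskable TFO")

        # promoter-oriented offset, >= 2 nt of pyrimidine flank inside promoter
        p_off = int(rng.integers(2, 1000 - L - 2))
        flanked = "CT" + tract + "CT"
        if gene.strand == "+":
            gpos = ps + p_off - 2
            records[gene.scaffold] = (
                records[gene.scaffold][:gpos]
                + flanked
                + records[gene.scaffold][gpos + len(flanked) :]
            )
        else:
            gpos = pe - (p_off + L + 2)
            rc = revcomp(flanked)
            records[gene.scaffold] = (
                records[gene.scaffold][:gpos]
                + rc
                + records[gene.scaffold][gpos + len(rc) :]
            )

        host.transcript = trial
        rows.append(
            (host.lnc_id, gene.gene_id, plant.motif, plant.mismatch_rate,
             t_off, p_off, L)
        )

    genome.records = records
    # re-write mutated lncRNA loci into the genome
    for l in loci.values():
        if l.role != "lncrna":
            continue
        genomic = l.transcript if l.strand == "+" else revcomp(l.transcript)
        arr = list(genome.records[l.scaffold])
        off = 0
        for (s, e) in l.blocks:
            arr[s:e] = list(genomic[off : off + (e - s)])
            off += e - s
        genome.records[l.scaffold] = "".join(arr)
    # redundant decoys copy their host sequence, refresh them
    for l in loci.values():
        if l.role == "redundant_decoy":
            s, e = l.span
            seq = genome.records[l.scaffold][s:e]
            l.transcript = seq if l.strand == "+" else revcomp(seq)
    return pd.DataFrame(
        rows,
        columns=["lncrna_id", "gene_id", "motif", "mismatch_rate",
                 "tfo_offset", "tts_offset", "length"],
    )


# ---------------------------------------------------------------------------
# Alignments and the full bundle


def simulate_alignments(
    loci: dict[str, LncLocus], rng: np.random.Generator
) -> list[TranscriptAlignment]:
    out = []
    for l in sorted(loci.values(), key=lambda l: l.lnc_id):
        if l.role == "lowquality_decoy":
            identity = 0.90
            coverage = float(rng.uniform(0.76, 0.95))
        else:
            identity = float(rng.uniform(0.96, 1.0))
            coverage = float(rng.uniform(0.80, 0.99))
        out.append(
            TranscriptAlignment(
                l.lnc_id, l.scaffold, l.strand, l.blocks, identity, coverage,
                l.transcript,
            )
        )
    return out


def simulate_exonic_decoys(
    annotation: Annotation, genome: Genome, n: int, rng: np.random.Generator
) -> list[TranscriptAlignment]:
    genes = sorted(annotation, key=lambda g: g.gene_id)
    out = []
    for i in range(n):
        g = genes[int(rng.integers(0, len(genes)))]
        xs, xe = g.exons[0]
        s = max(g.span[0], xs - 50)
        e = min(g.span[1], xe + 50)
        seq = genome.slice(g.scaffold, s, e, g.strand)
        out.append(
            TranscriptAlignment(
                f"exonic_{i + 1:04d}", g.scaffold, g.strand, ((s, e),),
                float(rng.uniform(0.96, 1.0)), float(rng.uniform(0.80, 0.99)), seq,
            )
        )
    return out


def simulate_truth_bundle(config: SimulationConfig) -> TruthBundle:
    """Generate the full synthetic study: genome, plants, counts, alignments."""
    rng = np.random.default_rng(config.seed)
    genome, annotation, loci = simulate_genome_annotation(config, rng)
    triplex_truth = plant_triplex_pairs(config, genome, annotation, loci, rng)

    alignments = simulate_alignments(loci, rng)
    alignments += simulate_exonic_decoys(annotation, genome, config.n_exonic_decoys, rng)

    gene_ids = sorted(g.gene_id for g in annotation)
    transcript_ids = sorted(loci)
    features = gene_ids + transcript_ids

    planted = {l.lnc_id for l in loci.values() if l.role in ("lncrna", "redundant_decoy")}
    low_support = {l.lnc_id for l in loci.values() if l.role == "lowsupport_decoy"}

    de_features: dict[str, float] = {}
    coupling: dict[str, tuple[int, float]] = {}
    de_gene_pool = [g for g in gene_ids if g not in set(triplex_truth["gene_id"])]
    for g in de_gene_pool[: config.n_de_genes]:
        de_features[g] = config.de_log2fc * (1 if rng.random() < 0.5 else -1)
    if config.couple_targets_to_de:
        for pid, row in enumerate(triplex_truth.itertuples()):
            coupling[row.gene_id] = (pid, +1.0)
            coupling[row.lncrna_id] = (pid, -1.0)

    phase_pool = [f for f in features if f not in de_features and f not in coupling]
    # alternating signs keep growth-phase effects library-size balanced
    phase_de_features = {
        f: config.phase_log2fc * (1 if i % 2 == 0 else -1)
        for i, f in enumerate(phase_pool[-config.n_phase_de:])
    } if config.n_phase_de else {}

    module_features: dict[str, int] = {}
    pool = [f for f in features
            if f not in de_features and f not in coupling and f not in phase_de_features]
    # modules mix genes and lncRNAs, mirroring co-expression of both classes
    gene_pool = [f for f in pool if f.startswith("gene")]
    lnc_pool = [f for f in pool if f.startswith("lnc")]
    gi = li = 0
    for m, size in enumerate(config.module_sizes, start=1):
        n_lnc = max(size // 5, 1)
        for _ in range(size - n_lnc):
            if gi < len(gene_pool):
                module_features[gene_pool[gi]] = m
                gi += 1
        for _ in range(n_lnc):
            if li < len(lnc_pool):
                module_features[lnc_pool[li]] = m
                li += 1

    counts, de_truth, module_truth = simulate_counts(
        config, features, rng,
        de_features=de_features,
        phase_de_features=phase_de_features,
        module_features=module_features,
        coupling=coupling,
        supported=planted,
        unsupported=low_support,
    )
    # the coupling latent carries the heat-stress fold-change for the
    # planted target pairs; record it in the DE truth
    for fid, (_, sign) in coupling.items():
        de_truth.loc[fid, "true_log2fc"] = sign * config.de_log2fc
    return TruthBundle(
        config=config, genome=genome, annotation=annotation, loci=loci,
        alignments=alignments, counts=counts, de_truth=de_truth,
        module_truth=module_truth, triplex_truth=triplex_truth,
    )
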