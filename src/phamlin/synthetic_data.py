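"""Synthetic mosaic phage pangenomes with planted ground truth.

The generator emulates the statistical structure a phage comparative
analysis assumes: K genome clusters, each derived from an ancestral gene
cassette with a cluster-specific G+C content; a core pham set carried by
every member; accessory phams carried by subsets of members; per-genome
orphams with no relatives anywhere; a tunable rate of pham sharing between
clusters; and unrelated singleton genomes. Within a cluster, members
diverge from the ancestor by i.i.d. per-site nucleotide substitution, so
intra-cluster ANI is controlled directly by the configured rate.

The configured ``intra_cluster_site_mutation_rate`` is the target
*pairwise* divergence between cluster members: half the rate is applied
independently on each lineage from the ancestor, so two members differ at
approximately the configured rate. Substitutions that would create an
internal stop codon are reverted, keeping every CDS translatable.

Proteins are simulated first (near-uniform residue draws with a mild
dipeptide repeat tendency) and reverse-translated with codon weights solved
to hit the cluster's G+C target; intergenic gaps are drawn at the same
target, so genome-wide %GC tracks the cluster setting.

Every stochastic draw goes through one ``numpy`` generator seeded from the
config, so a run is fully reproducible from its seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

from .genome_io import Gene, Genome, write_fasta, write_genbank, _translate_cds
from .pham_builder import Protein

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_pangenome",
    "emit",
    "mutate_sequence",
    "random_genome",
    "proteins_from_genomes",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
# Robinson & Robinson background amino-acid frequencies; uniform draws would
# over-represent rare high-scoring residues (W, C) and inflate chance
# local-alignment identity between unrelated proteins
_AA_FREQ = np.array([
    0.078, 0.019, 0.054, 0.063, 0.039, 0.074, 0.022, 0.051, 0.057, 0.091,
    0.022, 0.045, 0.052, 0.043, 0.051, 0.071, 0.058, 0.064, 0.013, 0.032,
])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()
_BASES = np.array(list("ACGT"))


def _codon_backtable() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[11]
    back: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        back.setdefault(aa, []).append(codon)
    return {aa: sorted(codons) for aa, codons in back.items()}


_BACKTABLE = _codon_backtable()
_STOPS = set(CodonTable.unambiguous_dna_by_id[11].stop_codons)
_GC_COUNT = {aa: np.array([sum(b in "GC" for b in c) for c in codons])
             for aa, codons in _BACKTABLE.items()}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated pangenome."""

    seed: int = 0
    n_clusters: int = 4
    cluster_size_range: tuple[int, int] = (3, 6)
    n_singletons: int = 2
    genes_per_genome: tuple[int, int] = (15, 25)
    gene_length_aa: tuple[int, int] = (80, 300)
    core_fraction: float = 0.7
    intra_cluster_site_mutation_rate: float = 0.05  # target pairwise divergence
    inter_cluster_share_rate: float = 0.02
    orpham_rate: float = 0.10  # fraction of each genome's genes planted as orphams
    shared_gene_divergence: float = 0.20  # nt divergence of a pham copy shared across clusters
    gc_targets: tuple[float, ...] = (0.45, 0.52, 0.58, 0.64)  # cycled per cluster
    singleton_gc_range: tuple[float, float] = (0.46, 0.64)
    intergenic_gap: tuple[int, int] = (20, 120)
    minus_strand_prob: float = 0.2

    def validate(self) -> None:
        rates = {
            "core_fraction": self.core_fraction,
            "intra_cluster_site_mutation_rate": self.intra_cluster_site_mutation_rate,
            "inter_cluster_share_rate": self.inter_cluster_share_rate,
            "orpham_rate": self.orpham_rate,
            "minus_strand_prob": self.minus_strand_prob,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.core_fraction + self.orpham_rate > 1.0:
            raise ValueError("core_fraction + orpham_rate exceeds 1: no room for accessory genes")
        if self.n_clusters < 0 or self.n_singletons < 0:
            raise ValueError("counts must be non-negative")
        if self.n_clusters + self.n_singletons < 1:
            raise ValueError("nothing to simulate")
        if self.cluster_size_range[0] < 2:
            raise ValueError("clusters need >= 2 members")
        for lo, hi in (self.cluster_size_range, self.genes_per_genome,
                       self.gene_length_aa, self.intergenic_gap):
            if lo > hi:
                raise ValueError(f"range ({lo}, {hi}) is inverted")
        for g in self.gc_targets + self.singleton_gc_range:
            if not 0.2 <= g <= 0.8:
                raise ValueError("gc targets outside the plausible 0.2-0.8 range")


@dataclass
class SyntheticTruth:
    """Planted labels and realized statistics for a simulated pangenome."""

    genome_cluster: dict[str, str]  # genome id -> planted cluster / singleton label
    gene_pham: dict[str, str]  # gene id -> planted pham label
    planted_orphams: set[str]  # pham labels realized with exactly one gene
    realized_intra_ani: dict[str, float]  # cluster label -> mean pairwise identity
    realized_sharing: dict[str, float]  # cluster label -> shared-pham fraction
    config: SimConfig = field(default_factory=SimConfig)

    def partition(self) -> dict[str, str]:
        return dict(self.genome_cluster)


# ---------------------------------------------------------------------------
# Sequence-level primitives
# ---------------------------------------------------------------------------


def random_protein(length: int, rng: np.random.Generator, repeat_prob: float = 0.05) -> str:
    """Random amino-acid sequence at natural background composition, with a
    mild dipeptide repeat tendency."""
    draws = rng.choice(len(_AA20), size=length, p=_AA_FREQ)
    repeats = rng.random(length) < repeat_prob
    out = [_AA20[draws[0]]]
    for i in range(1, length):
        out.append(out[-1] if repeats[i] else _AA20[draws[i]])
    return "".join(out)


def _solve_codon_theta(protein: str, gc_target: float) -> float:
    """Exponential-tilt weight solving E[codon GC] = 3 * gc_target, clamped."""

    from collections import Counter

    counts = Counter(protein)

    def expected_gc(theta: float) -> float:
        total = 0.0
        for aa, n in counts.items():
            g = _GC_COUNT[aa]
            w = np.exp(theta * g)
            total += n * float((w * g).sum() / w.sum())
        return total / (3 * len(protein))

    lo, hi = -8.0, 8.0
    if expected_gc(lo) >= gc_target:
        return lo
    if expected_gc(hi) <= gc_target:
        return hi
    for _ in range(40):
        mid = (lo + hi) / 2
        if expected_gc(mid) < gc_target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def reverse_translate(protein: str, gc_target: float, rng: np.random.Generator) -> str:
    """Codon choice tilted so the gene's expected G+C matches the target."""
    theta = _solve_codon_theta(protein, gc_target)
    cdf = {}
    for aa in set(protein):
        w = np.exp(theta * _GC_COUNT[aa])
        cdf[aa] = np.cumsum(w / w.sum())
    draws = rng.random(len(protein))
    return "".join(
        _BACKTABLE[aa][int(np.searchsorted(cdf[aa], u))]
        for aa, u in zip(protein, draws)
    )


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """i.i.d. per-site substitution at the given rate (always to a new base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        base = arr[i].decode()
        if base not in "ACGT":
            continue
        choices = [b for b in "ACGT" if b != base]
        arr[i] = choices[rng.integers(3)].encode()
    return arr.tobytes().decode()


def _mutate_cds(nt: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution over a CDS; stop-creating codon hits are reverted."""
    mutated = mutate_sequence(nt, rate, rng)
    codons = [mutated[i : i + 3] for i in range(0, len(mutated), 3)]
    for i, codon in enumerate(codons[:-1]):
        if codon in _STOPS:
            codons[i] = nt[3 * i : 3 * i + 3]
    return "".join(codons)


def _random_gaps(n: int, total_hint: tuple[int, int], gc: float, rng: np.random.Generator) -> list[str]:
    gaps = []
    for _ in range(n):
        length = int(rng.integers(total_hint[0], total_hint[1] + 1))
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        gaps.append("".join(_BASES[rng.choice(4, size=length, p=p)]))
    return gaps


def random_genome(length: int, gc: float, rng: np.random.Generator, gid: str = "rand") -> Genome:
    """A gene-free random genome at the requested G+C, for tests and examples."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(_BASES[rng.choice(4, size=length, p=p)])
    return Genome(id=gid, sequence=seq)


# ---------------------------------------------------------------------------
# Pangenome simulation
# ---------------------------------------------------------------------------


@dataclass
class _PlantedGene:
    pham: str
    nt: str  # ancestral CDS, plus-strand orientation
    strand: str


def _make_gene_pool(prefix: str, n: int, cfg: SimConfig, gc: float,
                    rng: np.random.Generator) -> list[_PlantedGene]:
    pool = []
    for i in range(n):
        length = int(rng.integers(cfg.gene_length_aa[0], cfg.gene_length_aa[1] + 1))
        protein = random_protein(length, rng)
        nt = reverse_translate(protein, gc, rng)
        strand = "-" if rng.random() < cfg.minus_strand_prob else "+"
        pool.append(_PlantedGene(pham=f"{prefix}_{i + 1:03d}", nt=nt, strand=strand))
    return pool


def _assemble(genome_id: str, planted: Sequence[tuple[_PlantedGene, str]], gc: float,
              cfg: SimConfig, rng: np.random.Generator,
              fixed_gaps: Sequence[str] | None = None) -> Genome:
    """Lay gene cassettes (already-mutated nt given per gene) onto a genome.

    ``fixed_gaps``, when given, supplies the leading intergenic gaps (one
    before each of the first len(fixed_gaps) genes); the rest are drawn
    fresh. Inherited-then-mutated gaps keep cluster members positionally
    homologous over their core region.
    """
    from Bio.Seq import Seq

    gaps = _random_gaps(len(planted) + 1, cfg.intergenic_gap, gc, rng)
    for i, fg in enumerate(fixed_gaps or ()):
        gaps[i] = fg
    parts = [gaps[0]]
    genes = []
    pos = len(gaps[0])
    for i, (pg, nt) in enumerate(planted):
        placed = nt if pg.strand == "+" else str(Seq(nt).reverse_complement())
        genes.append(
            Gene(
                gene_id=f"{genome_id}_g{i + 1:03d}",
                start=pos,
                end=pos + len(placed),
                strand=pg.strand,
                translation=_translate_cds(nt),
            )
        )
        parts.append(placed)
        pos += len(placed)
        parts.append(gaps[i + 1])
        pos += len(gaps[i + 1])
    return Genome(id=genome_id, sequence="".join(parts), genes=genes, source_format="genbank")


def _hamming_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    same = sum(1 for x, y in zip(a[:n], b[:n]) if x == y)
    return same / n


def simulate_pangenome(config: SimConfig = SimConfig()) -> tuple[list[Genome], SyntheticTruth]:
    """Generate a planted-cluster pangenome and its ground truth."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    half_rate = cfg.intra_cluster_site_mutation_rate / 2.0

    cluster_labels = [f"cluster_{k + 1:02d}" for k in range(cfg.n_clusters)]
    gcs = {lab: cfg.gc_targets[k % len(cfg.gc_targets)] for k, lab in enumerate(cluster_labels)}
    sizes = {lab: int(rng.integers(cfg.cluster_size_range[0], cfg.cluster_size_range[1] + 1))
             for lab in cluster_labels}
    genes_target = {lab: int(rng.integers(cfg.genes_per_genome[0], cfg.genes_per_genome[1] + 1))
                    for lab in cluster_labels}

    core_pool: dict[str, list[_PlantedGene]] = {}
    acc_pool: dict[str, list[_PlantedGene]] = {}
    n_orph: dict[str, int] = {}
    for k, lab in enumerate(cluster_labels):
        g = genes_target[lab]
        n_core = max(1, round(cfg.core_fraction * g))
        n_orph[lab] = round(cfg.orpham_rate * g)
        n_acc = max(0, g - n_core - n_orph[lab])
        core_pool[lab] = _make_gene_pool(f"{lab}_core", n_core, cfg, gcs[lab], rng)
        acc_pool[lab] = _make_gene_pool(f"{lab}_acc", n_acc, cfg, gcs[lab], rng)

    # inter-cluster sharing: a cluster imports a diverged copy of another
    # cluster's core pham — shared phams between real clusters are old
    # homologs, related at the protein level but well separated in
    # nucleotide identity
    imported: dict[str, list[_PlantedGene]] = {lab: [] for lab in cluster_labels}
    for lab, donor in itertools.permutations(cluster_labels, 2):
        for pg in core_pool[donor]:
            if rng.random() < cfg.inter_cluster_share_rate:
                diverged = _mutate_cds(pg.nt, cfg.shared_gene_divergence, rng)
                imported[lab].append(_PlantedGene(pham=pg.pham, nt=diverged, strand=pg.strand))

    # accessory carriage: each accessory pham goes to >= 2 members
    carriers: dict[str, dict[str, set[int]]] = {}
    for lab in cluster_labels:
        carriers[lab] = {}
        for pg in acc_pool[lab]:
            n = int(rng.integers(2, sizes[lab] + 1)) if sizes[lab] > 2 else 2
            chosen = rng.choice(sizes[lab], size=n, replace=False)
            carriers[lab][pg.pham] = set(int(c) for c in chosen)

    genomes: list[Genome] = []
    gene_pham: dict[str, str] = {}
    genome_cluster: dict[str, str] = {}
    core_region: dict[str, list[str]] = {lab: [] for lab in cluster_labels}
    orpham_counter = itertools.count(1)

    for lab in cluster_labels:
        shared_part = imported[lab]
        ancestral_gaps = _random_gaps(len(core_pool[lab]) + len(shared_part) + 1,
                                      cfg.intergenic_gap, gcs[lab], rng)
        for m in range(sizes[lab]):
            gid = f"{lab}_m{m + 1:02d}"
            planted: list[tuple[_PlantedGene, str]] = []
            comparable: list[str] = []
            member_gaps = [mutate_sequence(gap, half_rate, rng) for gap in ancestral_gaps]
            for pg, gap in zip(core_pool[lab] + shared_part, member_gaps):
                nt = _mutate_cds(pg.nt, half_rate, rng)
                planted.append((pg, nt))
                comparable.append(gap)
                comparable.append(nt)
            comparable.append(member_gaps[-1])
            for pg in acc_pool[lab]:
                if m in carriers[lab][pg.pham]:
                    planted.append((pg, _mutate_cds(pg.nt, half_rate, rng)))
            orph = _make_gene_pool(f"orpham_{next(orpham_counter):04d}", n_orph[lab], cfg, gcs[lab], rng)
            # re-prefix so each orpham pham label is globally unique
            orph = [
                _PlantedGene(pham=f"orpham_{gid}_{i + 1:03d}", nt=pg.nt, strand=pg.strand)
                for i, pg in enumerate(orph)
            ]
            planted.extend((pg, pg.nt) for pg in orph)
            genome = _assemble(gid, planted, gcs[lab], cfg, rng, fixed_gaps=member_gaps)
            # gene order is preserved by _assemble; map ids to planted phams
            for i, (pg, _) in enumerate(planted):
                gene_pham[f"{gid}_g{i + 1:03d}"] = pg.pham
            genome_cluster[gid] = lab
            core_region[lab].append("".join(comparable))
            genomes.append(genome)

    singleton_labels = []
    for s in range(cfg.n_singletons):
        lab = f"singleton_{s + 1:02d}"
        singleton_labels.append(lab)
        gid = f"{lab}_m01"
        gc = float(rng.uniform(*cfg.singleton_gc_range))
        g = int(rng.integers(cfg.genes_per_genome[0], cfg.genes_per_genome[1] + 1))
        pool = _make_gene_pool(f"{lab}_uniq", g, cfg, gc, rng)
        planted = [(pg, pg.nt) for pg in pool]
        genome = _assemble(gid, planted, gc, cfg, rng)
        for i, (pg, _) in enumerate(planted):
            gene_pham[f"{gid}_g{i + 1:03d}"] = pg.pham
        genome_cluster[gid] = lab
        genomes.append(genome)

    # realized statistics from the truth itself
    pham_count: dict[str, int] = {}
    for pham in gene_pham.values():
        pham_count[pham] = pham_count.get(pham, 0) + 1
    planted_orphams = {p for p, c in pham_count.items() if c == 1}

    realized_intra_ani = {}
    for lab in cluster_labels:
        regions = core_region[lab]
        pairs = list(itertools.combinations(range(len(regions)), 2))
        realized_intra_ani[lab] = (
            sum(_hamming_identity(regions[i], regions[j]) for i, j in pairs) / len(pairs)
            if pairs else 1.0
        )

    universe: dict[str, set[str]] = {}
    for gene_id, pham in gene_pham.items():
        gid = gene_id.rsplit("_g", 1)[0]
        universe.setdefault(genome_cluster[gid], set()).add(pham)
    realized_sharing = {}
    for lab in cluster_labels + singleton_labels:
        others = set().union(*(u for l, u in universe.items() if l != lab)) if len(universe) > 1 else set()
        realized_sharing[lab] = len(universe[lab] & others) / len(universe[lab])

    truth = SyntheticTruth(
        genome_cluster=genome_cluster,
        gene_pham=gene_pham,
        planted_orphams=planted_orphams,
        realized_intra_ani=realized_intra_ani,
        realized_sharing=realized_sharing,
        config=cfg,
    )
    return genomes, truth


def proteins_from_genomes(genomes: Sequence[Genome]) -> list[Protein]:
    """Flatten genome annotations into the protein records pham building uses."""
    return [
        Protein(protein_id=gene.gene_id, phage_id=g.id, sequence=gene.translation)
        for g in genomes
        for gene in g.genes
        if gene.translation
    ]


def emit(genomes: Sequence[Genome], truth: SyntheticTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write GenBank + FASTA + truth tables; byte-identical for a given seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for g in genomes:
        p = out / f"{g.id}.gbk"
        write_genbank(g, p)
        paths[g.id] = p
    fasta = out / "genomes.fasta"
    write_fasta(list(genomes), fasta)
    paths["fasta"] = fasta

    import pandas as pd

    gt = pd.DataFrame(
        [
            {"genome": gid, "cluster": lab,
             "realized_intra_ani": truth.realized_intra_ani.get(lab, float("nan")),
             "realized_sharing": truth.realized_sharing.get(lab, float("nan"))}
            for gid, lab in sorted(truth.genome_cluster.items())
        ],
        columns=["genome", "cluster", "realized_intra_ani", "realized_sharing"],
    )
    gt_path = out / "genome_truth.tsv"
    gt.to_csv(gt_path, sep="\t", index=False)
    paths["genome_truth"] = gt_path

    rows = [
        {"gene_id": gene_id, "genome": gene_id.rsplit("_g", 1)[0], "pham": pham,
         "is_orpham": pham in truth.planted_orphams}
        for gene_id, pham in sorted(truth.gene_pham.items())
    ]
    gene_path = out / "gene_truth.tsv"
    pd.DataFrame(rows).to_csv(gene_path, sep="\t", index=False)
    paths["gene_truth"] = gene_path
    return paths
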