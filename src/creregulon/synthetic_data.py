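"""Synthetic genomes with planted CRE sites and regulon-structured expression.

Every downstream stage of the pipeline is validated against data generated
here, where the ground truth — planted site coordinates and regulon
membership with per-phase fold effects — is known exactly.  The generator
emulates a single contig of i.i.d. bases at a chosen GC content (the default
0.31 matches a low-GC firmicute genome), genes alternating strands with
roughly exponential intergenic gaps, a degenerate 16-bp pseudo-palindromic
motif planted in upstream regions and inside ORFs, and a two-strain
multi-phase intensity matrix in which regulon genes carry multiplicative
fold effects over log-normal noise.

All randomness flows from a single integer seed; identical seeds give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from creregulon.expression import ExpressionMatrix, SampleKey
from creregulon.io_formats import FeatureRecord, SequenceRecord, reverse_complement
from creregulon.motif_discovery import BASES, Pwm, build_pwm, uniform_background

#: COG functional category letters (plus the not-in-COGs pool) used for
#: per-category differential-expression summaries.
COG_CATEGORIES = tuple("GEHRKFTCIONMPJLQVDUS") + ("-",)

CRE_CONSENSUS = "WTGWAAACGWTWWCAW"

#: Non-palindromic, strong-edged consensus used to benchmark exact-offset
#: recovery of the Gibbs sampler.  Pseudo-palindromic motifs with degenerate
#: (W) edge columns — like the CRE itself — admit shifted, strand-collapsed
#: alignments that genuinely outscore the planted configuration, so exact
#: offsets are not identifiable for them; this motif has the same column
#: degeneracy budget (10 single-base + 6 two-base columns) without that
#: degeneracy.
BENCHMARK_CONSENSUS = "TGGCAWRYKMWTTCCG"


@dataclass(frozen=True)
class PlantedSite:
    contig: str
    start0: int
    strand: str
    context: str  # upstream | orf
    source_gene: str
    site_sequence: str  # strand-adjusted (as sampled from the PWM)


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic dataset: planted sites and regulon effects."""

    planted_sites: list[PlantedSite] = field(default_factory=list)
    regulon: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0


def cre_consensus_pwm(strength: float = 0.9, consensus: str = CRE_CONSENSUS) -> Pwm:
    """A CRE-like PWM realising an IUPAC consensus string.

    Single-base columns give the named base probability ``strength`` (the rest
    split evenly); two-base IUPAC columns (e.g. W = A/T) split ``strength``
    between the two named bases.  At the default strength the matrix carries
    ≈17 bits of information — in the range of genuine CRE alignments.
    """
    iupac = {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "W": "AT", "S": "CG", "R": "AG", "Y": "CT", "K": "GT", "M": "AC",
    }
    rows = []
    for ch in consensus:
        bases = iupac[ch]
        row = np.full(4, (1.0 - strength) / (4 - len(bases)))
        for b in bases:
            row[BASES.index(b)] = strength / len(bases)
        rows.append(row)
    return Pwm(
        width=len(consensus),
        probs=np.array(rows),
        pseudocount=0.0,
        background=uniform_background(),
    )


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[i] for i in rng.choice(4, size=length, p=p))


def generate_genome(
    n_genes: int,
    mean_gene_len: int = 600,
    mean_intergenic: int = 120,
    gc: float = 0.31,
    seed: int = 0,
    contig_id: str = "synthetic_1",
    intergenic_floor: int = 26,
    cog_weights: dict[str, float] | None = None,
) -> tuple[SequenceRecord, list[FeatureRecord]]:
    """Generate one contig of i.i.d. bases with non-overlapping genes.

    Genes alternate strands; intergenic gaps are ``intergenic_floor`` plus an
    exponential excess (the floor, motif width + 10 by default, guarantees
    every gap can host a planted site).  Each gene is assigned a COG category
    letter drawn from ``cog_weights`` (uniform over the 21 categories by
    default, '-' meaning not in COGs).
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if not (0 < gc < 1):
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if cog_weights is None:
        cats = list(COG_CATEGORIES)
        weights = np.full(len(cats), 1.0 / len(cats))
    else:
        cats = list(cog_weights)
        weights = np.array(list(cog_weights.values()), dtype=float)
        weights = weights / weights.sum()
    features = []
    pos = 0
    excess = max(mean_intergenic - intergenic_floor, 1)
    for i in range(n_genes):
        gap = intergenic_floor + int(rng.exponential(excess))
        start = pos + gap
        length = max(90, int(rng.gamma(4.0, mean_gene_len / 4.0)))
        length -= length % 3
        strand = "+" if i % 2 == 0 else "-"
        cog = str(rng.choice(cats, p=weights))
        attrs = {} if cog == "-" else {"cog": cog}
        features.append(
            FeatureRecord(
                contig=contig_id,
                start0=start,
                end0=start + length,
                strand=strand,
                feature_id=f"SYN{i + 1:04d}",
                feature_type="gene",
                attributes=attrs,
            )
        )
        pos = start + length
    tail = intergenic_floor + int(rng.exponential(excess))
    total_len = pos + tail
    sequence = _random_dna(rng, total_len, gc)
    return SequenceRecord(id=contig_id, sequence=sequence), features


def _upstream_interval(
    gene: FeatureRecord, neighbours: list[FeatureRecord], contig_len: int, max_len: int = 400
) -> tuple[int, int]:
    """Genomic interval of the gene's upstream gap, clipped to adjacent genes."""
    if gene.strand == "+":
        lo = max((f.end0 for f in neighbours if f.end0 <= gene.start0), default=0)
        lo = max(lo, gene.start0 - max_len)
        return lo, gene.start0
    hi = min((f.start0 for f in neighbours if f.start0 >= gene.end0), default=contig_len)
    hi = min(hi, gene.end0 + max_len)
    return gene.end0, hi


def plant_sites(
    genome: SequenceRecord,
    annotations: list[FeatureRecord],
    pwm: Pwm,
    n_upstream: int,
    n_orf: int,
    seed: int = 0,
    orf_margin: int = 9,
) -> tuple[SequenceRecord, SyntheticTruth]:
    """Plant motif instances into distinct upstream regions and distinct ORFs.

    Each site is sampled column-wise from the PWM, placed on a uniformly
    random strand (written as its reverse complement when '-'), at a uniform
    eligible position.  Sites never overlap one another; the truth records
    exact genomic coordinates, context and source gene.
    """
    rng = np.random.default_rng(seed)
    width = pwm.width
    seq = list(genome.sequence)
    contig_len = len(seq)
    occupied: set[int] = set()
    truth = SyntheticTruth(seed=seed)
    genes = sorted(annotations, key=lambda f: f.start0)

    def try_place(lo: int, hi: int, context: str, gene_id: str) -> bool:
        """Place one sampled site within [lo, hi); returns success."""
        if hi - lo < width:
            return False
        positions = [
            p
            for p in range(lo, hi - width + 1)
            if not occupied & set(range(p, p + width))
        ]
        if not positions:
            return False
        start = int(rng.choice(positions))
        site = pwm.sample_site(rng)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        written = site if strand == "+" else reverse_complement(site)
        seq[start : start + width] = written
        occupied.update(range(start, start + width))
        truth.planted_sites.append(
            PlantedSite(
                contig=genome.id,
                start0=start,
                strand=strand,
                context=context,
                source_gene=gene_id,
                site_sequence=site,
            )
        )
        return True

    up_candidates = list(rng.permutation(len(genes)))
    placed = 0
    for gi in up_candidates:
        if placed >= n_upstream:
            break
        g = genes[gi]
        lo, hi = _upstream_interval(g, genes, contig_len)
        if try_place(lo, hi, "upstream", g.feature_id):
            placed += 1
    if placed < n_upstream:
        raise ValueError(
            f"not enough eligible upstream regions: placed {placed} of {n_upstream}"
        )
    orf_candidates = list(rng.permutation(len(genes)))
    placed = 0
    for gi in orf_candidates:
        if placed >= n_orf:
            break
        g = genes[gi]
        if any(s.source_gene == g.feature_id and s.context == "orf" for s in truth.planted_sites):
            continue
        if try_place(g.start0 + orf_margin, g.end0 - orf_margin, "orf", g.feature_id):
            placed += 1
    if placed < n_orf:
        raise ValueError(f"not enough eligible ORFs: placed {placed} of {n_orf}")
    return SequenceRecord(id=genome.id, sequence="".join(seq)), truth


def generate_expression(
    annotations: list[FeatureRecord],
    regulon_spec: dict[str, float | dict[str, float]],
    noise_cv: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
    phases: tuple[str, ...] = ("M", "L", "T", "S"),
    wt_strain: str = "824WT",
    mutant_strain: str = "824ccpA",
    base_median: float = 500.0,
    base_sigma: float = 1.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-strain, multi-phase intensity matrix with regulon fold effects.

    Every gene's wild-type level is drawn log-normal (median ``base_median``,
    log-sd ``base_sigma``); the mutant level is the wild-type level times the
    gene's fold effect (1 outside the regulon).  Replicates carry
    multiplicative log-normal noise with coefficient of variation
    ``noise_cv``; ``noise_cv=0`` gives exact fold changes.  ``regulon_spec``
    maps gene → fold, or gene → {phase: fold} for phase-specific effects.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be ≥ 0")
    if replicates < 1:
        raise ValueError("replicates must be ≥ 1")
    rng = np.random.default_rng(seed)
    genes = [f.feature_id for f in annotations]
    regulon: dict[str, dict[str, float]] = {}
    for gene, spec in regulon_spec.items():
        if gene not in genes:
            raise ValueError(f"regulon gene {gene!r} not in the annotation")
        folds = {p: float(spec) for p in phases} if not isinstance(spec, dict) else {
            p: float(v) for p, v in spec.items()
        }
        if any(v <= 0 for v in folds.values()):
            raise ValueError(f"fold effects must be > 0 (gene {gene!r})")
        regulon[gene] = folds
    sigma_noise = float(np.sqrt(np.log1p(noise_cv**2)))
    base = base_median * np.exp(rng.normal(0.0, base_sigma, size=len(genes)))
    samples = [
        SampleKey(strain=strain, phase=phase, replicate=rep)
        for strain in (wt_strain, mutant_strain)
        for phase in phases
        for rep in range(1, replicates + 1)
    ]
    values = np.empty((len(genes), len(samples)))
    for j, key in enumerate(samples):
        col = base.copy()
        if key.strain == mutant_strain:
            for gi, gene in enumerate(genes):
                fold = regulon.get(gene, {}).get(key.phase, 1.0)
                col[gi] = col[gi] * fold
        if sigma_noise > 0:
            col = col * np.exp(rng.normal(0.0, sigma_noise, size=len(genes)))
        values[:, j] = col
    matrix = ExpressionMatrix(genes=genes, samples=samples, values=values)
    truth = SyntheticTruth(regulon=regulon, seed=seed)
    return matrix, truth


def generate_motif_regions(
    n_regions: int,
    region_len: int,
    pwm: Pwm,
    seed: int = 0,
    gc: float = 0.31,
    sites_per_region: int = 1,
) -> tuple[list[str], list[tuple[int, int, str, str]]]:
    """Background regions each carrying planted motif instances.

    Returns the regions and a truth list of ``(region_index, offset, strand,
    site_sequence)`` tuples; the site sequence is strand-adjusted.  Used to
    benchmark motif discovery in isolation from genome structure.
    """
    rng = np.random.default_rng(seed)
    width = pwm.width
    if region_len < sites_per_region * (width + 2):
        raise ValueError("regions too short for the requested number of sites")
    regions = []
    truth = []
    for i in range(n_regions):
        seq = list(_random_dna(rng, region_len, gc))
        taken: set[int] = set()
        for _ in range(sites_per_region):
            while True:
                off = int(rng.integers(0, region_len - width + 1))
                if not taken & set(range(off - width + 1, off + width)):
                    break
            site = pwm.sample_site(rng)
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            written = site if strand == "+" else reverse_complement(site)
            seq[off : off + width] = written
            taken.add(off)
            taken.update(range(off, off + width))
            truth.append((i, off, strand, site))
        regions.append("".join(seq))
    return regions, truth
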