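"""Ungapped log-odds profile scanning with training-set score calibration.

The profile model is a gapless chain of match states — equivalent to a
log-odds position-specific scoring matrix in bits — because the training
alignment is ungapped, so insert/delete machinery would be untrainable.  A
window's bit score is the sum of per-position log2(motif/background) terms;
N contributes 0 at every position.

The scan threshold (the "significance score") is calibrated on the training
set itself: the lowest positive bit score attained by any training site.
Windows scoring at or above it are primary hits; windows scoring slightly
below it (within a configurable slack) are rescued when their associated gene
is differentially expressed after regulator inactivation.  An extreme-value
(Gumbel) calibration maps bit scores to E-values for reporting, but
thresholding uses the bit score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import gumbel_r

from creregulon.io_formats import SequenceRecord, reverse_complement
from creregulon.expression import DeCall
from creregulon.motif_discovery import (
    MotifAlignment,
    Pwm,
    _window_scores,
    encode,
)
from creregulon.regions import GeneModel, UpstreamRegion

logger = logging.getLogger(__name__)


@dataclass
class ProfileModel:
    """Position-specific log-odds model (bits) with its scan calibration."""

    width: int
    log_odds: np.ndarray  # (width, 4) in bits
    background: np.ndarray  # (4,)
    significance_score: float | None = None
    slack: float = 0.5  # bits; the "slightly lower" rescue margin

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.shape != (self.width, 4):
            raise ValueError("log_odds must be (width, 4)")
        if self.slack < 0:
            raise ValueError("slack must be ≥ 0")

    def reverse_complement(self) -> "ProfileModel":
        return replace(self, log_odds=self.log_odds[::-1, ::-1].copy())


@dataclass(frozen=True)
class EvdFit:
    """Gumbel fit to background scores: E(s) = n_targets · exp(−lambda·(s − mu))."""

    mu: float
    lam: float
    n_samples: int

    def evalue(self, score: float, n_targets: int = 1) -> float:
        return n_targets * float(np.exp(-self.lam * (score - self.mu)))


@dataclass
class CreHit:
    """One candidate CRE site located on the genome."""

    contig: str
    start0: int
    end0: int
    strand: str
    score: float
    context: str  # upstream | orf | intergenic-other
    associated_gene: str | None = None
    inclusion: str = "primary"  # primary | rescued-by-DE
    status: str = "kept"  # kept | removed
    removal_reason: str | None = None

    def __post_init__(self) -> None:
        if self.status == "removed" and not self.removal_reason:
            raise ValueError("removed hits must carry a removal reason")

    @property
    def midpoint(self) -> float:
        return (self.start0 + self.end0) / 2.0


@dataclass
class ScanReport:
    n_upstream: int
    n_orf: int
    hits_by_gene: dict[str, list[CreHit]]
    parameters: dict = field(default_factory=dict)


def build_profile(pwm: Pwm, background: np.ndarray | None = None) -> ProfileModel:
    """Convert a PWM into the log-odds profile (bits) against the background."""
    bg = pwm.background if background is None else np.asarray(background, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background frequencies must be > 0")
    if np.any(pwm.probs <= 0):
        raise ValueError("PWM contains zero probabilities; rebuild with a pseudocount")
    return ProfileModel(
        width=pwm.width,
        log_odds=np.log2(pwm.probs / bg),
        background=bg,
    )


def score_window(model: ProfileModel, window: str) -> float:
    """Bit score of one window: Σ_i log_odds[i][x_i], with N scoring 0."""
    if len(window) != model.width:
        raise ValueError(f"window length {len(window)} != model width {model.width}")
    codes = encode(window)
    lo = np.hstack([model.log_odds, np.zeros((model.width, 1))])
    return float(lo[np.arange(model.width), codes].sum())


def score_all_windows(model: ProfileModel, sequence: str) -> np.ndarray:
    """Bit scores of every width-sized window of ``sequence`` (forward strand)."""
    return _window_scores(encode(sequence), model.log_odds, model.width)


def calibrate_threshold(
    model: ProfileModel, training_sites: MotifAlignment | Sequence[str]
) -> ProfileModel:
    """Set the significance score: the lowest positive training-site score."""
    seqs = (
        training_sites.site_sequences
        if isinstance(training_sites, MotifAlignment)
        else list(training_sites)
    )
    positive = [s for s in (score_window(model, seq) for seq in seqs) if s > 0]
    if not positive:
        raise ValueError("no training site scores positive; cannot calibrate")
    return replace(model, significance_score=min(positive))


def calibrate_evd(
    model: ProfileModel,
    n_random: int = 5000,
    seq_len: int | None = None,
    background: np.ndarray | None = None,
    seed: int = 0,
    scores: np.ndarray | None = None,
) -> EvdFit:
    """Fit a Gumbel law to max-scores of random background sequences.

    Draws ``n_random`` i.i.d. background sequences of length ``seq_len``
    (default: the model width, so the max is over a single window), records
    each sequence's best window score, and fits location ``mu`` and scale
    ``1/lambda`` by maximum likelihood.  ``scores`` bypasses simulation for
    testing the fit itself.
    """
    if scores is None:
        if n_random < 100:
            raise ValueError("n_random must be ≥ 100")
        bg = model.background if background is None else np.asarray(background, float)
        bg = bg / bg.sum()
        L = model.width if seq_len is None else seq_len
        if L < model.width:
            raise ValueError("seq_len must be ≥ model width")
        rng = np.random.default_rng(seed)
        draws = rng.choice(4, size=(n_random, L), p=bg).astype(np.int8)
        scores = np.array(
            [_window_scores(row, model.log_odds, model.width).max() for row in draws]
        )
    scores = np.asarray(scores, dtype=float)
    if scores.std() == 0:
        raise ValueError("degenerate (zero-variance) score sample")
    loc, scale = gumbel_r.fit(scores)
    return EvdFit(mu=float(loc), lam=float(1.0 / scale), n_samples=len(scores))


def _de_genes(de_calls: Iterable[DeCall] | None) -> set[str]:
    if de_calls is None:
        return set()
    return {c.gene for c in de_calls if c.direction != "none"}


def _down_genes(de_calls: Iterable[DeCall] | None) -> set[str]:
    if de_calls is None:
        return set()
    return {c.gene for c in de_calls if c.direction == "down"}


def _resolve_overlaps(hits: list[CreHit]) -> list[CreHit]:
    """Greedy best-score overlap resolution, leftmost on ties.

    Overlapping hits on the same strand collapse to the best-scoring one
    (leftmost on an exact tie); afterwards a palindromic double hit (identical
    interval surviving on both strands) keeps the higher-scoring strand, '+'
    on an exact tie.  Per-strand resolution runs first so that a palindromic
    window competes on both physical strands before its labels collapse.
    """
    resolved: list[CreHit] = []
    by_group: dict[tuple[str, str], list[CreHit]] = {}
    for h in hits:
        by_group.setdefault((h.contig, h.strand), []).append(h)
    for group in by_group.values():
        group.sort(key=lambda h: (-h.score, h.start0))
        taken: list[CreHit] = []
        for h in group:
            if all(h.end0 <= t.start0 or h.start0 >= t.end0 for t in taken):
                taken.append(h)
        resolved.extend(taken)
    by_interval: dict[tuple[str, int, int], CreHit] = {}
    for h in resolved:
        key = (h.contig, h.start0, h.end0)
        prev = by_interval.get(key)
        if (
            prev is None
            or h.score > prev.score
            or (h.score == prev.score and h.strand == "+")
        ):
            by_interval[key] = h
    kept = list(by_interval.values())
    kept.sort(key=lambda h: (h.contig, h.start0, h.strand))
    return kept


def _scan_interval(
    model: ProfileModel,
    genome_seq: str,
    contig: str,
    start0: int,
    end0: int,
    context: str,
    gene: str | None,
    de_genes: set[str],
) -> list[CreHit]:
    sub = genome_seq[start0:end0]
    if len(sub) < model.width:
        return []
    threshold = model.significance_score
    rescue_floor = threshold - model.slack
    hits = []
    fwd = score_all_windows(model, sub)
    rev = score_all_windows(model, reverse_complement(sub))[::-1]
    for strand, scores in (("+", fwd), ("-", rev)):
        candidate = np.flatnonzero(scores >= rescue_floor)
        for off in candidate:
            score = float(scores[off])
            if score >= threshold:
                inclusion = "primary"
            elif gene is not None and gene in de_genes:
                inclusion = "rescued-by-DE"
            else:
                continue
            hits.append(
                CreHit(
                    contig=contig,
                    start0=start0 + int(off),
                    end0=start0 + int(off) + model.width,
                    strand=strand,
                    score=score,
                    context=context,
                    associated_gene=gene,
                    inclusion=inclusion,
                )
            )
    return hits


def scan(
    model: ProfileModel,
    genome: SequenceRecord,
    gene_models: list[GeneModel],
    upstream_regions: list[UpstreamRegion],
    de_calls: Iterable[DeCall] | None = None,
) -> list[CreHit]:
    """Scan upstream regions and ORFs on both strands for CRE-like windows.

    Inclusion follows two rules: (i) windows with bit score at or above the
    significance score; (ii) windows within ``model.slack`` bits below it
    whose associated gene (or operon) is differentially expressed.  Overlaps
    on a strand resolve to the best-scoring window.
    """
    if model.significance_score is None:
        raise ValueError("model is not calibrated: significance_score unset")
    de = _de_genes(de_calls)
    # operon-aware rescue: a region's lead gene stands for all operon members
    operon_members: dict[str, set[str]] = {}
    for g in gene_models:
        operon_members.setdefault(g.operon_id or g.feature_id, set()).add(g.feature_id)
    gene_de: set[str] = set()
    for g in gene_models:
        members = operon_members.get(g.operon_id or g.feature_id, {g.feature_id})
        if members & de:
            gene_de.add(g.feature_id)
    hits: list[CreHit] = []
    for region in upstream_regions:
        hits.extend(
            _scan_interval(
                model,
                genome.sequence,
                region.contig,
                region.start0,
                region.end0,
                "upstream",
                region.gene_id,
                gene_de,
            )
        )
    for g in gene_models:
        hits.extend(
            _scan_interval(
                model,
                genome.sequence,
                g.contig,
                g.start0,
                g.end0,
                "orf",
                g.feature_id,
                gene_de,
            )
        )
    return _resolve_overlaps(hits)


def filter_hits(
    hits: list[CreHit],
    gene_models: list[GeneModel],
    de_calls: Iterable[DeCall] | None = None,
    three_prime_fraction: float = 0.5,
) -> list[CreHit]:
    """Apply the two site-removal rules; idempotent.

    Rule i: an ORF hit whose midpoint lies in the 3' portion of the ORF
    (beyond ``three_prime_fraction`` of its strand-oriented length) is removed
    when a strictly higher-scoring hit exists in the 5' portion of the same
    ORF or in that gene's upstream region.  Rule ii: an ORF hit in a gene that
    is down-regulated after regulator inactivation (i.e. a gene the regulator
    activates) is removed — activated genes carry their functional sites
    upstream of the promoter, not inside the ORF.
    """
    genes = {g.feature_id: g for g in gene_models}
    down = _down_genes(de_calls)

    def orf_fraction(hit: CreHit) -> float | None:
        g = genes.get(hit.associated_gene or "")
        if g is None or len(g) == 0:
            return None
        frac = (hit.midpoint - g.start0) / len(g)
        return frac if g.strand == "+" else 1.0 - frac

    out: list[CreHit] = []
    by_gene: dict[str, list[CreHit]] = {}
    for h in hits:
        if h.associated_gene:
            by_gene.setdefault(h.associated_gene, []).append(h)
    for h in hits:
        if h.status == "removed":
            out.append(h)
            continue
        new = replace(h)
        if h.context == "orf" and h.associated_gene:
            if h.associated_gene in down:
                new = replace(
                    h,
                    status="removed",
                    removal_reason="in ORF of a regulator-activated (down-regulated) gene",
                )
            else:
                frac = orf_fraction(h)
                if frac is not None and frac > three_prime_fraction:
                    competitors = by_gene.get(h.associated_gene, [])
                    for c in competitors:
                        if c is h or c.score <= h.score:
                            continue
                        if c.context == "upstream":
                            break
                        cf = orf_fraction(c)
                        if cf is not None and cf <= three_prime_fraction:
                            break
                    else:
                        out.append(new)
                        continue
                    new = replace(
                        h,
                        status="removed",
                        removal_reason="3'-ORF site with a higher-scoring 5'/promoter site",
                    )
        out.append(new)
    return out


def classify_and_report(
    hits: list[CreHit],
    upstream_regions: list[UpstreamRegion],
    gene_models: list[GeneModel],
) -> ScanReport:
    """Assign context by hit midpoint and count kept upstream vs in-ORF sites."""
    finalized: list[CreHit] = []
    for h in hits:
        context = "intergenic-other"
        gene = h.associated_gene
        for r in upstream_regions:
            if r.contig == h.contig and r.start0 <= h.midpoint < r.end0:
                context, gene = "upstream", r.gene_id
                break
        else:
            for g in gene_models:
                if g.contig == h.contig and g.start0 <= h.midpoint < g.end0:
                    context, gene = "orf", g.feature_id
                    break
        finalized.append(replace(h, context=context, associated_gene=gene))
    kept = [h for h in finalized if h.status == "kept"]
    n_upstream = sum(1 for h in kept if h.context == "upstream")
    n_orf = sum(1 for h in kept if h.context == "orf")
    by_gene: dict[str, list[CreHit]] = {}
    for h in finalized:
        if h.associated_gene:
            by_gene.setdefault(h.associated_gene, []).append(h)
    return ScanReport(n_upstream=n_upstream, n_orf=n_orf, hits_by_gene=by_gene)


def write_profile(model: ProfileModel, path) -> None:
    """Plain-text tabular serialization: width, background, per-position log-odds."""
    with open(path, "w") as fh:
        fh.write(f"# creregulon profile model\nwidth\t{model.width}\n")
        fh.write("background\t" + "\t".join(f"{b:.10g}" for b in model.background) + "\n")
        sig = "" if model.significance_score is None else f"{model.significance_score:.10g}"
        fh.write(f"significance_score\t{sig}\n")
        fh.write(f"slack\t{model.slack:.10g}\n")
        fh.write("pos\tA\tC\tG\tT\n")
        for i, row in enumerate(model.log_odds):
            fh.write(f"{i}\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def read_profile(path) -> ProfileModel:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    header = {}
    rows = []
    for ln in lines:
        parts = ln.split("\t")
        if parts[0] in ("width", "background", "significance_score", "slack"):
            header[parts[0]] = parts[1:]
        elif parts[0] != "pos":
            rows.append([float(x) for x in parts[1:5]])
    sig_field = header["significance_score"]
    sig = float(sig_field[0]) if sig_field and sig_field[0] else None
    return ProfileModel(
        width=int(header["width"][0]),
        log_odds=np.array(rows),
        background=np.array([float(x) for x in header["background"]]),
        significance_score=sig,
        slack=float(header["slack"][0]),
    )
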