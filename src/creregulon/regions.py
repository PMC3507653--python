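"""Operon grouping and strand-aware upstream-region extraction.

Motif discovery operates on the non-coding DNA 5' of each regulated
transcription unit.  Genes on the same strand separated by a short intergenic
gap are grouped into operons (an explicit ``operon`` annotation attribute
overrides the distance heuristic), and by default only the operon lead gene —
the 5'-most member on its strand — contributes an upstream region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from creregulon.io_formats import FeatureRecord, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class GeneModel(FeatureRecord):
    """A gene feature annotated with its operon membership."""

    operon_id: str = ""
    is_operon_lead: bool = True


@dataclass(frozen=True)
class UpstreamRegion:
    """Upstream non-coding interval of a gene, strand-adjusted.

    ``sequence`` reads 5'→3' relative to the gene: for a − strand gene it is
    the reverse complement of the genomic window ``[start0, end0)``.
    """

    gene_id: str
    contig: str
    start0: int
    end0: int
    strand: str
    sequence: str

    def __len__(self) -> int:
        return self.end0 - self.start0

    @property
    def region_id(self) -> str:
        return f"{self.gene_id}|{self.contig}:{self.start0}-{self.end0}({self.strand})"


def group_operons(
    features: list[FeatureRecord],
    max_gap: int = 100,
    require_same_strand: bool = True,
) -> list[GeneModel]:
    """Group adjacent same-strand genes with gap ≤ ``max_gap`` into operons.

    The gap bound is inclusive.  Features carrying an ``operon`` attribute are
    grouped by that id instead; heuristic and explicit groups never merge.
    The operon lead is the 5'-most member on the operon's strand.
    """
    ordered = sorted(features, key=lambda f: (f.contig, f.start0))
    models: list[GeneModel] = []
    auto_counter = 0
    current: list[FeatureRecord] = []

    def flush() -> None:
        nonlocal auto_counter
        if not current:
            return
        explicit = current[0].attributes.get("operon")
        if explicit:
            operon_id = explicit
        else:
            auto_counter += 1
            operon_id = f"operon_{auto_counter:04d}"
        lead = current[0] if current[0].strand == "+" else current[-1]
        for f in current:
            models.append(
                GeneModel(
                    contig=f.contig,
                    start0=f.start0,
                    end0=f.end0,
                    strand=f.strand,
                    feature_id=f.feature_id,
                    feature_type=f.feature_type,
                    attributes=dict(f.attributes),
                    operon_id=operon_id,
                    is_operon_lead=f is lead,
                )
            )
        current.clear()

    for f in ordered:
        if not current:
            current.append(f)
            continue
        prev = current[-1]
        same_contig = f.contig == prev.contig
        same_strand = f.strand == prev.strand or not require_same_strand
        gap = f.start0 - prev.end0
        prev_op = prev.attributes.get("operon")
        this_op = f.attributes.get("operon")
        if prev_op is not None or this_op is not None:
            joined = prev_op is not None and prev_op == this_op
        else:
            joined = same_contig and same_strand and gap <= max_gap
        if joined:
            current.append(f)
        else:
            flush()
            current.append(f)
    flush()
    models.sort(key=lambda m: (m.contig, m.start0))
    return models


def extract_upstream(
    genome: SequenceRecord,
    models: list[GeneModel],
    max_len: int = 400,
    clip_to_prev_feature: bool = True,
    operon_level: bool = True,
) -> list[UpstreamRegion]:
    """Extract upstream non-coding regions (the motif-discovery substrate).

    For a + strand gene the region is ``[max(prev_feature_end, start − max_len),
    start)``; for a − strand gene the mirror-image window 3' of its end, with
    the returned sequence reverse-complemented so it always reads towards the
    gene start.  With ``operon_level`` only operon lead genes yield regions.
    Zero-length regions (back-to-back genes) are omitted with a log entry.
    """
    contig_len = len(genome.sequence)
    by_contig: dict[str, list[GeneModel]] = {}
    for m in models:
        by_contig.setdefault(m.contig, []).append(m)
    unknown = set(by_contig) - {genome.id}
    if unknown:
        raise ValueError(f"features on contig(s) {sorted(unknown)} not in genome {genome.id!r}")
    regions: list[UpstreamRegion] = []
    for contig, genes in by_contig.items():
        genes = sorted(genes, key=lambda g: g.start0)
        for i, g in enumerate(genes):
            if g.end0 > contig_len:
                raise ValueError(f"gene {g.feature_id!r} extends beyond the genome")
            if operon_level and not g.is_operon_lead:
                continue
            if g.strand == "+":
                lo = g.start0 - max_len
                if clip_to_prev_feature:
                    prev_ends = [h.end0 for h in genes[:i] if h.end0 <= g.start0]
                    if prev_ends:
                        lo = max(lo, max(prev_ends))
                lo = max(lo, 0)
                hi = g.start0
            else:
                hi = g.end0 + max_len
                if clip_to_prev_feature:
                    next_starts = [h.start0 for h in genes[i + 1 :] if h.start0 >= g.end0]
                    if next_starts:
                        hi = min(hi, min(next_starts))
                hi = min(hi, contig_len)
                lo = g.end0
            if hi <= lo:
                logger.info("gene %s: empty upstream region, omitted", g.feature_id)
                continue
            window = genome.sequence[lo:hi]
            seq = window if g.strand == "+" else reverse_complement(window)
            regions.append(
                UpstreamRegion(
                    gene_id=g.feature_id,
                    contig=contig,
                    start0=lo,
                    end0=hi,
                    strand=g.strand,
                    sequence=seq,
                )
            )
    return regions
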