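"""End-to-end orchestration: expression → regions → discovery → scan → report.

This is the analysis in one call, on any dataset laid out as (genome,
annotation, expression matrix): classify differential expression of the
mutant-vs-wild-type contrast, extract upstream regions of the up-regulated
genes/operons, discover the CRE motif by Gibbs sampling plus the recursive
occurrence pass, build and calibrate the log-odds profile, scan all upstream
regions and ORFs, and apply the site-filtering rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from creregulon import expression as expr
from creregulon import regions as regmod
from creregulon.cre_scan import (
    CreHit,
    ProfileModel,
    build_profile,
    calibrate_threshold,
    classify_and_report,
    filter_hits,
    scan,
    ScanReport,
)
from creregulon.expression import DeCall, ExpressionMatrix
from creregulon.io_formats import FeatureRecord, SequenceRecord
from creregulon.motif_discovery import (
    MotifAlignment,
    Pwm,
    build_pwm,
    consensus,
    gibbs_sample_motif,
    recursive_pass,
)
from creregulon.regions import GeneModel, UpstreamRegion


@dataclass
class PipelineResult:
    de_calls: list[DeCall]
    up_genes: set[str]
    gene_models: list[GeneModel]
    upstream_regions: list[UpstreamRegion]  # all genes, gene-level
    alignment: MotifAlignment
    pwm: Pwm
    consensus: str
    model: ProfileModel
    hits: list[CreHit]
    report: ScanReport
    params: dict = field(default_factory=dict)


def run_pipeline(
    genome: SequenceRecord,
    features: list[FeatureRecord],
    matrix: ExpressionMatrix,
    mutant_strain: str = "824ccpA",
    wt_strain: str = "824WT",
    phases: tuple[str, ...] = ("M", "L", "T", "S"),
    width: int = 16,
    up_threshold: float = 2.0,
    restarts: int = 8,
    seed: int = 0,
    slack: float = 0.5,
) -> PipelineResult:
    """Run the full regulon-reconstruction analysis on one dataset."""
    norm = expr.quantile_normalize(matrix)
    table = expr.fold_changes(
        norm, (mutant_strain, list(phases)), (wt_strain, list(phases))
    )
    calls = expr.classify_de(table, up_threshold=up_threshold)
    up_genes = {c.gene for c in calls if c.direction == "up"}
    models = regmod.group_operons(features)
    up_models = [m for m in models if m.feature_id in up_genes]
    disc_regions = [
        r
        for r in regmod.extract_upstream(genome, up_models, operon_level=True)
        if len(r) >= width
    ]
    seqs = [r.sequence for r in disc_regions]
    ids = [r.region_id for r in disc_regions]
    alignment, disc_pwm = gibbs_sample_motif(
        seqs, width=width, restarts=restarts, seed=seed, region_ids=ids
    )
    alignment = recursive_pass(seqs, disc_pwm, alignment=alignment, region_ids=ids)
    pwm = build_pwm(alignment, background=disc_pwm.background)
    model = build_profile(pwm)
    model.slack = slack
    model = calibrate_threshold(model, alignment)
    all_ups = regmod.extract_upstream(genome, models, operon_level=False)
    hits = scan(model, genome, models, all_ups, de_calls=calls)
    hits = filter_hits(hits, models, de_calls=calls)
    report = classify_and_report(hits, all_ups, models)
    return PipelineResult(
        de_calls=calls,
        up_genes=up_genes,
        gene_models=models,
        upstream_regions=all_ups,
        alignment=alignment,
        pwm=pwm,
        consensus=consensus(pwm),
        model=model,
        hits=hits,
        report=report,
        params=dict(width=width, restarts=restarts, seed=seed, slack=slack),
    )


def site_recovery_stats(
    hits: list[CreHit],
    planted_intervals: list[tuple[int, int]],
    upstream_regions: list[UpstreamRegion],
    min_overlap: int | None = None,
    width: int = 16,
) -> tuple[float, float]:
    """(precision, recall) of kept upstream-context hits against planted sites.

    A hit matches a planted site when their intervals overlap by at least half
    the motif width (``min_overlap`` overrides), the standard site-level
    criterion in binding-site benchmarking — it tolerates the ±1 phase
    indeterminacy of degenerate-edged motifs without crediting unrelated
    windows.
    """
    if min_overlap is None:
        min_overlap = width // 2

    def in_upstream(h: CreHit) -> bool:
        return any(
            r.contig == h.contig and r.start0 <= h.midpoint < r.end0
            for r in upstream_regions
        )

    kept_up = [h for h in hits if h.status == "kept" and in_upstream(h)]

    def overlaps(h: CreHit, iv: tuple[int, int]) -> bool:
        return min(h.end0, iv[1]) - max(h.start0, iv[0]) >= min_overlap

    if not planted_intervals:
        return (0.0 if kept_up else 1.0), 1.0
    tp = sum(1 for h in kept_up if any(overlaps(h, iv) for iv in planted_intervals))
    recall = sum(
        1 for iv in planted_intervals if any(overlaps(h, iv) for h in kept_up)
    ) / len(planted_intervals)
    precision = tp / len(kept_up) if kept_up else 0.0
    return precision, recall
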