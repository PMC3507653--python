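"""Expression-matrix normalisation, fold changes and differential-expression calls.

The experimental design is a two-strain comparison (wild type vs a *ccpA*
inactivation mutant) sampled across fermentation phases — middle (M) and late
(L) exponential growth, the acidogenesis/solventogenesis transition (T) and
stationary phase (S), optionally with post-glucose-depletion points S2/S3.
Differential expression is a pure fold-change criterion: a gene is called up
at a phase when mutant/wild-type ≥ 2 and down when ≤ 1/2 (thresholds
inclusive, reciprocal rule by design since only the 2-fold cut-off is given
for either direction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage


class SampleKey(NamedTuple):
    """Identifies one array: (strain, growth phase, technical replicate)."""

    strain: str
    phase: str
    replicate: int

    def label(self, delimiter: str = "|") -> str:
        return f"{self.strain}{delimiter}{self.phase}{delimiter}{self.replicate}"


@dataclass
class ExpressionMatrix:
    """Per-gene signal intensities (positive reals) keyed by :class:`SampleKey`."""

    genes: list[str]
    samples: list[SampleKey]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.genes)} genes × {len(self.samples)} samples"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate (strain, phase, replicate) sample keys")
        if not np.all(self.values > 0):
            raise ValueError("all intensities must be > 0")

    def to_frame(self, delimiter: str = "|") -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.genes, name="gene"),
            columns=[s.label(delimiter) for s in self.samples],
        )

    def columns_for(self, strain: str, phase: str) -> list[int]:
        return [
            j
            for j, s in enumerate(self.samples)
            if s.strain == strain and s.phase == phase
        ]

    @property
    def strains(self) -> list[str]:
        return sorted({s.strain for s in self.samples})

    @property
    def phases(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.phase not in seen:
                seen.append(s.phase)
        return seen


@dataclass
class FoldChangeTable:
    """Per-gene, per-phase fold changes (numerator ÷ denominator condition)."""

    table: pd.DataFrame  # index: gene ids, columns: phases, values > 0

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def phases(self) -> list[str]:
        return list(self.table.columns)

    def fold(self, gene: str, phase: str) -> float:
        return float(self.table.at[gene, phase])


Direction = Literal["up", "down", "none"]


@dataclass(frozen=True)
class DeCall:
    gene: str
    phase: str
    direction: Direction
    fold: float


@dataclass
class CategorySummary:
    """Per-phase, per-COG-category counts of up/down-regulated genes.

    ``percent`` is 100 × (n_up + n_down) / total DE genes of the phase, the
    statistic quoted for category G (carbohydrate transport and metabolism).
    """

    counts: pd.DataFrame  # MultiIndex columns (phase, direction), index category
    totals: pd.Series  # per phase: total DE genes
    percent: pd.DataFrame  # index category, columns phase
    empty_phases: list[str] = field(default_factory=list)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the same intensity distribution.

    Each column's order statistics are replaced by the row-wise mean of the
    order statistics across all columns; ranks within a column are preserved
    and tied values share the mean of their target quantiles.  The operation
    is idempotent.
    """
    values = matrix.values
    n_genes, n_samples = values.shape
    if n_samples == 1:
        warnings.warn("single sample: quantile normalization is the identity")
        return ExpressionMatrix(matrix.genes, matrix.samples, values.copy())
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        # tie groups share the mean of their target quantiles
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        stops = np.concatenate((boundaries, [n_genes]))
        for a, b in zip(starts, stops):
            out[order[a:b], j] = target[a:b].mean()
    return ExpressionMatrix(matrix.genes, matrix.samples, out)


_AGGREGATES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "median": lambda a: np.median(a, axis=1),
    "mean": lambda a: np.mean(a, axis=1),
}


def _condition_values(
    matrix: ExpressionMatrix, strain: str, phase: str
) -> np.ndarray:
    cols = matrix.columns_for(strain, phase)
    if not cols:
        raise ValueError(f"missing condition: strain={strain!r}, phase={phase!r}")
    return matrix.values[:, cols]


def fold_changes(
    matrix: ExpressionMatrix,
    numerator: tuple[str, Sequence[str]],
    denominator: tuple[str, Sequence[str]],
    aggregate: Literal["median", "mean"] = "median",
) -> FoldChangeTable:
    """Per-gene fold change: aggregate(numerator replicates) ÷ aggregate(denominator).

    ``numerator`` and ``denominator`` are ``(strain, phases)`` pairs.  When the
    phase sets match, ratios are taken phase against the same phase (the
    mutant-vs-wild-type contrast); a single denominator phase is broadcast
    against every numerator phase (the glucose-depletion contrast, e.g. S2 and
    S3 each against S within the wild type).  Technical replicates are
    combined by the ``aggregate`` statistic (median by default, robust to
    single-probe outliers) before the ratio is formed.
    """
    num_strain, num_phases = numerator
    den_strain, den_phases = denominator
    num_phases = list(num_phases)
    den_phases = list(den_phases)
    agg = _AGGREGATES[aggregate]
    cols = {}
    for phase in num_phases:
        if phase in den_phases:
            den_phase = phase
        elif len(den_phases) == 1:
            den_phase = den_phases[0]
        else:
            raise ValueError(
                f"ambiguous denominator for phase {phase!r}: {den_phases}"
            )
        num = agg(_condition_values(matrix, num_strain, phase))
        den = agg(_condition_values(matrix, den_strain, den_phase))
        cols[phase] = num / den
    table = pd.DataFrame(cols, index=pd.Index(matrix.genes, name="gene"))
    return FoldChangeTable(table)


def classify_de(table: FoldChangeTable, up_threshold: float = 2.0) -> list[DeCall]:
    """Call each gene/phase up (fold ≥ threshold), down (≤ 1/threshold) or none.

    Both thresholds are inclusive, and the down cut-off is the reciprocal of
    the up cut-off, so the classification is symmetric under fold → 1/fold.
    """
    if up_threshold <= 1:
        raise ValueError("up_threshold must be > 1")
    down_threshold = 1.0 / up_threshold
    calls = []
    for phase in table.phases:
        col = table.table[phase]
        for gene, fold in col.items():
            if fold >= up_threshold:
                direction: Direction = "up"
            elif fold <= down_threshold:
                direction = "down"
            else:
                direction = "none"
            calls.append(DeCall(gene=gene, phase=phase, direction=direction, fold=float(fold)))
    return calls


NOT_IN_COGS = "Not in COGs"


def category_summary(
    calls: Iterable[DeCall],
    cog_map: dict[str, str],
    de_totals: dict[str, int] | None = None,
) -> CategorySummary:
    """Tabulate up/down-regulated genes per COG functional category and phase.

    Genes absent from ``cog_map`` are pooled under ``"Not in COGs"``.  The
    per-category percentage is taken over all differentially expressed genes
    of the phase (up + down); phases with no DE calls report 0% and are
    flagged in ``empty_phases``.

    When genes carry multiple COG letters the per-category rows double-count
    them, so the column sums exceed the number of unique DE genes; pass the
    unique-gene counts as ``de_totals`` (phase → count) to compute percentages
    on the correct denominator.  Without the override, totals are the column
    sums — exact whenever each gene has one category.
    """
    rows: dict[tuple[str, str], dict[str, int]] = {}
    phases: list[str] = []
    for call in calls:
        if call.phase not in phases:
            phases.append(call.phase)
        if call.direction == "none":
            continue
        cat = cog_map.get(call.gene, NOT_IN_COGS)
        key = (cat, call.phase)
        rows.setdefault(key, {"up": 0, "down": 0})[call.direction] += 1
    categories = sorted({cat for cat, _ in rows})
    columns = pd.MultiIndex.from_product([phases, ["up", "down"]], names=["phase", "direction"])
    counts = pd.DataFrame(0, index=pd.Index(categories, name="category"), columns=columns)
    for (cat, phase), c in rows.items():
        counts.at[cat, (phase, "up")] = c["up"]
        counts.at[cat, (phase, "down")] = c["down"]
    if de_totals is None:
        totals = pd.Series(
            {phase: int(counts[phase].to_numpy().sum()) for phase in phases},
            name="total_de",
        )
    else:
        totals = pd.Series(
            {phase: int(de_totals[phase]) for phase in phases}, name="total_de"
        )
    percent = pd.DataFrame(index=counts.index, columns=phases, dtype=float)
    empty = []
    for phase in phases:
        total = totals[phase]
        per_cat = counts[(phase, "up")] + counts[(phase, "down")]
        if total == 0:
            percent[phase] = 0.0
            empty.append(phase)
        else:
            percent[phase] = 100.0 * per_cat / total
    return CategorySummary(counts=counts, totals=totals, percent=percent, empty_phases=empty)


@dataclass
class Dendrogram:
    """Average-linkage tree: leaf labels plus a scipy-format merge matrix."""

    labels: list[str]
    merges: np.ndarray  # scipy linkage matrix, heights = 1 - mean pairwise r


def correlation_distance(profiles: np.ndarray) -> np.ndarray:
    """Condensed 1 − Pearson-r distances; zero-variance rows sit at distance 1."""
    n = profiles.shape[0]
    sd = profiles.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant profile(s): distance set to 1")
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    norms[constant] = 1.0
    unit = centered / norms[:, None]
    corr = unit @ unit.T
    dist = 1.0 - corr
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    iu = np.triu_indices(n, k=1)
    return np.maximum(dist[iu], 0.0)


def cluster_profiles(log_ratios: pd.DataFrame) -> Dendrogram:
    """Agglomerative average-linkage clustering of expression profiles.

    Distance is 1 − Pearson correlation across conditions.  Rows are sorted
    lexicographically by gene id before linkage so that equal-distance merges
    resolve deterministically.
    """
    if log_ratios.shape[0] < 2:
        raise ValueError("need at least 2 genes to cluster")
    if log_ratios.isna().any().any():
        raise ValueError("missing values in profile matrix")
    ordered = log_ratios.sort_index()
    condensed = correlation_distance(ordered.to_numpy(dtype=float))
    merges = linkage(condensed, method="average")
    return Dendrogram(labels=list(ordered.index), merges=merges)


def timecourse_profile(
    matrix: ExpressionMatrix,
    strain: str,
    reference_phase: str = "M",
    aggregate: Literal["median", "mean"] = "median",
) -> FoldChangeTable:
    """Within-strain expression ratios of every phase to a reference phase.

    This is the time-course view used for sporulation-gene profiles: each
    gene's trajectory relative to its level at the first (middle-exponential)
    time point.
    """
    phases = [s.phase for s in matrix.samples if s.strain == strain]
    if reference_phase not in phases:
        raise ValueError(f"reference phase {reference_phase!r} missing for strain {strain!r}")
    uniq: list[str] = []
    for p in phases:
        if p not in uniq:
            uniq.append(p)
    agg = _AGGREGATES[aggregate]
    ref = agg(_condition_values(matrix, strain, reference_phase))
    cols = {
        phase: agg(_condition_values(matrix, strain, phase)) / ref for phase in uniq
    }
    table = pd.DataFrame(cols, index=pd.Index(matrix.genes, name="gene"))
    return FoldChangeTable(table)
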