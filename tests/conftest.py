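import numpy as np
import pytest

from creregulon.expression import ExpressionMatrix, SampleKey
from creregulon.io_formats import FeatureRecord, SequenceRecord
from creregulon.regions import GeneModel


@pytest.fixture
def toy_matrix():
    """3 genes × 2 samples, the hand-computable quantile-normalization case."""
    return ExpressionMatrix(
        genes=["g1", "g2", "g3"],
        samples=[SampleKey("824WT", "M", 1), SampleKey("824WT", "M", 2)],
        values=np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]),
    )


def make_gene(feature_id, start0, end0, strand="+", contig="c1", **attrs):
    return FeatureRecord(
        contig=contig,
        start0=start0,
        end0=end0,
        strand=strand,
        feature_id=feature_id,
        feature_type="gene",
        attributes=attrs,
    )


def make_model(feature_id, start0, end0, strand="+", contig="c1", operon_id="", lead=True, **attrs):
    return GeneModel(
        contig=contig,
        start0=start0,
        end0=end0,
        strand=strand,
        feature_id=feature_id,
        feature_type="gene",
        attributes=attrs,
        operon_id=operon_id or feature_id,
        is_operon_lead=lead,
    )


@pytest.fixture
def small_genome():
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
    return SequenceRecord(id="c1", sequence=seq)
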