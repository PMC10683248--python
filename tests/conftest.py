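import numpy as np
import pandas as pd
import pytest

from mmis import (
    AnnotationField,
    AnnotationSchema,
    AnnotationSources,
    GeneRecord,
    GeneRegistry,
)


@pytest.fixture
def three_gene_registry() -> GeneRegistry:
    """One gene per category on distinct contigs, hand-specified intervals."""
    return GeneRegistry(
        [
            GeneRecord(
                symbol="MTG1",
                chromosome="chrM",
                start=100,
                end=1000,
                strand="+",
                category="mt_protein_coding",
                mane_transcript="MTG1.t1",
                all_transcripts=("MTG1.t1",),
            ),
            GeneRecord(
                symbol="NUC1",
                chromosome="chr1",
                start=5000,
                end=9000,
                strand="-",
                category="disease_nuclear",
                mane_transcript="NUC1.t2",
                all_transcripts=("NUC1.t1", "NUC1.t2"),
            ),
            GeneRecord(
                symbol="LOC1",
                chromosome="chr2",
                start=200,
                end=450,
                strand="+",
                category="mito_localized_nuclear",
                mane_transcript="LOC1.t1",
                all_transcripts=("LOC1.t1", "LOC1.t3"),
            ),
        ]
    )


@pytest.fixture
def tiny_schema() -> AnnotationSchema:
    """Three fields, one per level, covering all three dtypes."""
    return AnnotationSchema(
        [
            AnnotationField("sift_like", "predictor_score", "continuous", "variant"),
            AnnotationField("expressed", "tissue_expression", "boolean", "gene"),
            AnnotationField("exon_count", "basic", "integer", "transcript"),
        ]
    )


@pytest.fixture
def tiny_sources(three_gene_registry) -> AnnotationSources:
    """Hand-joined source tables matching the tiny schema and registry."""
    return AnnotationSources(
        variant=pd.DataFrame(
            [
                {
                    "chromosome": "chrM",
                    "position": 150,
                    "ref": "A",
                    "alt": "G",
                    "consequence": "missense_variant",
                    "sift_like": "0.93",
                }
            ]
        ),
        gene=pd.DataFrame([{"gene": "MTG1", "expressed": "1"}]),
        transcript=pd.DataFrame(
            [{"transcript": "MTG1.t1", "gene": "MTG1", "exon_count": "4"}]
        ),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231127)
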