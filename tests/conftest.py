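import numpy as np
import pandas as pd
import pytest

from spongefunc.io_formats import AsvTable, OrfAnnotation, TranscriptCounts


@pytest.fixture
def toy_asv_table() -> AsvTable:
    counts = pd.DataFrame(
        [[10, 5, 5, 0], [2, 2, 4, 12], [7, 0, 3, 10]],
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        columns=pd.Index(["a1", "a2", "a3", "a4"], name="asv_id"),
    )
    taxonomy = pd.DataFrame(
        {
            "domain": ["Bacteria"] * 4,
            "phylum": ["Chloroflexi", "Chloroflexi", "Proteobacteria", "Poribacteria"],
            "class": ["Dehalococcoidia", "Dehalococcoidia", "Gamma", "Omni"],
            "order": ["o1", "o1", "o3", "o4"],
            "family": ["f1", "f1", "f3", "f4"],
            "genus": ["g1", "g1", "g2", np.nan],
        },
        index=pd.Index(["a1", "a2", "a3", "a4"], name="asv_id"),
    )
    metadata = pd.DataFrame(
        {
            "species": ["sp1", "sp1", "sp2"],
            "location": ["L1", "L2", "L1"],
            "habitat": ["deep", "deep", "shallow"],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return AsvTable(counts=counts, taxonomy=taxonomy, metadata=metadata)


@pytest.fixture
def toy_transcriptome() -> tuple[TranscriptCounts, OrfAnnotation]:
    tc = TranscriptCounts(
        expected_counts=pd.DataFrame(
            {"s1": [100.0, 40.0, 0.0], "s2": [50.0, 60.0, 30.0]},
            index=pd.Index(["t1", "t2", "t3"], name="transcript_id"),
        )
    )
    ann = OrfAnnotation(
        records=pd.DataFrame(
            {
                "transcript_id": ["t1", "t1", "t2", "t3"],
                "peptide_id": ["p1", "p2", "p3", "p4"],
                "peptide_length": [100, 300, 200, 150],
                "ko": ["K00001", "K00002", "K00001", None],
                "taxon": [
                    "Bacteria;Chloroflexi;c;o;f;g",
                    "Bacteria;Proteobacteria;c;o;f;g",
                    "Bacteria;Chloroflexi;c;o;f;g",
                    None,
                ],
            }
        )
    )
    return tc, ann
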