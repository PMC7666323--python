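import numpy as np
import pytest

from gcprofiler.io import MutationRecord, SampleLabel
from gcprofiler.signatures import synthetic_catalog
from gcprofiler.simulate import STUDY_CELLS


@pytest.fixture(scope="session")
def catalog():
    return synthetic_catalog()


@pytest.fixture(scope="session")
def study_labels():
    """Clinical labels laid out on the study's sequenced-case cross-table."""
    labels = []
    i = 0
    for (lauren, mol), n in sorted(STUDY_CELLS.items()):
        for _ in range(n):
            i += 1
            labels.append(SampleLabel(f"S{i:04d}", lauren, mol))
    return labels


@pytest.fixture
def toy_records():
    """20 hand-written records across 3 samples and 4 genes.

    Hand tally of protein-altering events for cohort {S1, S2}:
      TP53: S1 missense@101, S1 nonsense@150, S2 missense@101      -> 3
      CDH1: S1 frameshift@7, S1 frameshift@7 (exact duplicate),
            S2 splice@88, S2 inframe@90                            -> 3
      KRAS: S2 missense@12                                          -> 1
      MUC4: none protein-altering (silent + noncoding only)         -> 0
    S3 carries events in all genes but is outside the cohort.
    """
    mk = MutationRecord
    return [
        mk("S1", "TP53", "missense", "17", 101, "C", "T", "ACA"),
        mk("S1", "TP53", "nonsense", "17", 150, "G", "A", "TGA"),
        mk("S2", "TP53", "missense", "17", 101, "C", "T", "ACA"),
        mk("S1", "TP53", "silent", "17", 200, "G", "A", "AGA"),
        mk("S1", "CDH1", "frameshift_indel", "16", 7, "A", "-", None),
        mk("S1", "CDH1", "frameshift_indel", "16", 7, "A", "-", None),  # dup
        mk("S2", "CDH1", "splice_site", "16", 88, "C", "G", "TCT"),
        mk("S2", "CDH1", "inframe_indel", "16", 90, "AGT", "A", None),
        mk("S2", "KRAS", "missense", "12", 12, "G", "T", "TGT"),
        mk("S1", "KRAS", "silent", "12", 40, "C", "T", "GCG"),
        mk("S1", "MUC4", "silent", "3", 5, "T", "C", "ATA"),
        mk("S2", "MUC4", "other_noncoding", "3", 9, "A", "G", "CAC"),
        mk("S3", "TP53", "missense", "17", 101, "C", "T", "ACA"),
        mk("S3", "TP53", "nonsense", "17", 155, "C", "A", "GCG"),
        mk("S3", "CDH1", "missense", "16", 30, "T", "G", "CTC"),
        mk("S3", "KRAS", "frameshift_indel", "12", 60, "G", "-", None),
        mk("S3", "KRAS", "missense", "12", 61, "G", "C", "AGA"),
        mk("S3", "MUC4", "missense", "3", 70, "C", "T", "GCT"),
        mk("S3", "MUC4", "splice_site", "3", 71, "G", "A", "TGG"),
        mk("S3", "MUC4", "silent", "3", 72, "A", "G", "CAC"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
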