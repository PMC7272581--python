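import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hlacapseq.reference import (
    AlleleName,
    AlleleReference,
    Locus,
    ReferenceSet,
)


def make_allele(
    locus=Locus.A,
    f1=1,
    f2=1,
    f3=1,
    exons=("ACGT", "TTGG"),
    exon_ids=(2, 3),
    flank5="",
    flank3="",
):
    """Hand-build an allele reference from explicit exon sequences."""
    seq = flank5
    table = []
    pos = len(flank5)
    for exon_id, exon_seq in zip(exon_ids, exons):
        table.append((exon_id, pos, pos + len(exon_seq)))
        seq += exon_seq
        pos += len(exon_seq)
    seq += flank3
    return AlleleReference(AlleleName(locus, f1, f2, f3), seq, tuple(table))


def make_truth(rows):
    """Truth table from (sample, locus, hap, allele, weight) tuples."""
    return pd.DataFrame(
        [
            {
                "sample_id": s,
                "locus": l,
                "haplotype_index": h,
                "allele": a,
                "true_relative_expression": w,
                "capture_bias": 1.0,
                "sampling_weight": w,
            }
            for s, l, h, a, w in rows
        ]
    )


@pytest.fixture(scope="session")
def class1_panel():
    from hlacapseq.simulate import synthesize_panel

    return synthesize_panel([Locus.A, Locus.B, Locus.C], 3, 3, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
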