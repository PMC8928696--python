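import numpy as np
import pandas as pd
import pytest

from cutdecon import simdata
from cutdecon.fragio import GenomeIndex


@pytest.fixture
def small_genome():
    return GenomeIndex.from_dict({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def tiny_sim():
    """A small, fast simulation: 30-kb chromosome, sparse features."""
    cfg = simdata.SimConfig(
        genome=GenomeIndex.from_dict({"chrS": 30_000}),
        n_pol_features=2,
        n_k27_features=1,
        k27_feature_width=800.0,
        n_fragments=3_000,
        seed=11,
    )
    truth = simdata.simulate_truth(cfg)
    frags, table = simdata.sample_fragments(cfg, truth)
    return cfg, truth, frags, table


def bp_precision_recall(peaks, label, intervals, genome_length):
    """Base-pair-level precision and recall of labelled peaks against
    ground-truth intervals."""
    called = np.zeros(genome_length, dtype=bool)
    true = np.zeros(genome_length, dtype=bool)
    for pk in peaks:
        if pk.target == label:
            called[pk.start:pk.end] = True
    for _, row in intervals.iterrows():
        true[max(0, row["start"]):row["end"]] = True
    tp = (called & true).sum()
    precision = tp / max(called.sum(), 1)
    recall = tp / max(true.sum(), 1)
    return precision, recall


def frags_df(rows):
    """Build a fragment DataFrame from (chrom, start, end[, barcode[, count]])."""
    out = []
    for r in rows:
        chrom, start, end = r[:3]
        barcode = r[3] if len(r) > 3 else ""
        count = r[4] if len(r) > 4 else 1
        out.append((chrom, start, end, barcode, count))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "barcode", "count"])
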