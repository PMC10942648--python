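import numpy as np
import pytest

from mstarr.datamodel import CountMatrix, GenomicWindow, SampleMeta
from mstarr.qc import detection_filter, repeatability_filter
from mstarr.simulate import simulate_mstarr_experiment


def make_samples(n_pairs_per_cond: int = 6, treatment: str = "baseline"):
    """One treatment's sample sheet: n pairs per methylation condition."""
    out = []
    for methyl in ("unmethylated", "methylated"):
        for r in range(1, n_pairs_per_cond + 1):
            pid = f"{treatment}_{methyl[0]}{r}"
            for mol in ("DNA", "RNA"):
                out.append(
                    SampleMeta(f"{pid}_{mol}", mol, methyl, treatment, pid,
                               library_size=1_000_000)
                )
    return out


@pytest.fixture(scope="session")
def small_experiment():
    """2000-window mixed experiment with 10% active, half MD."""
    return simulate_mstarr_experiment(
        2000, active_fraction=0.1, md_fraction=0.5, effect_size_log2=2.0, seed=11
    )


@pytest.fixture(scope="session")
def analyzed_experiment(small_experiment):
    cm, truth = small_experiment
    ana = cm.subset_windows(detection_filter(cm))
    ana = ana.subset_windows(repeatability_filter(ana))
    return ana, truth.set_index("window_id").loc[ana.window_ids]


def toy_count_matrix(counts, n_pairs=3, treatment="baseline"):
    counts = np.asarray(counts)
    samples = make_samples(n_pairs, treatment)
    windows = [
        GenomicWindow("chrT", i * 600, (i + 1) * 600) for i in range(counts.shape[0])
    ]
    return CountMatrix(windows=windows, samples=samples, counts=counts)
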