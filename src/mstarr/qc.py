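"""Window-inclusion and sample-QC rules.

Three rules gate the per-window model fit, applied per treatment condition:

* detection: a window needs non-zero DNA input in at least ``min_dna``
  replicates of *each* methylation condition, and non-zero RNA in at least
  ``min_rna`` replicates of *either* methylation condition;
* repeatability: DNA abundance must be repeatable across replicate
  libraries — a window is dropped when >= 25% of its pairwise DNA
  differences fall outside the central 90% of the pooled difference
  distribution across all windows;
* sample QC: libraries with an outlying proportion of zero counts over
  testable windows are reported (with their pair partner) for removal.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, SampleMeta, meta_frame


def _single_treatment(samples: Sequence[SampleMeta]) -> None:
    treatments = {s.treatment for s in samples}
    if len(treatments) > 1:
        raise ValueError(
            f"filter applies per treatment; got samples from {sorted(treatments)}"
        )


def detection_filter(
    cm: CountMatrix,
    min_dna_per_methcond: int = 3,
    min_rna_either_methcond: int = 3,
) -> np.ndarray:
    """Boolean mask of windows passing the detection rule (one treatment)."""
    _single_treatment(cm.samples)
    meta = meta_frame(cm.samples)
    nz = cm.counts > 0

    def n_nonzero(molecule: str, methylation: str) -> np.ndarray:
        sel = ((meta["molecule"] == molecule) & (meta["methylation"] == methylation)).values
        return nz[:, sel].sum(axis=1)

    for methyl in ("methylated", "unmethylated"):
        if not ((meta["molecule"] == "DNA") & (meta["methylation"] == methyl)).any():
            raise ValueError(f"no DNA samples in {methyl} condition")

    dna_ok = (n_nonzero("DNA", "methylated") >= min_dna_per_methcond) & (
        n_nonzero("DNA", "unmethylated") >= min_dna_per_methcond
    )
    rna_ok = (n_nonzero("RNA", "methylated") >= min_rna_either_methcond) | (
        n_nonzero("RNA", "unmethylated") >= min_rna_either_methcond
    )
    return dna_ok & rna_ok


def repeatability_filter(
    cm: CountMatrix,
    pair_frac: float = 0.25,
    central_quantile: float = 0.90,
    scale: str = "log2cpm",
) -> np.ndarray:
    """Boolean mask of windows retained by the DNA-repeatability rule.

    All pairwise differences of DNA abundance are pooled across windows into
    one reference distribution; the central ``central_quantile`` interval
    (inclusive) defines "inside". A window is removed iff at least
    ``pair_frac`` of its own pairs fall strictly outside.

    ``scale`` is "log2cpm" (library-size adjusted, default) or "counts".
    """
    dna_idx = [i for i, s in enumerate(cm.samples) if s.molecule == "DNA"]
    if len(dna_idx) < 2:
        raise ValueError("repeatability filter needs >= 2 DNA samples")
    x = cm.counts[:, dna_idx].astype(float)
    if scale == "log2cpm":
        lib = cm.library_sizes()[dna_idx]
        x = np.log2((x + 0.5) / (lib + 1.0) * 1e6)
    elif scale != "counts":
        raise ValueError(f"unknown scale {scale!r}")

    pairs = list(itertools.combinations(range(x.shape[1]), 2))
    diffs = np.stack([x[:, i] - x[:, j] for i, j in pairs], axis=1)  # windows x pairs
    alpha = (1.0 - central_quantile) / 2.0
    q_lo, q_hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    outside = (diffs < q_lo) | (diffs > q_hi)  # boundary values are inside
    frac_outside = outside.mean(axis=1)
    return frac_outside < pair_frac  # removed iff >= pair_frac outside


def sample_qc_report(cm: CountMatrix, k: float = 5.0) -> pd.DataFrame:
    """Per-sample zero-count proportions with outlier flags.

    A sample is flagged when its zero proportion exceeds
    median + k * MAD across samples; the paired library of a flagged sample
    is listed for removal too (the assay is uninterpretable unpaired).
    Flagging is a recommendation — nothing is removed automatically.
    """
    zero_prop = (cm.counts == 0).mean(axis=0)
    med = float(np.median(zero_prop))
    mad = float(np.median(np.abs(zero_prop - med)))
    threshold = med + k * mad if np.isfinite(k) else np.inf
    flagged = zero_prop > threshold

    partner_of = {}
    by_pair: dict[str, list[str]] = {}
    for s in cm.samples:
        by_pair.setdefault(s.pair_id, []).append(s.sample_id)
    for members in by_pair.values():
        if len(members) == 2:
            partner_of[members[0]] = members[1]
            partner_of[members[1]] = members[0]

    remove = set()
    for s, fl in zip(cm.samples, flagged):
        if fl:
            remove.add(s.sample_id)
            if s.sample_id in partner_of:
                remove.add(partner_of[s.sample_id])

    return pd.DataFrame(
        {
            "sample_id": cm.sample_ids,
            "zero_proportion": zero_prop,
            "library_size": cm.library_sizes().astype(int),
            "flagged": flagged,
            "recommend_removal": [s in remove for s in cm.sample_ids],
        }
    )
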