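"""Genome segmentation into fixed windows, fragment counting, rarefaction.

The assay quantifies reporter fragments per 600-bp non-overlapping genomic
window; a fragment overlapping a window by at least 1 bp counts toward it,
so a fragment spanning a window boundary increments every window it touches.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, GenomicWindow, SampleMeta

log = logging.getLogger("mstarr")

DEFAULT_WIDTH = 600


def segment_genome(
    chrom_sizes: Mapping[str, int], width: int = DEFAULT_WIDTH
) -> list[GenomicWindow]:
    """Tile each chromosome with non-overlapping ``width``-bp windows.

    The final window of a chromosome whose length is not a multiple of
    ``width`` is retained and flagged ``partial``.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    out: list[GenomicWindow] = []
    for chrom, length in chrom_sizes.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        starts = range(0, length, width)
        for s in starts:
            e = min(s + width, length)
            out.append(GenomicWindow(chrom, s, e, partial=(e - s < width)))
    return out


def count_fragments(
    fragments: pd.DataFrame,
    windows: Sequence[GenomicWindow],
    samples: Sequence[SampleMeta],
) -> CountMatrix:
    """Count fragments overlapping each window, per sample.

    ``fragments`` holds columns chrom/start/end/sample_id. Any-overlap rule:
    cell (w, s) = number of fragments of sample s overlapping window w by
    >= 1 bp; a fragment spanning k windows increments all k. Fragments on
    chromosomes absent from the window set are tallied and logged.
    """
    sample_idx = {s.sample_id: i for i, s in enumerate(samples)}
    counts = np.zeros((len(windows), len(samples)), dtype=np.int64)

    # group windows per chromosome; within a chromosome they are sorted,
    # non-overlapping tiles, so overlap reduces to a searchsorted range
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, ([], [], []))  # type: ignore[arg-type]
    tmp: dict[str, list[list[int]]] = {c: [[], [], []] for c in by_chrom}
    for i, w in enumerate(windows):
        tmp[w.chrom][0].append(w.start)
        tmp[w.chrom][1].append(w.end)
        tmp[w.chrom][2].append(i)
    for c, (ss, ee, ii) in tmp.items():
        order = np.argsort(ss)
        by_chrom[c] = (
            np.asarray(ss)[order],
            np.asarray(ee)[order],
            np.asarray(ii)[order],
        )

    skipped = 0
    for row in fragments.itertuples(index=False):
        if row.end <= row.start:
            raise ValueError(f"invalid fragment [{row.start},{row.end})")
        if row.sample_id not in sample_idx:
            raise ValueError(f"fragment sample {row.sample_id!r} not in metadata")
        if row.chrom not in by_chrom:
            skipped += 1
            continue
        starts, ends, idx = by_chrom[row.chrom]
        # windows with start < frag.end and end > frag.start
        lo = np.searchsorted(ends, row.start, side="right")
        hi = np.searchsorted(starts, row.end, side="left")
        if hi > lo:
            counts[idx[lo:hi], sample_idx[row.sample_id]] += 1
        else:
            skipped += 1
    if skipped:
        log.warning("%d fragments overlapped no window", skipped)
    return CountMatrix(windows=list(windows), samples=list(samples), counts=counts)


def read_fragment_bed(path, sample_id: str | None = None) -> pd.DataFrame:
    """BED4 fragment file; name column = sample_id unless given explicitly."""
    from .io import _is_header

    rows = []
    with open(path) as fh:
        for line in fh:
            if _is_header(line):
                continue
            p = line.rstrip("\n").split("\t")
            sid = sample_id if sample_id is not None else p[3]
            rows.append((p[0], int(p[1]), int(p[2]), sid))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample_id"])


def rarefaction_curve(
    counts: CountMatrix,
    fractions: Sequence[float],
    detection_rule: Callable[[CountMatrix], np.ndarray],
    seed: int = 0,
) -> pd.DataFrame:
    """Binomially thin counts at each depth fraction and re-apply detection.

    Thinning each cell with probability f is the count-level equivalent of
    subsampling the underlying reads. Fraction 1.0 reproduces the unthinned
    analysis exactly. Returns a table fraction -> surviving windows.
    """
    fracs = list(fractions)
    if any(f <= 0 or f > 1 for f in fracs):
        raise ValueError("fractions must lie in (0, 1]")
    if sorted(fracs) != fracs:
        raise ValueError("fractions must be sorted ascending")
    rng = np.random.default_rng(seed)
    rows = []
    for f in fracs:
        if f == 1.0:
            thinned = counts
        else:
            thin = rng.binomial(counts.counts, f)
            thinned = CountMatrix(counts.windows, counts.samples, thin)
        mask = detection_rule(thinned)
        rows.append({"fraction": f, "n_windows": int(np.sum(mask))})
    return pd.DataFrame(rows)
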