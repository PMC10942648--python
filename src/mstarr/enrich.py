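"""Interval/point overlap and Fisher's-exact enrichment.

All containment uses 0-based half-open coordinates: a CpG at position 600
belongs to window [600, 1200), not [0, 600).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AnnotationSet, GenomicWindow

log = logging.getLogger("mstarr")

Z975 = 1.959963984540054


@dataclass
class EnrichmentResult:
    """2x2 overlap table with log2 odds ratio, Woolf 95% CI, exact p."""

    table: tuple[int, int, int, int]  # a=both, b=query only, c=subject only, d=neither
    log2_or: float
    ci95: tuple[float, float]
    p: float
    degenerate: bool = False


def windows_contain_points(
    windows: Sequence[GenomicWindow], points: pd.DataFrame
) -> np.ndarray:
    """Boolean per window: contains >= 1 of the given CpG positions."""
    member = np.zeros(len(windows), dtype=bool)
    idx = _point_window_index(windows, points)
    member[idx[idx >= 0]] = True
    return member


def _point_window_index(
    windows: Sequence[GenomicWindow], points: pd.DataFrame
) -> np.ndarray:
    """For each point, the index of its containing window (-1 if none)."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for c in {w.chrom for w in windows}:
        ws = [(w.start, w.end, i) for i, w in enumerate(windows) if w.chrom == c]
        ws.sort()
        arr = np.array(ws)
        by_chrom[c] = (arr[:, 0], arr[:, 1], arr[:, 2])
    out = np.full(len(points), -1, dtype=int)
    for k, row in enumerate(points.itertuples(index=False)):
        if row.chrom not in by_chrom:
            continue
        starts, ends, idx = by_chrom[row.chrom]
        j = np.searchsorted(starts, row.pos, side="right") - 1
        if j >= 0 and row.pos < ends[j]:
            out[k] = idx[j]
    return out


def windows_overlap_intervals(
    windows: Sequence[GenomicWindow], intervals: pd.DataFrame
) -> np.ndarray:
    """Boolean per window: overlaps >= 1 interval by >= 1 bp."""
    member = np.zeros(len(windows), dtype=bool)
    for c in {w.chrom for w in windows}:
        sub = intervals[intervals["chrom"] == c]
        widx = [i for i, w in enumerate(windows) if w.chrom == c]
        if len(sub) == 0 or not widx:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        cummax_end = np.maximum.accumulate(ends)
        for i in widx:
            w = windows[i]
            hi = np.searchsorted(starts, w.end, side="left")
            if hi > 0 and cummax_end[hi - 1] > w.start:
                member[i] = True
    return member


def annotation_membership(
    ann: AnnotationSet, universe: Sequence[GenomicWindow]
) -> np.ndarray:
    if ann.kind == "points":
        return windows_contain_points(universe, ann.records)
    return windows_overlap_intervals(universe, ann.records)


def overlap_table(
    query: np.ndarray | AnnotationSet,
    subject: np.ndarray | AnnotationSet,
    universe: Sequence[GenomicWindow],
) -> tuple[int, int, int, int]:
    """2x2 membership table over an explicit universe of windows.

    a = in both, b = query only, c = subject only, d = neither; cell sums
    always equal |universe|.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    q = query if isinstance(query, np.ndarray) else annotation_membership(query, universe)
    s = subject if isinstance(subject, np.ndarray) else annotation_membership(subject, universe)
    q = np.asarray(q, bool)
    s = np.asarray(s, bool)
    if q.shape != (len(universe),) or s.shape != (len(universe),):
        raise ValueError("membership vectors must match the universe")
    a = int((q & s).sum())
    b = int((q & ~s).sum())
    c = int((~q & s).sum())
    d = int((~q & ~s).sum())
    return (a, b, c, d)


def fisher_exact(table: tuple[int, int, int, int]) -> EnrichmentResult:
    """Exact two-sided Fisher test with a Woolf confidence interval.

    p sums hypergeometric outcomes with probability <= the observed
    table's. The point log2(OR) is the sample odds ratio; when any cell is
    zero the Haldane-Anscombe 0.5 correction is applied to the estimate
    and the CI. A zero row or column margin leaves the OR undefined
    (flagged degenerate, p = 1).
    """
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return EnrichmentResult(table, np.nan, (np.nan, np.nan), 1.0, degenerate=True)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = float(a), float(b), float(c), float(d)
    log_or = np.log(a_ * d_ / (b_ * c_))
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    to_log2 = 1.0 / np.log(2.0)
    return EnrichmentResult(
        table=table,
        log2_or=float(log_or * to_log2),
        ci95=(float((log_or - Z975 * se) * to_log2), float((log_or + Z975 * se) * to_log2)),
        p=float(p),
    )


def ela_harness(
    study_sets: dict[str, pd.DataFrame],
    array_backgrounds: dict[str, pd.DataFrame],
    study_background: dict[str, str],
    windows: Sequence[GenomicWindow],
    regulatory: np.ndarray,
    methylation_dependent: np.ndarray,
) -> pd.DataFrame:
    """Per-study CpG enrichment in regulatory and MD windows.

    For each study (a chrom/pos CpG list) against its declared array
    background: test 1 asks whether study CpGs are enriched among CpGs
    falling in regulatory windows; test 2 restricts the universe to CpGs
    inside regulatory windows and asks for enrichment in
    methylation-dependent windows. Study CpGs absent from their background
    are dropped with a warning count.
    """
    reg = np.asarray(regulatory, bool)
    md = np.asarray(methylation_dependent, bool)
    rows = []
    for study, cpgs in study_sets.items():
        if len(cpgs) == 0:
            raise ValueError(f"study {study!r} has an empty CpG set")
        bg_name = study_background[study]
        bg = array_backgrounds[bg_name]
        bg_keys = set(zip(bg["chrom"], bg["pos"]))
        in_bg = np.array([(c, p) in bg_keys for c, p in zip(cpgs["chrom"], cpgs["pos"])])
        if (~in_bg).any():
            log.warning("study %s: %d CpGs absent from background %s",
                        study, int((~in_bg).sum()), bg_name)
        study_keys = set(
            zip(cpgs["chrom"].to_numpy()[in_bg], cpgs["pos"].to_numpy()[in_bg])
        )
        widx = _point_window_index(windows, bg)
        is_study = np.array([(c, p) in study_keys for c, p in zip(bg["chrom"], bg["pos"])])
        in_reg = (widx >= 0) & reg[np.maximum(widx, 0)]
        in_md = (widx >= 0) & md[np.maximum(widx, 0)]

        res1 = fisher_exact(_table_from_masks(is_study, in_reg))
        within = in_reg
        if within.sum() > 0:
            res2 = fisher_exact(
                _table_from_masks(is_study[within], in_md[within])
            )
        else:
            res2 = EnrichmentResult((0, 0, 0, 0), np.nan, (np.nan, np.nan), 1.0, True)
        for test, res in (("regulatory", res1), ("md_given_regulatory", res2)):
            rows.append({"study": study, "test": test, "a": res.table[0],
                         "b": res.table[1], "c": res.table[2], "d": res.table[3],
                         "log2_or": res.log2_or, "ci_low": res.ci95[0],
                         "ci_high": res.ci95[1], "p": res.p,
                         "degenerate": res.degenerate})
    return pd.DataFrame(rows)


def _table_from_masks(q: np.ndarray, s: np.ndarray) -> tuple[int, int, int, int]:
    return (
        int((q & s).sum()), int((q & ~s).sum()),
        int((~q & s).sum()), int((~q & ~s).sum()),
    )


def compare_result_sets(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    effect_field: str = "beta",
    flag_field: str = "regulatory",
) -> dict:
    """Cross-dataset concordance over the shared window universe.

    Fisher test of joint significance membership, plus the squared Pearson
    correlation of effect sizes over windows significant in both (reported
    NaN below 3 such windows). Result frames are indexed by window_id.
    """
    shared = results_a.index.intersection(results_b.index)
    if len(shared) == 0:
        raise ValueError("empty shared window universe")
    fa = results_a.loc[shared, flag_field].to_numpy(bool)
    fb = results_b.loc[shared, flag_field].to_numpy(bool)
    res = fisher_exact(_table_from_masks(fa, fb))
    both = fa & fb
    if both.sum() >= 3:
        ea = results_a.loc[shared, effect_field].to_numpy(float)[both]
        eb = results_b.loc[shared, effect_field].to_numpy(float)[both]
        r, p_r = stats.pearsonr(ea, eb)
        r2 = float(r**2)
    else:
        r2, p_r = np.nan, np.nan
    infinite = res.table[1] == 0 and res.table[2] == 0 and res.table[0] > 0
    return {
        "n_shared": int(len(shared)),
        "table": res.table,
        "log2_or": np.inf if infinite else res.log2_or,
        "ci95": res.ci95,
        "p": res.p,
        "degenerate": res.degenerate or infinite,
        "n_joint_significant": int(both.sum()),
        "r2": r2,
        "r2_p": p_r,
    }
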