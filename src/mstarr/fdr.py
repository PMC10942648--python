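"""Permutation-based empirical FDR with positive-beta subsampling.

Most windows in a reporter experiment show far more DNA input than RNA
output, so the observed p-value distribution is loaded with windows having
"significantly no" activity. A naive permutation null is therefore
miscalibrated. The remedy: restrict both the observed analysis set and
each permutation's null contribution to windows with a *positive*
RNA-vs-DNA coefficient, subsampling each permutation to N such windows
(N = the observed count).

Two permutation schemes feed two tests:
* molecule-label swaps (RNA/DNA within each replicate pair) null out the
  activity test;
* methylation-label reshuffles across pairs null out the
  methylation-dependence (interaction) test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .datamodel import CountMatrix, SampleMeta, validate_pairing
from . import model as _model

log = logging.getLogger("mstarr")


# ---------------------------------------------------------------- permutations

def _pair_ids(samples: Sequence[SampleMeta]) -> list[str]:
    seen: dict[str, None] = {}
    for s in samples:
        seen.setdefault(s.pair_id, None)
    return list(seen)


def permute_molecule_labels(
    samples: Sequence[SampleMeta], n_perm: int, seed: int
) -> np.ndarray:
    """Per-permutation swap plans: (n_perm, n_pairs) booleans.

    Each replicate pair independently swaps its DNA/RNA labels with
    probability 1/2. Applying a plan twice restores the original labels.

    Plans that leave a methylation condition's labels entirely unswapped
    (or entirely swapped) are redrawn: with few pairs such draws are not
    rare (2/2^k per condition) and they replay the observed statistic (up
    to sign) into the null rather than breaking it. The restriction is
    data-independent, so the null remains valid under exchangeability.
    """
    validate_pairing(list(samples))
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    pairs = _pair_ids(samples)
    meth_of = {s.pair_id: s.methylation for s in samples}
    groups = []
    for cond in ("unmethylated", "methylated"):
        idx = [i for i, p in enumerate(pairs) if meth_of[p] == cond]
        if len(idx) >= 2:
            groups.append(np.array(idx))
    rng = np.random.default_rng(seed)
    plans = np.empty((n_perm, len(pairs)), dtype=bool)
    for i in range(n_perm):
        while True:
            row = rng.random(len(pairs)) < 0.5
            if all(0 < row[g].sum() < len(g) for g in groups):
                plans[i] = row
                break
    return plans


def permute_methylation_labels(
    samples: Sequence[SampleMeta], n_perm: int, seed: int
) -> np.ndarray:
    """Per-permutation methylation assignment: (n_perm, n_pairs) booleans
    (True = methylated), preserving the original balance. Draws are
    independent across permutations (sampling with replacement from the
    space of balanced assignments; the identity is permitted)."""
    pairs = _pair_ids(samples)
    meth_of = {s.pair_id: s.methylation == "methylated" for s in samples}
    n_meth = sum(meth_of[p] for p in pairs)
    if n_meth == 0 or n_meth == len(pairs):
        raise ValueError("need both methylation conditions to permute")
    rng = np.random.default_rng(seed)
    plans = np.zeros((n_perm, len(pairs)), dtype=bool)
    for i in range(n_perm):
        chosen = rng.choice(len(pairs), size=n_meth, replace=False)
        plans[i, chosen] = True
    return plans


def _permuted_design(
    samples: Sequence[SampleMeta],
    molecule_swap: np.ndarray | None = None,
    methylation_plan: np.ndarray | None = None,
) -> np.ndarray:
    """Design matrix under permuted labels (None = observed labels)."""
    pairs = _pair_ids(samples)
    pair_index = {p: i for i, p in enumerate(pairs)}
    m = np.array([1.0 if s.methylation == "methylated" else 0.0 for s in samples])
    s_ = np.array([1.0 if s.molecule == "RNA" else 0.0 for s in samples])
    if molecule_swap is not None:
        flip = np.array([molecule_swap[pair_index[s.pair_id]] for s in samples])
        s_ = np.where(flip, 1.0 - s_, s_)
    if methylation_plan is not None:
        m = np.array(
            [1.0 if methylation_plan[pair_index[s.pair_id]] else 0.0 for s in samples]
        )
    return np.column_stack([np.ones_like(m), m, s_ * (1.0 - m), s_ * m])


# ------------------------------------------------------------- null ensembles

@dataclass
class NullEnsemble:
    """Pooled permutation p-values for one statistic.

    ``null_p[j]`` holds permutation j's (subsampled) null p-values and
    ``weights[j]`` the rescaling factor N/available applied when a
    permutation yields fewer than N positive-beta windows.
    """

    scheme: str  # "molecule_label" | "methylation_label"
    n_perm: int
    null_p: list[np.ndarray]
    weights: list[float]
    N: int
    seed: int


def build_null(
    perm_fits: Sequence[_model.ModelFits],
    statistic: str,
    N: int,
    seed: int,
    scheme: str = "molecule_label",
    selector_fits: Sequence[_model.ModelFits] | None = None,
) -> NullEnsemble:
    """Subsample each permutation's positive-beta windows to N and pool
    their p-values (activity or interaction statistic).

    The positive-beta selection comes from ``selector_fits`` (default: the
    permutation fits themselves). The interaction null re-uses the window
    sets selected under the molecule-label permutations — pass those fits
    as the selector with the same seed to reproduce the identical sets.

    Permutations with fewer than N positive-beta windows keep all of them,
    with their null counts rescaled by N/available; permutations with none
    contribute nothing (logged).
    """
    if statistic not in ("activity", "interaction"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if selector_fits is None:
        selector_fits = perm_fits
    rng = np.random.default_rng(seed)
    null_p: list[np.ndarray] = []
    weights: list[float] = []
    n_empty = 0
    for fits, sel in zip(perm_fits, selector_fits):
        pos = np.flatnonzero(sel.positive_beta)
        if pos.size == 0:
            n_empty += 1
            continue
        if pos.size > N:
            pos = rng.choice(pos, size=N, replace=False)
            w = 1.0
        else:
            w = N / pos.size
        p = (
            _model.activity_pvalue(fits)[pos]
            if statistic == "activity"
            else fits.p_int[pos]
        )
        p = p[np.isfinite(p)]
        null_p.append(p)
        weights.append(w)
    if n_empty:
        log.info("%d permutations contributed no positive-beta windows", n_empty)
    return NullEnsemble(
        scheme=scheme, n_perm=len(perm_fits), null_p=null_p, weights=weights,
        N=N, seed=seed,
    )


def empirical_fdr(p_obs: np.ndarray, null: NullEnsemble) -> np.ndarray:
    """Per-window empirical q-values.

    FDR(t) = mean over permutations of the (rescaled) count of null p <= t,
    divided by max(1, #observed p <= t); the q-value at an observed p is
    the minimum FDR(t) over thresholds t >= p (monotonized), capped at 1.
    """
    p_obs = np.asarray(p_obs, float)
    if not null.null_p:
        raise ValueError("empty null ensemble")
    order = np.argsort(p_obs)
    sorted_p = p_obs[order]
    # ties: every tied value gets the count at the last tied position
    n_obs_le = np.searchsorted(sorted_p, sorted_p, side="right").astype(float)

    null_counts = np.zeros(sorted_p.size)
    for p, w in zip(null.null_p, null.weights):
        sp = np.sort(p)
        null_counts += w * np.searchsorted(sp, sorted_p, side="right")
    mean_null = null_counts / len(null.null_p)

    fdr_t = mean_null / np.maximum(n_obs_le, 1.0)
    # running minimum from largest p downward, cap at 1
    q_sorted = np.minimum(np.minimum.accumulate(fdr_t[::-1])[::-1], 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ------------------------------------------------------------- classification

def classify_windows(
    fits: _model.ModelFits,
    q_act: np.ndarray,
    q_int: np.ndarray,
    fdr_threshold: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Flag regulatory / methylation-dependent windows and summarize.

    regulatory: positive-beta and activity q < threshold;
    methylation-dependent (MD): regulatory and interaction q < threshold;
    direction: unmeth_higher iff b2 > b3.
    """
    pos = fits.positive_beta
    regulatory = pos & (q_act < fdr_threshold)
    md = regulatory & (q_int < fdr_threshold)
    direction = np.where(
        md, np.where(fits.beta[:, 2] > fits.beta[:, 3], "unmeth_higher", "meth_higher"), ""
    )
    table = pd.DataFrame(
        {
            "positive_beta": pos,
            "q_act": q_act,
            "q_int": q_int,
            "regulatory": regulatory,
            "methylation_dependent": md,
            "direction": direction,
        }
    )
    summary = classification_summary(
        n_analyzed=int(fits.ok.sum()),
        n_regulatory=int(regulatory.sum()),
        n_md=int(md.sum()),
        n_unmeth_higher=int((direction == "unmeth_higher").sum()),
    )
    return table, summary


def classification_summary(
    n_analyzed: int, n_regulatory: int, n_md: int, n_unmeth_higher: int
) -> dict:
    """Counts plus the derived percentages reported for a classification."""
    pct = lambda num, den: 100.0 * num / den if den else float("nan")
    return {
        "n_analyzed": n_analyzed,
        "n_regulatory": n_regulatory,
        "n_md": n_md,
        "n_unmeth_higher": n_unmeth_higher,
        "pct_regulatory_of_analyzed": pct(n_regulatory, n_analyzed),
        "pct_md_of_regulatory": pct(n_md, n_regulatory),
        "pct_unmeth_higher_of_md": pct(n_unmeth_higher, n_md),
    }


def condition_specific(
    q_by_treatment: pd.DataFrame,
    fdr_threshold: float = 0.01,
    mode: str = "default",
    stringent_fdr: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition-specificity of regulatory calls across treatments.

    ``q_by_treatment``: windows x treatments of activity q-values (NaN for
    windows not analyzed in a treatment, treated as not regulatory).
    default mode: specific to T iff q < threshold in T and q >= threshold
    everywhere else; stringent: q < threshold in T and q > stringent_fdr
    everywhere else. Returns (per-window profile, upset-style counts of
    every intersection class).
    """
    if mode not in ("default", "stringent"):
        raise ValueError(f"unknown mode {mode!r}")
    treatments = list(q_by_treatment.columns)
    if len(treatments) < 2:
        raise ValueError("need >= 2 treatments")
    q = q_by_treatment.to_numpy(dtype=float)
    reg = np.nan_to_num(q, nan=1.0) < fdr_threshold

    profile = pd.DataFrame(reg, columns=treatments, index=q_by_treatment.index)
    labels = []
    for i in range(len(profile)):
        active = [t for t, r in zip(treatments, reg[i]) if r]
        if len(active) == 1:
            t = active[0]
            others = [j for j, tt in enumerate(treatments) if tt != t]
            if mode == "stringent":
                ok = all(np.nan_to_num(q[i, j], nan=1.0) > stringent_fdr for j in others)
            else:
                ok = True
            labels.append(f"{t}-specific" if ok else "mixed")
        elif len(active) == 0:
            labels.append("none")
        elif len(active) == len(treatments):
            labels.append("shared")
        else:
            labels.append("+".join(active))
    profile["class"] = labels

    upset_rows = []
    for r in range(0, len(treatments) + 1):
        for combo in itertools.combinations(treatments, r):
            members = np.all(
                [reg[:, treatments.index(t)] == (t in combo) for t in treatments], axis=0
            )
            upset_rows.append({"set": "+".join(combo) if combo else "none",
                               "n_windows": int(members.sum())})
    return profile, pd.DataFrame(upset_rows)


# ------------------------------------------------------ auxiliary statistics

def proportion_binomial_test(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p: sum of outcome probabilities no larger
    than that of the observed k (the standard minimum-likelihood rule)."""
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie in (0, 1)")
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def storey_qvalue(
    p: np.ndarray, lambda_grid: np.ndarray | None = None, pi0: float | None = None
) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is smoothed by a cubic
    spline over the lambda grid and read off at the largest lambda, capped
    to (0, 1]. With fewer than 10 p-values (or pi0 given) the plug-in value
    is used; pi0 = 1 reduces to Benjamini-Hochberg.
    """
    p = np.asarray(p, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 10:
            pi0 = 1.0
        else:
            grid = (
                np.arange(0.05, 0.96, 0.05) if lambda_grid is None
                else np.asarray(lambda_grid, float)
            )
            pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
            if grid.size >= 4:
                spl = interpolate.UnivariateSpline(grid, pi0_l, k=3)
                pi0 = float(spl(grid.max()))
            else:
                pi0 = float(pi0_l[-1])
            pi0 = min(max(pi0, 1e-8), 1.0)
    order = np.argsort(p)
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(q_sorted[::-1])[::-1], 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ------------------------------------------------------------- full analysis

@dataclass
class TreatmentResult:
    """Everything the activity/MD analysis produces for one treatment."""

    fits: _model.ModelFits
    p_act: np.ndarray
    q_act: np.ndarray
    q_int: np.ndarray
    classification: pd.DataFrame
    summary: dict
    N: int


def _fit_once(
    logcpm: np.ndarray,
    design: np.ndarray,
    library_sizes: np.ndarray,
    moderate: bool,
    quality_weights: bool,
) -> _model.ModelFits:
    w, _ = _model.precision_weights(logcpm, design, library_sizes)
    if quality_weights:
        sw = _model.sample_quality_weights(logcpm, design)
        w = w * sw[None, :]
    fits = _model.fit_windows(logcpm, w, design)
    _model.moderate_variances(fits, enabled=moderate)
    _model.compute_pvalues(fits, moderate=moderate)
    return fits


def analyze_treatment(
    cm: CountMatrix,
    n_perm: int = 100,
    seed: int = 1,
    fdr_threshold: float = 0.01,
    moderate: bool = True,
    quality_weights: bool = True,
    norm_factors: bool = True,
) -> TreatmentResult:
    """Observed fit plus both permutation nulls for one treatment's samples.

    The identical normalization / weighting / fitting code path is applied
    to the observed labels and to every permutation, which is what keeps
    the empirical FDR calibrated.
    """
    if n_perm <= 0:
        raise ValueError("need at least one permutation")
    lib = cm.library_sizes()
    if norm_factors:
        lib = lib * _model.normalization_factors(cm.counts, lib)
    y = _model.log_cpm(cm.counts, lib)

    X_obs = _model.build_design(cm.samples)
    obs = _fit_once(y, X_obs, lib, moderate, quality_weights)
    p_act = _model.activity_pvalue(obs)
    pos_obs = obs.positive_beta
    N = int(pos_obs.sum())

    mol_plans = permute_molecule_labels(cm.samples, n_perm, seed)
    meth_plans = permute_methylation_labels(cm.samples, n_perm, seed + 1)

    act_fits, int_fits = [], []
    for j in range(n_perm):
        Xp = _permuted_design(cm.samples, molecule_swap=mol_plans[j])
        act_fits.append(_fit_once(y, Xp, lib, moderate, quality_weights))
        Xm = _permuted_design(cm.samples, methylation_plan=meth_plans[j])
        int_fits.append(_fit_once(y, Xm, lib, moderate, quality_weights))

    null_act = build_null(act_fits, "activity", N, seed + 2, scheme="molecule_label")
    # identical subsampled window sets (same selector, same seed), refit
    # under the methylation-label permutation
    null_int = build_null(
        int_fits, "interaction", N, seed + 2,
        scheme="methylation_label", selector_fits=act_fits,
    )

    q_act = np.ones_like(p_act)
    q_int = np.ones_like(p_act)
    if pos_obs.any():
        q_act[pos_obs] = empirical_fdr(p_act[pos_obs], null_act)
        p_int_obs = obs.p_int[pos_obs]
        finite = np.isfinite(p_int_obs)
        qi = np.ones_like(p_int_obs)
        if finite.any():
            qi[finite] = empirical_fdr(p_int_obs[finite], null_int)
        q_int[pos_obs] = qi

    classification, summary = classify_windows(obs, q_act, q_int, fdr_threshold)
    return TreatmentResult(
        fits=obs, p_act=p_act, q_act=q_act, q_int=q_int,
        classification=classification, summary=summary, N=N,
    )
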