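"""Synthetic mSTARR-seq experiments, annotation sets, and cohort data.

The reporter-count generator emulates the study design: paired plasmid
DNA/RNA libraries per 600-bp window, six replicate transfections per
methylation condition (methylated vs sham/unmethylated) per treatment
(baseline, IFNA, dex), gamma-Poisson (negative-binomial) counts, and a
known truth table of active / methylation-dependent / condition-specific
windows. Inactive windows transcribe at a small background floor (default
5% of the DNA scale) so that the detection filter is non-trivially
exercised.

The cohort generator emulates the macrophage integration data: per
individual, baseline window methylation (bounded-logit Gaussian) and a
linked-gene expression response coupled to methylation at a configurable
target correlation, stronger at "IFNA-specific" than "shared"
enhancer-gene pairs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datamodel import AnnotationSet, CountMatrix, GenomicWindow, SampleMeta
from .invivo import CohortDataset

DEFAULT_WIDTH = 600


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    mean = np.maximum(np.asarray(mean, float), 1e-9)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_mstarr_experiment(
    n_windows: int,
    replicates_per_condition: int = 6,
    treatments: Sequence[str] = ("baseline",),
    active_fraction: float = 0.0,
    md_fraction: float = 0.5,
    condition_specific_fraction: float = 0.0,
    effect_size_log2: float = 2.0,
    mean_dna_depth: float = 100.0,
    dispersion: float = 0.2,
    background_floor: float = 0.05,
    background_sd_log: float = 1.5,
    seed: int = 0,
    chrom: str = "chrS",
    width: int = DEFAULT_WIDTH,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate paired DNA/RNA counts with known regulatory truth.

    Returns (CountMatrix covering all treatments, truth table). Truth holds
    per window: active_unmeth / active_meth / md flags, the condition
    profile (treatments in which the window is active), per-condition
    effects, baseline abundance and dispersion. A methylation-dependent
    window has effect_size_log2 enrichment when unmethylated and background
    transcription only when methylated.
    """
    for name, frac in (
        ("active_fraction", active_fraction),
        ("md_fraction", md_fraction),
        ("condition_specific_fraction", condition_specific_fraction),
    ):
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    if replicates_per_condition < 2:
        raise ValueError("need >= 2 replicates per condition")
    if mean_dna_depth <= 0:
        raise ValueError("mean_dna_depth must be positive")

    rng = np.random.default_rng(np.random.SeedSequence([0x5747, seed]))
    windows = [
        GenomicWindow(chrom, i * width, (i + 1) * width) for i in range(n_windows)
    ]

    active = rng.random(n_windows) < active_fraction
    md = active & (rng.random(n_windows) < md_fraction)
    specific = active & (rng.random(n_windows) < condition_specific_fraction)
    profile = np.empty(n_windows, dtype=object)
    own_treatment = rng.choice(len(treatments), size=n_windows)
    for i in range(n_windows):
        if not active[i]:
            profile[i] = ()
        elif specific[i] and len(treatments) > 1:
            profile[i] = (treatments[own_treatment[i]],)
        else:
            profile[i] = tuple(treatments)

    abundance = rng.lognormal(np.log(mean_dna_depth), 0.5, size=n_windows)
    active_unmeth = active
    active_meth = active & ~md  # an MD window is silenced when methylated
    effect_unmeth = np.where(active_unmeth, effect_size_log2, 0.0)
    effect_meth = np.where(active_meth, effect_size_log2, 0.0)

    samples: list[SampleMeta] = []
    cols: list[np.ndarray] = []
    for trt in treatments:
        for methyl in ("unmethylated", "methylated"):
            for r in range(1, replicates_per_condition + 1):
                pair = f"{trt}_{methyl[0]}{r}"
                libfac_dna = rng.lognormal(0.0, 0.15)
                libfac_rna = rng.lognormal(0.0, 0.15)
                dna_mean = abundance * libfac_dna
                if methyl == "unmethylated":
                    eff, act_state = effect_unmeth, active_unmeth
                else:
                    eff, act_state = effect_meth, active_meth
                in_cond = np.array([trt in p for p in profile])
                # background (leaky) transcription is bursty: drawn fresh
                # per RNA library, heavy-tailed, mean-corrected so the
                # average background stays at `background_floor` of the DNA
                # scale. Each RNA library is thereby dominated by a minority
                # of windows — the typical window is RNA-poor relative to
                # its DNA input — while no window is *consistently*
                # elevated, keeping the inactive truth labels clean.
                floor_s = background_floor * rng.lognormal(
                    -0.5 * background_sd_log**2, background_sd_log, size=n_windows
                )
                gain = floor_s + np.where(in_cond & act_state, 2.0**eff, 0.0)
                rna_mean = abundance * libfac_rna * gain
                cols.append(_nb(rng, dna_mean, dispersion))
                samples.append(
                    SampleMeta(f"{pair}_DNA", "DNA", methyl, trt, pair)
                )
                cols.append(_nb(rng, rna_mean, dispersion))
                samples.append(
                    SampleMeta(f"{pair}_RNA", "RNA", methyl, trt, pair)
                )
    counts = np.column_stack(cols)
    for j, s in enumerate(samples):
        s.library_size = int(counts[:, j].sum())

    truth = pd.DataFrame(
        {
            "window_id": [w.window_id for w in windows],
            "active_unmeth": active_unmeth,
            "active_meth": active_meth,
            "md": md,
            "condition_profile": [";".join(p) for p in profile],
            "effect_unmeth": effect_unmeth,
            "effect_meth": effect_meth,
            "baseline_abundance": abundance,
            "dispersion": dispersion,
        }
    )
    return CountMatrix(windows=windows, samples=samples, counts=counts), truth


def simulate_annotation_sets(
    windows: Sequence[GenomicWindow],
    set_specs: Sequence[dict],
    seed: int = 0,
    active: np.ndarray | None = None,
) -> dict[str, AnnotationSet]:
    """Point (CpG) and interval annotation sets with controlled coverage.

    Each spec: {"name", "kind" ("points"|"intervals"), "coverage",
    "enrichment" (default 1)}. ``coverage`` is the fraction of windows
    containing at least one member; with enrichment e, membership *odds*
    for active windows are e-fold those of inactive windows (requires the
    ``active`` mask). Sets are non-exclusive: a window may belong to many.
    """
    rng = np.random.default_rng(np.random.SeedSequence([0x414e, seed]))
    out: dict[str, AnnotationSet] = {}
    n = len(windows)
    for spec in set_specs:
        cov = spec["coverage"]
        if not (0.0 < cov <= 1.0):
            raise ValueError("coverage fraction must lie in (0, 1]")
        e = float(spec.get("enrichment", 1.0))
        if e != 1.0 and active is None:
            raise ValueError("enrichment requires an `active` mask")
        if cov == 1.0:
            p = np.ones(n)
        elif e == 1.0 or active is None or not active.any() or active.all():
            p = np.full(n, cov)
        else:
            from scipy.optimize import brentq

            f_a = active.mean()

            def total_cov(log_o: float) -> float:
                o = np.exp(log_o)
                return f_a * (e * o) / (1 + e * o) + (1 - f_a) * o / (1 + o) - cov

            log_o = brentq(total_cov, -30, 30)
            o = np.exp(log_o)
            p = np.where(active, (e * o) / (1 + e * o), o / (1 + o))
        member = rng.random(n) < p

        rows = []
        for w, m in zip(windows, member):
            if not m:
                continue
            if spec["kind"] == "points":
                rows.append({"chrom": w.chrom, "pos": int(rng.integers(w.start, w.end))})
            else:
                s = int(rng.integers(w.start, w.end - 1))
                rows.append({"chrom": w.chrom, "start": s, "end": min(s + 200, w.end)})
        cols = ["chrom", "pos"] if spec["kind"] == "points" else ["chrom", "start", "end"]
        df = pd.DataFrame(rows) if rows else pd.DataFrame(columns=cols)
        out[spec["name"]] = AnnotationSet(name=spec["name"], kind=spec["kind"], records=df)
    return out


def simulate_macrophage_cohort(
    n_individuals: int = 35,
    n_pairs: int = 1000,
    r_target_specific: float = -0.17,
    r_target_shared: float = -0.05,
    meth_variance: float = 0.02,
    noise_sd: float = 1.0,
    seed: int = 0,
    n_specific: int | None = None,
    target_unit: str = "individual",
    exact: bool = False,
) -> tuple[CohortDataset, pd.DataFrame]:
    """Simulate a cohort with methylation-coupled expression responses.

    Baseline window methylation is bounded-logit Gaussian; the linked
    gene's response (infected minus baseline log-CPM) is a + b*methylation
    + noise, with b set so the realized correlation matches the target.
    ``target_unit`` chooses which correlation the target refers to:
    "individual" — the within-individual correlation across pairs (the
    in vivo cohort readout); "pair" — the per-pair correlation across
    individuals (the locus-wise readout).

    Pairs are labelled "IFNA-specific" (first ``n_specific``, default
    half) carrying ``r_target_specific``, the rest "shared" carrying
    ``r_target_shared``.

    With ``exact=True`` (pair mode) the noise is orthogonalized against
    methylation so each pair's *realized sample* correlation equals its
    target exactly — the construction for planting a locus of known R^2.
    """
    if n_individuals < 3:
        raise ValueError("need >= 3 individuals")
    for r in (r_target_specific, r_target_shared):
        if abs(r) > 1:
            raise ValueError("|r_target| must be <= 1")
    if meth_variance <= 0 and (r_target_specific or r_target_shared):
        raise ValueError("zero methylation variance cannot carry a correlation")
    if target_unit not in ("individual", "pair"):
        raise ValueError(f"unknown target_unit {target_unit!r}")

    rng = np.random.default_rng(np.random.SeedSequence([0x434f, seed]))
    if n_specific is None:
        n_specific = n_pairs // 2
    group = np.array(
        ["IFNA-specific"] * n_specific + ["shared"] * (n_pairs - n_specific)
    )
    r_target = np.where(group == "IFNA-specific", r_target_specific, r_target_shared)

    # methylation: logit-normal around pair-specific means
    mu = rng.uniform(0.15, 0.85, size=n_pairs)
    sigma_z = np.sqrt(meth_variance) / 0.25  # delta-method scale at m ~ 0.5
    z = logit(mu)[None, :] + rng.normal(0.0, sigma_z, size=(n_individuals, n_pairs))
    meth = np.clip(expit(z), 0.001, 0.999)

    # slope from the realized methylation spread on the targeted axis
    if target_unit == "individual":
        sd_m = np.empty(n_pairs)
        for g in ("IFNA-specific", "shared"):
            sel = group == g
            sd_m[sel] = meth[:, sel].std() if sel.any() else 1.0
    else:
        sd_m = meth.std(axis=0)
    sd_m = np.maximum(sd_m, 1e-12)
    with np.errstate(divide="ignore"):
        if noise_sd == 0:
            b = np.sign(r_target)
        else:
            b = r_target / np.sqrt(1.0 - np.minimum(r_target**2, 1.0 - 1e-12)) * noise_sd / sd_m

    if exact:
        if target_unit != "pair":
            raise ValueError("exact planting requires target_unit='pair'")
        response = np.empty_like(meth)
        for p in range(n_pairs):
            x = meth[:, p] - meth[:, p].mean()
            e = rng.normal(size=n_individuals)
            e = e - e.mean()
            e -= x * (e @ x) / (x @ x)
            x_hat = x / np.linalg.norm(x)
            e_hat = e / np.linalg.norm(e)
            rt = r_target[p]
            response[:, p] = noise_sd * (
                rt * x_hat + np.sqrt(1.0 - rt**2) * e_hat
            ) * np.sqrt(n_individuals)
    else:
        response = b[None, :] * meth + rng.normal(0.0, noise_sd, size=meth.shape)

    individuals = [f"ind{i + 1:02d}" for i in range(n_individuals)]
    # one window and one gene per pair, each on its own 1-Mb tile so that
    # nearest-gene linking (<= 100 kb) recovers exactly the intended pairs
    win_ids, genes_rows, links_rows = [], [], []
    for p in range(n_pairs):
        start = p * 1_000_000
        wid = f"chrC:{start}-{start + 600}"
        gid = f"gene{p:04d}"
        win_ids.append(wid)
        genes_rows.append(
            {"gene_id": gid, "chrom": "chrC", "start": start + 5_000,
             "end": start + 7_000, "strand": "+"}
        )
        links_rows.append(
            {"window_id": wid, "gene_id": gid, "distance": 4_400, "source": "table"}
        )
    genes = pd.DataFrame(genes_rows)
    links = pd.DataFrame(links_rows)

    gene_ids = [g["gene_id"] for g in genes_rows]
    expr_baseline = pd.DataFrame(
        rng.normal(5.0, 1.0, size=(n_individuals, n_pairs)),
        index=individuals, columns=gene_ids,
    )
    expr_infected = expr_baseline + pd.DataFrame(
        response, index=individuals, columns=gene_ids
    )
    meth_df = pd.DataFrame(meth, index=individuals, columns=win_ids)

    dataset = CohortDataset(
        individuals=individuals,
        meth_baseline=meth_df,
        expr_baseline=expr_baseline,
        expr_infected=expr_infected,
        genes=genes,
        links=links,
    )
    truth = pd.DataFrame(
        {
            "window_id": win_ids,
            "gene_id": gene_ids,
            "group": group,
            "r_target": r_target,
            "slope": b,
            "meth_mean": meth.mean(axis=0),
            "meth_var": meth.var(axis=0),
            "noise_sd": noise_sd,
        }
    )
    return dataset, truth
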