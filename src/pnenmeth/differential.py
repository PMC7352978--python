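"""Differential methylation: moderated per-CpG tests and bump-hunted regions.

DMPs come from a two-group linear model per probe with empirical-Bayes
variance moderation: residual variances are shrunk toward a common prior
whose degrees of freedom and scale are estimated by moment matching on
the log-variance ensemble (the scaled-F model). The moderated t has
residual + prior degrees of freedom; p-values are BH-adjusted.

DMRs are found by bump hunting: probes are clustered by genomic gap,
per-probe group differences are smoothed by a running mean within each
cluster, candidate bumps are maximal same-sign runs of smoothed
coefficients exceeding a cutoff, and their areas are calibrated against
a label-permutation null (family-wise p from the permutation maxima).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import polygamma, psi
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .arrays_io import (
    PROMOTER_FEATURES,
    FEATURES,
    ISLAND_RELATIONS,
    AnalysisConfig,
    BetaMatrix,
    ProbeManifest,
    chrom_sort_key,
)

logger = logging.getLogger("pnenmeth")

__all__ = [
    "dmp_test",
    "summarize_distribution",
    "dmr_bumphunter",
    "moderate_variances",
]


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def _running_mean_sorted(y: np.ndarray, x: np.ndarray, span: float = 0.4) -> np.ndarray:
    """Windowed running mean of y over the ordering of x (trend smoother)."""
    order = np.argsort(x, kind="mergesort")
    n = len(y)
    k = max(int(span * n), 5)
    half = k // 2
    ys = y[order]
    c = np.r_[0.0, np.cumsum(ys)]
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    sm = (c[hi] - c[lo]) / (hi - lo)
    out = np.empty(n)
    out[order] = sm
    return out


def moderate_variances(
    s2: np.ndarray,
    df_resid: float,
    prior_df: float | None = None,
    covariate: np.ndarray | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Shrink per-probe variances toward an empirical-Bayes prior.

    Fits ``s2 ~ s0^2 * F(df_resid, d0)`` by matching the mean and
    variance of log(s2) (digamma/trigamma moments). When ``covariate``
    is given (typically mean methylation), the prior scale follows a
    running-mean trend of log(s2) on the covariate instead of a single
    constant, accommodating the mean-variance dependence of bounded
    methylation fractions; the prior df comes from the spread around
    the trend. Returns the posterior variances
    ``(d0*s0^2 + df*s2) / (d0 + df)``, the prior df ``d0`` and the
    per-probe prior scale. ``prior_df`` overrides the estimated d0
    (0 disables moderation; inf fully pools).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all probe variances are zero")
    floor = s2[ok].min()
    z = np.log(np.where(ok, s2, floor))

    if covariate is not None and len(np.unique(covariate)) > 5:
        trend = _running_mean_sorted(z, np.asarray(covariate, dtype=float))
    else:
        trend = np.full_like(z, float(z.mean()))
    resid = z - trend
    e_var = float(resid.var(ddof=1)) if len(resid) > 1 else 0.0

    if prior_df is None:
        resid_var = e_var - float(polygamma(1, df_resid / 2.0))
        if resid_var > 0:
            d0 = 2.0 * _trigamma_inverse(resid_var)
        else:
            d0 = np.inf
    else:
        d0 = float(prior_df)

    # E[log s2] = log s0^2 + digamma(d/2) - log(d/2) under the chi-square
    # part alone (d0 -> inf); the finite-d0 fit adds the prior moments.
    if np.isfinite(d0) and d0 > 0:
        log_s02 = (
            trend
            - float(psi(df_resid / 2.0))
            + float(psi(d0 / 2.0))
            + np.log(df_resid / d0)
        )
        s02 = np.exp(log_s02)
        post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
    elif d0 == 0:
        s02 = np.exp(trend)  # nominal; unused in the posterior
        post = s2.copy()
    else:  # d0 = inf: fully pooled onto the (possibly trended) prior
        s02 = np.exp(trend - float(psi(df_resid / 2.0)) + np.log(df_resid / 2.0))
        post = s02.copy()
    return post, d0, s02


# ---------------------------------------------------------------------------
# DMP testing
# ---------------------------------------------------------------------------


def _split_groups(
    columns: pd.Index, groups: Mapping[str, str] | pd.Series, test: str, reference: str
) -> tuple[list[str], list[str]]:
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    g1 = [s for s in columns if groups.get(s) == test]
    g0 = [s for s in columns if groups.get(s) == reference]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {len(g1)} {test!r}, {len(g0)} {reference!r})"
        )
    return g1, g0


def dmp_test(
    beta: BetaMatrix,
    groups: Mapping[str, str] | pd.Series,
    config: AnalysisConfig | None = None,
    *,
    test: str = "tumor",
    reference: str = "islet",
    prior_df: float | None = None,
    stat_scale: str = "mvalue",
) -> pd.DataFrame:
    """Moderated two-group test per probe.

    Group means and delta_beta (test minus reference) are reported on
    the beta scale; the moderated statistic is computed on M-values by
    default (``stat_scale="mvalue"``), the variance-stabilizing scale on
    which the common-prior model is well calibrated for bounded
    methylation fractions. ``stat_scale="beta"`` tests the raw
    fractions.

    Returns a DataFrame indexed by probe, sorted by p, with group means,
    delta_beta, moderated t, df, p, BH-adjusted p, a significance flag
    at the configured cutoff and the direction (hyper if delta_beta > 0
    else hypo). Zero-variance probes with zero effect get p = 1 and are
    flagged.
    """
    config = config or AnalysisConfig()
    df = beta.data
    if df.isna().any().any():
        raise ValueError("dmp_test requires a complete matrix; run filter_probes first")
    if stat_scale not in ("mvalue", "beta"):
        raise ValueError("stat_scale must be 'mvalue' or 'beta'")
    g1, g0 = _split_groups(df.columns, groups, test, reference)

    b1 = df[g1].to_numpy(dtype=float)
    b0 = df[g0].to_numpy(dtype=float)
    m1 = b1.mean(axis=1)
    m0 = b0.mean(axis=1)
    delta = m1 - m0

    if stat_scale == "mvalue":
        eps = 1e-6
        x1 = np.log2(np.clip(b1, eps, 1 - eps) / (1 - np.clip(b1, eps, 1 - eps)))
        x0 = np.log2(np.clip(b0, eps, 1 - eps) / (1 - np.clip(b0, eps, 1 - eps)))
    else:
        x1, x0 = b1, b0
    n1, n0 = x1.shape[1], x0.shape[1]
    mu1 = x1.mean(axis=1)
    mu0 = x0.mean(axis=1)
    effect = mu1 - mu0
    df_resid = n1 + n0 - 2
    rss = ((x1 - mu1[:, None]) ** 2).sum(axis=1) + ((x0 - mu0[:, None]) ** 2).sum(axis=1)
    s2 = rss / df_resid

    degenerate = s2 <= 1e-300
    if degenerate.any():
        s2 = np.where(degenerate, np.median(s2[~degenerate]) if (~degenerate).any() else 1e-6, s2)
    overall_mean = df.to_numpy(dtype=float).mean(axis=1)
    post, d0, s02 = moderate_variances(s2, df_resid, prior_df, covariate=overall_mean)
    se = np.sqrt(post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, effect / se, 0.0)
    df_total = df_resid + (d0 if np.isfinite(d0) else np.inf)
    if np.isfinite(df_total):
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(tstat))

    flagged = degenerate & (np.abs(effect) < 1e-12)
    p = np.where(flagged, 1.0, p)
    tstat = np.where(flagged, 0.0, tstat)

    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {
            "mean_tumor": m1,
            "mean_normal": m0,
            "delta_beta": delta,
            "moderated_t": tstat,
            "df": df_total,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj <= config.adj_p_cutoff,
            "direction": np.where(delta > 0, "hyper", "hypo"),
            "zero_variance": flagged,
        },
        index=df.index.rename("probe_id"),
    )
    return out.sort_values("p", kind="mergesort")


def summarize_distribution(
    dmps: pd.DataFrame, manifest: ProbeManifest
) -> pd.DataFrame:
    """Count significant DMPs per annotation category, hypo and hyper
    separately, normalized by the number of analyzed probes per category.

    The promoter roll-up (TSS1500 + TSS200 + 5'UTR) is reported as an
    extra row under classification "promoter".
    """
    ann = manifest.data.loc[manifest.data.index.intersection(dmps.index)]
    sig = dmps.loc[ann.index, "significant"]
    direction = dmps.loc[ann.index, "direction"]

    rows = []
    specs = [("island", "island_relation", ISLAND_RELATIONS), ("feature", "feature", FEATURES)]
    for classification, col, vocab in specs:
        for cat in vocab:
            in_cat = ann[col] == cat
            total = int(in_cat.sum())
            for d in ("hypo", "hyper"):
                count = int((in_cat & sig & (direction == d)).sum())
                rows.append(
                    {
                        "classification": classification,
                        "category": cat,
                        "direction": d,
                        "count": count,
                        "total": total,
                        "fraction": count / total if total else 0.0,
                    }
                )
    in_prom = ann["feature"].isin(PROMOTER_FEATURES)
    total = int(in_prom.sum())
    for d in ("hypo", "hyper"):
        count = int((in_prom & sig & (direction == d)).sum())
        rows.append(
            {
                "classification": "promoter",
                "category": "TSS1500+TSS200+5'UTR",
                "direction": d,
                "count": count,
                "total": total,
                "fraction": count / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bump hunting
# ---------------------------------------------------------------------------


def _cluster_probes(manifest: ProbeManifest, probe_ids: pd.Index, max_gap: int) -> np.ndarray:
    """Cluster id per probe: consecutive probes on one chromosome with
    inter-probe gap <= max_gap share a cluster."""
    ann = manifest.data.loc[probe_ids]
    chrom = ann["chrom"].to_numpy()
    pos = ann["pos"].to_numpy()
    cluster = np.zeros(len(ann), dtype=int)
    cid = 0
    for i in range(1, len(ann)):
        if chrom[i] != chrom[i - 1] or pos[i] - pos[i - 1] > max_gap:
            cid += 1
        cluster[i] = cid
    return cluster


def _running_mean(values: np.ndarray, cluster: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean within each cluster, truncated at edges."""
    out = np.empty_like(values, dtype=float)
    half = window // 2
    starts = np.flatnonzero(np.r_[True, cluster[1:] != cluster[:-1]])
    bounds = np.r_[starts, len(cluster)]
    for s, e in zip(bounds[:-1], bounds[1:]):
        seg = values[s:e]
        if len(seg) == 1:
            out[s:e] = seg
            continue
        c = np.r_[0.0, np.cumsum(seg)]
        idx = np.arange(len(seg))
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, len(seg))
        out[s:e] = (c[hi] - c[lo]) / (hi - lo)
    return out


def _find_bumps(
    smooth: np.ndarray, cluster: np.ndarray, cutoff: float, min_probes: int
) -> list[tuple[int, int, float]]:
    """Maximal same-sign runs with |smooth| >= cutoff and >= min_probes.

    Returns (start_index, end_index_inclusive, area) triples.
    """
    sign = np.where(smooth >= cutoff, 1, np.where(smooth <= -cutoff, -1, 0))
    bumps = []
    i = 0
    n = len(smooth)
    while i < n:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and sign[j + 1] == sign[i] and cluster[j + 1] == cluster[i]:
            j += 1
        if j - i + 1 >= min_probes:
            area = float(np.abs(smooth[i : j + 1]).sum())
            bumps.append((i, j, area))
        i = j + 1
    return bumps


def dmr_bumphunter(
    beta: BetaMatrix,
    groups: Mapping[str, str] | pd.Series,
    manifest: ProbeManifest,
    config: AnalysisConfig | None = None,
    *,
    test: str = "tumor",
    reference: str = "islet",
    max_gap: int = 300,
    window: int = 3,
    n_permutations: int = 250,
    cutoff_quantile: float = 0.99,
    rng_seed: int | None = None,
) -> pd.DataFrame:
    """Bump-hunting DMR detection with a label-permutation null.

    The cutoff is the ``cutoff_quantile`` quantile of |null smoothed
    coefficients| pooled over permutations. Candidate areas receive
    family-wise permutation p-values against the per-permutation maximum
    null area, using the add-one estimator (1 + #{null >= obs})/(1 + B),
    then BH adjustment.
    """
    config = config or AnalysisConfig()
    if n_permutations < 50:
        raise ValueError("n_permutations must be >= 50")
    df = beta.data
    if df.isna().any().any():
        raise ValueError("dmr_bumphunter requires a complete matrix")
    g1, g0 = _split_groups(df.columns, groups, test, reference)

    # position-sort the tested probes
    ann = manifest.data.loc[df.index.intersection(manifest.probe_ids)]
    order = ann.index  # manifest order is (chrom, pos)
    df = df.loc[order]

    cluster = _cluster_probes(manifest, df.index, max_gap)
    sizes = np.bincount(cluster)
    if (sizes >= config.dmr_min_probes).sum() == 0:
        logger.warning("dmr_bumphunter: no probe cluster has >= %d probes", config.dmr_min_probes)
        return _empty_dmr_frame()

    X = df[g1 + g0].to_numpy(dtype=float)
    n1 = len(g1)
    labels = np.r_[np.ones(n1, dtype=bool), np.zeros(len(g0), dtype=bool)]

    def smoothed_coef(lab: np.ndarray) -> np.ndarray:
        coef = X[:, lab].mean(axis=1) - X[:, ~lab].mean(axis=1)
        return _running_mean(coef, cluster, window)

    observed = smoothed_coef(labels)

    rng = np.random.default_rng(
        config.rng_seed if rng_seed is None else rng_seed
    )
    perms = [rng.permutation(labels) for _ in range(n_permutations)]
    null_smooth = np.stack([smoothed_coef(p) for p in perms])
    cutoff = float(np.quantile(np.abs(null_smooth), cutoff_quantile))

    null_max_area = np.zeros(n_permutations)
    for b in range(n_permutations):
        bumps = _find_bumps(null_smooth[b], cluster, cutoff, config.dmr_min_probes)
        if bumps:
            null_max_area[b] = max(a for _, _, a in bumps)

    candidates = _find_bumps(observed, cluster, cutoff, config.dmr_min_probes)
    if not candidates:
        return _empty_dmr_frame()

    ann = manifest.data.loc[df.index]
    chrom_arr = ann["chrom"].to_numpy()
    pos_arr = ann["pos"].to_numpy()
    rows = []
    for s, e, area in candidates:
        p = (1.0 + float((null_max_area >= area).sum())) / (1.0 + n_permutations)
        rows.append(
            {
                "chrom": str(chrom_arr[s]),
                "start": int(pos_arr[s]),
                "end": int(pos_arr[e]),
                "n_probes": e - s + 1,
                "area": area,
                "mean_effect": float(observed[s : e + 1].mean()),
                "p": p,
                "probe_ids": list(df.index[s : e + 1]),
            }
        )
    out = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["p_adj"] = p_adj
    out["significant"] = out["p_adj"] <= config.adj_p_cutoff
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def _empty_dmr_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "chrom",
            "start",
            "end",
            "n_probes",
            "area",
            "mean_effect",
            "p",
            "probe_ids",
            "p_adj",
            "significant",
        ]
    )


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """0-based half-open BED view of a DMR table."""
    bed = dmrs[["chrom", "start", "end"]].copy()
    bed["start"] = bed["start"] - 1
    bed["name"] = [f"dmr_{i + 1}" for i in range(len(bed))]
    bed["score"] = dmrs["area"]
    return bed
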