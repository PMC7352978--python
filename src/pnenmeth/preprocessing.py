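"""Probe filtering, beta-mixture quantile normalization, M-values, MDS.

The two Infinium probe chemistries have different dynamic ranges; type II
probes are compressed relative to type I. Normalization follows the
beta-mixture quantile (BMIQ) idea: per sample, fit a three-state beta
mixture (unmethylated U, hemimethylated H, methylated M) separately to
type I and type II probes, then map the type II U- and M-components onto
the corresponding type I components by quantile matching, and rescale
the H-component linearly between them. Type I probes are left untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .arrays_io import BetaMatrix, ProbeManifest

logger = logging.getLogger("pnenmeth")

__all__ = [
    "BetaMixtureFit",
    "NormalizationReport",
    "filter_probes",
    "fit_beta_mixture3",
    "bmiq_normalize",
    "mvalues",
    "classical_mds",
]

_MIN_PROBES_PER_TYPE = 50


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_probes(
    beta: BetaMatrix, manifest: ProbeManifest, mask: Iterable[str] = ()
) -> BetaMatrix:
    """Drop masked probes, probes with missing values, and probes absent
    from the manifest; retained values are unchanged."""
    df = beta.data
    mask = frozenset(mask)
    in_manifest = df.index.isin(manifest.probe_ids)
    masked = df.index.isin(mask)
    complete = ~df.isna().any(axis=1).to_numpy()
    keep = in_manifest & ~masked & complete
    logger.info(
        "filter_probes: kept %d/%d (removed %d masked, %d with missing values, "
        "%d absent from manifest)",
        int(keep.sum()),
        len(df),
        int((masked & in_manifest).sum()),
        int((~complete & in_manifest & ~masked).sum()),
        int((~in_manifest).sum()),
    )
    if not keep.any():
        raise ValueError("filter_probes removed every probe")
    return BetaMatrix(df.loc[keep])


# ---------------------------------------------------------------------------
# Beta-mixture fitting (EM with moment-matching M-step)
# ---------------------------------------------------------------------------


@dataclass
class BetaMixtureFit:
    """Three-component beta mixture ordered U < H < M."""

    a: np.ndarray  # shape (3,) alpha parameters
    b: np.ndarray  # shape (3,) beta parameters
    weights: np.ndarray  # shape (3,), sums to 1
    n_iter: int
    converged: bool
    log_likelihood: float

    @property
    def means(self) -> np.ndarray:
        return self.a / (self.a + self.b)

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        logp = np.stack(
            [
                np.log(self.weights[k] + 1e-300)
                + stats.beta.logpdf(x, self.a[k], self.b[k])
                for k in range(3)
            ]
        )
        return np.exp(logp - logsumexp(logp, axis=0))


def _moments_to_ab(mean: float, var: float) -> tuple[float, float]:
    mean = float(np.clip(mean, 1e-3, 1 - 1e-3))
    var = float(max(var, 1e-6))
    var = min(var, mean * (1 - mean) * 0.999)
    conc = mean * (1 - mean) / var - 1.0
    conc = float(np.clip(conc, 0.1, 1e4))
    return mean * conc, (1 - mean) * conc


def fit_beta_mixture3(
    x: np.ndarray, max_iter: int = 100, tol: float = 1e-6
) -> BetaMixtureFit:
    """EM fit of a 3-component beta mixture.

    Initial responsibilities come from thresholds at 0.25 and 0.75; the
    M-step matches each component's weighted mean and variance to a beta
    distribution. Components are kept ordered by mean (U < H < M).
    """
    x = np.clip(np.asarray(x, dtype=float), 1e-4, 1 - 1e-4)
    n = len(x)
    resp = np.zeros((3, n))
    resp[0] = x < 0.25
    resp[1] = (x >= 0.25) & (x <= 0.75)
    resp[2] = x > 0.75
    # guard: every component needs some mass to start
    resp += 1e-3
    resp /= resp.sum(axis=0)

    a = np.empty(3)
    b = np.empty(3)
    weights = np.empty(3)
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M-step
        for k in range(3):
            w = resp[k]
            sw = w.sum()
            weights[k] = sw / n
            m = float((w * x).sum() / sw)
            v = float((w * (x - m) ** 2).sum() / sw)
            a[k], b[k] = _moments_to_ab(m, v)
        order = np.argsort(a / (a + b))
        a, b, weights = a[order], b[order], weights[order]
        # E-step
        logp = np.stack(
            [
                np.log(weights[k] + 1e-300) + stats.beta.logpdf(x, a[k], b[k])
                for k in range(3)
            ]
        )
        ll = float(logsumexp(logp, axis=0).sum())
        resp = np.exp(logp - logsumexp(logp, axis=0))
        if abs(ll - prev_ll) < tol * (abs(prev_ll) + 1.0):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return BetaMixtureFit(a, b, weights, it, converged, prev_ll)


# ---------------------------------------------------------------------------
# BMIQ-style normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizationReport:
    """Per-sample mixture fits and transform accounting."""

    type1_fits: dict[str, BetaMixtureFit] = field(default_factory=dict)
    type2_fits: dict[str, BetaMixtureFit] = field(default_factory=dict)
    n_transformed: dict[str, int] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    fallback: list[str] = field(default_factory=list)


def _map_tail_component(
    x: np.ndarray, fit2: BetaMixtureFit, fit1: BetaMixtureFit, k: int
) -> np.ndarray:
    """Quantile-match component k of the type II fit onto the type I fit."""
    p = stats.beta.cdf(x, fit2.a[k], fit2.b[k])
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return stats.beta.ppf(p, fit1.a[k], fit1.b[k])


def bmiq_normalize(
    beta: BetaMatrix, manifest: ProbeManifest
) -> tuple[BetaMatrix, NormalizationReport]:
    """Align type II probe distributions to type I, per sample.

    U- and M-state type II probes (assigned by maximum posterior) are
    quantile-mapped between the fitted beta components; H-state probes
    are rescaled by the linear map sending the type II H-range onto the
    type I H-range. Samples with fewer than 50 probes of either type, or
    with a non-convergent fit, fall back to identity and are flagged.
    """
    df = beta.data
    common = df.index.intersection(manifest.probe_ids)
    design = manifest.data.loc[common, "design_type"]
    t1_probes = df.index.intersection(design.index[design == "I"])
    t2_probes = df.index.intersection(design.index[design == "II"])

    out = df.copy()
    report = NormalizationReport()

    if len(t2_probes) == 0:
        report.skipped = list(df.columns)
        report.n_transformed = {s: 0 for s in df.columns}
        logger.info("bmiq_normalize: no type II probes; matrix returned unchanged")
        return BetaMatrix(out), report

    for sample in df.columns:
        x1 = df.loc[t1_probes, sample].dropna().to_numpy()
        x2 = df.loc[t2_probes, sample].to_numpy()
        valid2 = ~np.isnan(x2)
        if len(x1) < _MIN_PROBES_PER_TYPE or valid2.sum() < _MIN_PROBES_PER_TYPE:
            logger.warning(
                "bmiq_normalize: sample %r has too few probes per type; skipped", sample
            )
            report.skipped.append(sample)
            report.n_transformed[sample] = 0
            continue

        fit1 = fit_beta_mixture3(x1)
        fit2 = fit_beta_mixture3(np.clip(x2[valid2], 1e-4, 1 - 1e-4))
        report.type1_fits[sample] = fit1
        report.type2_fits[sample] = fit2
        if not (fit1.converged and fit2.converged):
            logger.warning(
                "bmiq_normalize: EM did not converge for sample %r; identity fallback",
                sample,
            )
            report.fallback.append(sample)
            report.n_transformed[sample] = 0
            continue

        xv = np.clip(x2[valid2], 1e-4, 1 - 1e-4)
        resp = fit2.responsibilities(xv)
        state = resp.argmax(axis=0)
        mapped = xv.copy()

        for k in (0, 2):  # U and M tails: quantile matching
            sel = state == k
            if sel.any():
                mapped[sel] = _map_tail_component(xv[sel], fit2, fit1, k)

        sel_h = state == 1
        if sel_h.any():
            # Linear dilation: send the type II H-range onto the type I H-range.
            r1 = fit1.responsibilities(np.clip(x1, 1e-4, 1 - 1e-4))
            h1 = x1[r1.argmax(axis=0) == 1]
            h2 = xv[sel_h]
            lo2, hi2 = float(h2.min()), float(h2.max())
            if len(h1) >= 2 and hi2 > lo2:
                lo1, hi1 = float(h1.min()), float(h1.max())
                mapped[sel_h] = lo1 + (h2 - lo2) * (hi1 - lo1) / (hi2 - lo2)
            # else: too few type I H probes to define a target range; keep as is

        mapped = np.clip(mapped, 0.0, 1.0)
        col = out[sample].copy()
        col.loc[t2_probes[valid2]] = mapped
        out[sample] = col
        report.n_transformed[sample] = int(valid2.sum())

    return BetaMatrix(out), report


# ---------------------------------------------------------------------------
# M-values and MDS
# ---------------------------------------------------------------------------


def mvalues(beta: BetaMatrix, epsilon: float = 1e-6) -> pd.DataFrame:
    """M = log2(b / (1 - b)) with b clipped to [epsilon, 1 - epsilon]."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    b = beta.data.to_numpy(dtype=float)
    b = np.clip(b, epsilon, 1 - epsilon)
    m = np.log2(b / (1 - b))
    return pd.DataFrame(m, index=beta.probe_ids, columns=beta.sample_ids)


def classical_mds(beta: BetaMatrix, top_n: int | None = 1000) -> pd.DataFrame:
    """Torgerson (classical) scaling of samples into 2-D.

    Uses the ``top_n`` most-variable probes (all, with a warning, if the
    matrix has fewer), Euclidean sample distances, double centering and
    the top-two eigenvectors scaled by sqrt(eigenvalue). Deterministic up
    to the sign of each axis.
    """
    df = beta.data.dropna(axis=0, how="any")
    if df.shape[1] < 3:
        raise ValueError("classical_mds needs at least 3 samples")
    if top_n is not None and top_n < df.shape[0]:
        variances = df.var(axis=1).to_numpy()
        idx = np.argsort(variances)[::-1][:top_n]
        df = df.iloc[np.sort(idx)]
    elif top_n is not None and top_n > df.shape[0]:
        logger.warning(
            "classical_mds: requested top %d probes but only %d available", top_n, df.shape[0]
        )

    X = df.to_numpy(dtype=float).T  # samples x probes
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    np.fill_diagonal(d2, 0.0)
    d2 = np.maximum(d2, 0.0)

    n = d2.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:2]
    lam = np.maximum(evals[order], 0.0)
    coords = evecs[:, order] * np.sqrt(lam)[None, :]
    # sign convention: make the largest-magnitude loading of each axis positive
    for k in range(coords.shape[1]):
        j = int(np.abs(coords[:, k]).argmax())
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    return pd.DataFrame(coords, index=df.columns, columns=["dim1", "dim2"])
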