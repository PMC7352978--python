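"""Copy-number inference from methylation-array log2 intensities.

A query sample's per-probe log2 intensity is regressed on a panel of
normal references (ordinary least squares with intercept); the residual,
median-centered so the genome-wide median is zero, is the log2 copy
ratio. Ratios are aggregated into genomic bins that satisfy both a
minimum span (50 kb by default) and a minimum probe count, and bins are
called gain (ratio >= +0.150), loss (<= -0.150) or neutral. Per-group
gain/loss frequencies per bin give the circos-style tracks.

No segmentation is applied: calls are per-bin, matching thresholded
frequency plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arrays_io import AnalysisConfig, IntensityMatrix, ProbeManifest, SampleSheet

logger = logging.getLogger("pnenmeth")

__all__ = [
    "BinTrack",
    "fit_reference_baseline",
    "make_bins",
    "bin_ratios",
    "call_states",
    "group_frequency",
    "run_cna",
]


# ---------------------------------------------------------------------------
# Reference baseline
# ---------------------------------------------------------------------------


def fit_reference_baseline(query: pd.Series, refs: pd.DataFrame) -> pd.Series:
    """Per-probe log2 copy ratio of a query against normal references.

    OLS of the query on the reference columns plus intercept; the ratio
    is query minus fitted values, median-centered. Collinear reference
    columns are dropped with a warning.
    """
    if refs.shape[1] < 2:
        raise ValueError("fit_reference_baseline needs >= 2 reference samples")
    if not query.index.equals(refs.index):
        refs = refs.loc[query.index]

    y = query.to_numpy(dtype=float)
    R = refs.to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y)), R])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning(
            "fit_reference_baseline: reference columns are collinear "
            "(rank %d < %d); redundant directions dropped",
            rank,
            X.shape[1],
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    ratio = y - fitted
    ratio = ratio - np.median(ratio)
    return pd.Series(ratio, index=query.index, name=query.name)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


@dataclass
class BinTrack:
    """Ordered genomic bins with their member probes.

    ``bins`` has columns chrom/start/end/n_probes/degenerate (1-based
    inclusive coordinates); ``probe_ids`` lists member probes per bin.
    """

    bins: pd.DataFrame
    probe_ids: list[list[str]]

    def __len__(self) -> int:
        return len(self.bins)

    def to_bed(self) -> pd.DataFrame:
        bed = self.bins[["chrom", "start", "end"]].copy()
        bed["start"] = bed["start"] - 1  # 0-based half-open
        bed["name"] = [f"bin_{i + 1}" for i in range(len(bed))]
        return bed


def make_bins(manifest: ProbeManifest, config: AnalysisConfig | None = None) -> BinTrack:
    """Greedy per-chromosome binning.

    A window is extended probe by probe until its span is >= the minimum
    bin size AND it holds >= the minimum probe count, then closed.
    Trailing probes that cannot satisfy the minima merge into the
    previous bin. Bin boundaries sit midway between flanking probes;
    chromosomes with fewer probes than the minimum become a single
    flagged bin.
    """
    config = config or AnalysisConfig()
    min_bp = config.cna_min_bin_bp
    min_probes = config.cna_min_bin_probes

    rows = []
    members: list[list[str]] = []
    df = manifest.data
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        ids = list(grp.index)
        n = len(ids)
        if n < min_probes:
            logger.warning(
                "make_bins: chromosome %s has only %d probes (< %d); single bin",
                chrom,
                n,
                min_probes,
            )
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[0]),
                    "end": int(pos[-1]),
                    "n_probes": n,
                    "degenerate": True,
                }
            )
            members.append(ids)
            continue

        # terminal probes get an extrapolated half-gap so every probe
        # owns symmetric territory and edge bins are not undersized
        def left_bound(i: int) -> int:
            if i == 0:
                half = (pos[1] - pos[0]) // 2 if n > 1 else 0
                return max(1, int(pos[0] - half) + 1)
            return int((pos[i - 1] + pos[i]) // 2 + 1)

        def right_bound(j: int) -> int:
            if j == n - 1:
                half = (pos[-1] - pos[-2]) // 2 if n > 1 else 0
                return int(pos[-1] + half)
            return int((pos[j] + pos[j + 1]) // 2)

        def width(i: int, j: int) -> int:
            return right_bound(j) - left_bound(i) + 1

        bin_bounds: list[tuple[int, int]] = []  # probe index ranges [i, j]
        i = 0
        while i < n:
            j = i
            while j < n - 1 and not (width(i, j) >= min_bp and j - i + 1 >= min_probes):
                j += 1
            if width(i, j) >= min_bp and j - i + 1 >= min_probes:
                bin_bounds.append((i, j))
            else:  # trailing remainder: merge into the previous bin
                if bin_bounds:
                    bin_bounds[-1] = (bin_bounds[-1][0], j)
                else:
                    bin_bounds.append((i, j))
                break
            i = j + 1

        for k, (i0, j0) in enumerate(bin_bounds):
            start = left_bound(i0)
            end = right_bound(j0)
            satisfied = (width(i0, j0) >= min_bp) and (j0 - i0 + 1 >= min_probes)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_probes": j0 - i0 + 1,
                    "degenerate": not satisfied,
                }
            )
            members.append(ids[i0 : j0 + 1])

    bins = pd.DataFrame(rows)
    bins.index.name = "bin"
    return BinTrack(bins, members)


def bin_ratios(ratios: pd.Series | pd.DataFrame, bins: BinTrack) -> pd.DataFrame:
    """Mean per-bin log2 ratio; columns are samples (a Series becomes a
    single-column frame)."""
    if isinstance(ratios, pd.Series):
        ratios = ratios.to_frame(ratios.name or "sample")
    out = np.empty((len(bins), ratios.shape[1]))
    for k, ids in enumerate(bins.probe_ids):
        out[k] = ratios.loc[ids].mean(axis=0).to_numpy()
    return pd.DataFrame(out, index=bins.bins.index, columns=ratios.columns)


def call_states(
    binned: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Threshold bin ratios into gain / neutral / loss states.

    Boundaries are inclusive: ratio >= gain cutoff is a gain, ratio <=
    loss cutoff a loss.
    """
    config = config or AnalysisConfig()
    vals = binned.to_numpy(dtype=float)
    states = np.where(
        vals >= config.cna_gain_cutoff,
        "gain",
        np.where(vals <= config.cna_loss_cutoff, "loss", "neutral"),
    )
    return pd.DataFrame(states, index=binned.index, columns=binned.columns)


def group_frequency(
    calls: pd.DataFrame, groups: pd.Series | dict[str, str]
) -> pd.DataFrame:
    """Fraction of samples called gain / loss per bin and group."""
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    groups = groups.loc[[s for s in calls.columns if s in groups.index]]
    rows = []
    for label in groups.unique():
        samples = list(groups.index[groups == label])
        if not samples:
            raise ValueError(f"empty group {label!r}")
        sub = calls[samples]
        rows.append(
            pd.DataFrame(
                {
                    "bin": calls.index,
                    "group": label,
                    "gain_frac": (sub == "gain").mean(axis=1).to_numpy(),
                    "loss_frac": (sub == "loss").mean(axis=1).to_numpy(),
                    "n": len(samples),
                }
            )
        )
    if not rows:
        raise ValueError("no overlap between calls and group labels")
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_cna(
    intensity: IntensityMatrix,
    manifest: ProbeManifest,
    sheet: SampleSheet,
    config: AnalysisConfig | None = None,
    *,
    reference_group: str = "islet",
    query_samples: list[str] | None = None,
) -> tuple[BinTrack, pd.DataFrame, pd.DataFrame]:
    """Bin-level ratios and calls for every query against the normals.

    References default to the islet samples of the sheet. Returns
    (bins, per-bin ratio matrix, per-bin state matrix).
    """
    config = config or AnalysisConfig()
    refs = [s for s in sheet.samples_in_group(reference_group) if s in intensity.sample_ids]
    if len(refs) < 2:
        raise ValueError(f"need >= 2 {reference_group!r} references with intensities")
    if query_samples is None:
        query_samples = [s for s in sheet.tumors if s in intensity.sample_ids]

    df = intensity.data.loc[manifest.probe_ids.intersection(intensity.probe_ids)]
    ref_df = df[refs]
    ratio_cols = {}
    for sid in query_samples:
        ratio_cols[sid] = fit_reference_baseline(df[sid], ref_df)
    ratios = pd.DataFrame(ratio_cols)

    bins = make_bins(manifest.subset(df.index), config)
    binned = bin_ratios(ratios, bins)
    states = call_states(binned, config)
    return bins, binned, states
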