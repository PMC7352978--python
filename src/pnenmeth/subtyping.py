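"""PDX1-region subtyping by hierarchical clustering with bootstrap support.

Samples are clustered on the beta values of the CpGs inside the PDX1
region (chr13:28,480,000-28,510,000 by default) that are shared by the
450K and EPIC platforms, using Euclidean distance and Ward's minimum
variance criterion. Cluster confidence comes from multiscale bootstrap
resampling of probes: bootstrap proportions (BP) are collected at a grid
of resample scales, and the approximately unbiased (AU) support of each
internal edge is obtained by fitting the probit-transformed proportions
to v*sqrt(r) + c/sqrt(r) and extrapolating to scale -1, following the
signed-distance/curvature theory of multiscale bootstrap.

Subtype labels are anchored to references: the top-level cluster that
contains the alpha-cell references is subtype A (PDX1 methylated, worse
prognosis), the one with the beta-cell references subtype B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy import stats

from .arrays_io import AnalysisConfig, ProbeManifest, SampleSheet

logger = logging.getLogger("pnenmeth")

__all__ = [
    "Dendrogram",
    "EdgeSupport",
    "select_region_probes",
    "ward_dendrogram",
    "multiscale_bootstrap_support",
    "assign_subtypes",
]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2))


def select_region_probes(
    manifest: ProbeManifest,
    region: tuple[str, int, int],
    common_probes: Sequence[str] | frozenset[str],
) -> list[str]:
    """Probes inside the region (inclusive bounds) that are on both
    platforms, position-ordered."""
    chrom, start, end = region
    if not start < end:
        raise ValueError("region start must be < end")
    df = manifest.data
    mask = (df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] <= end)
    common = set(common_probes)
    selected = [p for p in df.index[mask] if p in common]
    if not selected:
        raise ValueError(
            f"no probes selected in {chrom}:{start}-{end} after platform intersection"
        )
    return selected


# ---------------------------------------------------------------------------
# Dendrogram
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Binary Ward merge tree over samples.

    Internal nodes are numbered n..2n-2 (scipy linkage convention, with
    n leaves); each has two children, a merge height on the distance
    scale, and the frozenset of leaf sample ids beneath it.
    """

    labels: list[str]
    linkage_matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        Z = self.linkage_matrix
        if Z.shape != (n - 1, 4):
            raise ValueError("linkage matrix shape does not match leaf count")
        leafsets: dict[int, frozenset[str]] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        for k in range(n - 1):
            a, b = int(Z[k, 0]), int(Z[k, 1])
            leafsets[n + k] = leafsets[a] | leafsets[b]
        self._leafsets = leafsets

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    def children(self, node: int) -> tuple[int, int]:
        n = self.n_leaves
        if node < n:
            raise ValueError(f"node {node} is a leaf")
        row = self.linkage_matrix[node - n]
        return int(row[0]), int(row[1])

    def height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else float(self.linkage_matrix[node - n, 2])

    def leaf_set(self, node: int) -> frozenset[str]:
        return self._leafsets[node]

    def internal_nodes(self) -> list[int]:
        return list(range(self.n_leaves, 2 * self.n_leaves - 1))

    def internal_leaf_sets(self) -> dict[int, frozenset[str]]:
        return {k: self._leafsets[k] for k in self.internal_nodes()}

    def root_split(self) -> tuple[tuple[int, frozenset[str]], tuple[int, frozenset[str]]]:
        a, b = self.children(self.root)
        return (a, self.leaf_set(a)), (b, self.leaf_set(b))

    def to_newick(self, support: Mapping[int, "EdgeSupport"] | None = None) -> str:
        def fmt(node: int) -> str:
            if node < self.n_leaves:
                return self.labels[node]
            a, b = self.children(node)
            label = ""
            if support is not None and node in support:
                es = support[node]
                label = f"au{es.au:.3f}_bp{es.bp:.3f}"
            return f"({fmt(a)},{fmt(b)}){label}:{self.height(node):.6f}"

        return fmt(self.root) + ";"


def ward_dendrogram(X: pd.DataFrame) -> Dendrogram:
    """Agglomerate samples (rows of X) by Ward's criterion on Euclidean
    distances; heights are on the distance scale."""
    if X.shape[0] < 2:
        raise ValueError("ward_dendrogram needs >= 2 samples")
    if np.isnan(X.to_numpy(dtype=float)).any():
        raise ValueError("ward_dendrogram requires complete data")
    Z = linkage(X.to_numpy(dtype=float), method="ward")
    return Dendrogram(list(X.index), Z)


# ---------------------------------------------------------------------------
# Multiscale bootstrap
# ---------------------------------------------------------------------------


@dataclass
class EdgeSupport:
    """Bootstrap support of one internal edge.

    ``bp_by_scale`` maps resample scale r to the fraction of bootstrap
    trees containing the identical leaf set; ``bp`` is the proportion at
    r = 1, ``au`` the approximately unbiased support extrapolated from
    the probit fit z(r) = v*sqrt(r) + c/sqrt(r), au = 1 - Phi(v - c).
    """

    node: int
    leaf_set: frozenset[str]
    bp_by_scale: dict[float, float]
    au: float
    bp: float
    v: float
    c: float
    fit_residual: float
    saturated: bool = False
    never_observed: bool = False


def _bootstrap_counts(
    values: np.ndarray,
    labels: list[str],
    target_sets: dict[int, frozenset[str]],
    n_boot: int,
    m: int,
    rng: np.random.Generator,
) -> dict[int, int]:
    """Count, per target node, bootstrap trees containing its leaf set."""
    n, P = values.shape
    counts = {k: 0 for k in target_sets}
    wanted: dict[frozenset[str], list[int]] = {}
    for k, s in target_sets.items():
        wanted.setdefault(s, []).append(k)
    for _ in range(n_boot):
        idx = rng.integers(0, P, size=m)
        Z = linkage(values[:, idx], method="ward")
        sets: list[frozenset[str]] = [frozenset([l]) for l in labels]
        for a, b in Z[:, :2].astype(int):
            sets.append(sets[a] | sets[b])
        for s in sets[n:]:
            if s in wanted:
                for k in wanted[s]:
                    counts[k] += 1
    return counts


def _fit_au(
    bp_by_scale: dict[float, float], n_boot: int
) -> tuple[float, float, float, float, bool]:
    """WLS probit fit across scales -> (au, v, c, residual, saturated).

    Scales where the raw proportion is exactly 0 or 1 carry no gradient
    information and are excluded; if fewer than two informative scales
    remain the edge is saturated and au equals the (rounded) proportion.
    """
    scales = np.array(sorted(bp_by_scale))
    bp = np.array([bp_by_scale[r] for r in scales])
    informative = (bp > 0.0) & (bp < 1.0)
    if informative.sum() < 2:
        sat_val = 1.0 if bp.mean() >= 0.5 else 0.0
        return sat_val, np.nan, np.nan, np.nan, True

    r = scales[informative]
    prop = np.clip(bp[informative], 1.0 / (n_boot + 1), n_boot / (n_boot + 1))
    z = stats.norm.ppf(1.0 - prop)
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    w = n_boot * stats.norm.pdf(z) ** 2 / (prop * (1.0 - prop))
    sw = np.sqrt(w)
    coef, res, *_ = np.linalg.lstsq(sw[:, None] * X, sw * z, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    residual = float(res[0]) if len(res) else 0.0
    au = float(1.0 - stats.norm.cdf(v - c))
    return au, v, c, residual, False


def multiscale_bootstrap_support(
    X: pd.DataFrame,
    dendrogram: Dendrogram,
    n_boot: int = 1000,
    scales: Sequence[float] = DEFAULT_SCALES,
    rng_seed: int = 0,
) -> dict[int, EdgeSupport]:
    """AU/BP support for every internal edge of the dendrogram.

    For each scale r, ``n_boot`` resamples of ceil(r*P) probes (columns)
    are drawn with replacement and reclustered; an edge is supported by
    a resample when the identical leaf set appears in the resampled
    tree. Feature (probe) resampling is deliberate: the object under
    assessment is the clustering of samples.
    """
    values = X.to_numpy(dtype=float)
    labels = list(X.index)
    if labels != dendrogram.labels:
        raise ValueError("X rows must match dendrogram leaves (same order)")
    P = values.shape[1]
    target_sets = dendrogram.internal_leaf_sets()
    # the root is trivially present in every tree; keep it for completeness
    rng = np.random.default_rng(rng_seed)

    bp_tables: dict[int, dict[float, float]] = {k: {} for k in target_sets}
    for r in scales:
        m = max(int(np.ceil(r * P)), 1)
        counts = _bootstrap_counts(values, labels, target_sets, n_boot, m, rng)
        for k in target_sets:
            bp_tables[k][float(r)] = counts[k] / n_boot

    out: dict[int, EdgeSupport] = {}
    r1 = min(scales, key=lambda r: abs(r - 1.0))
    for k, table in bp_tables.items():
        never = all(v == 0.0 for v in table.values())
        if never:
            out[k] = EdgeSupport(
                node=k,
                leaf_set=target_sets[k],
                bp_by_scale=table,
                au=0.0,
                bp=table[float(r1)],
                v=np.nan,
                c=np.nan,
                fit_residual=np.nan,
                saturated=True,
                never_observed=True,
            )
            continue
        au, v, c, res, sat = _fit_au(table, n_boot)
        out[k] = EdgeSupport(
            node=k,
            leaf_set=target_sets[k],
            bp_by_scale=table,
            au=au,
            bp=table[float(r1)],
            v=v,
            c=c,
            fit_residual=res,
            saturated=sat,
        )
    return out


# ---------------------------------------------------------------------------
# Subtype assignment
# ---------------------------------------------------------------------------


def assign_subtypes(
    dendrogram: Dendrogram,
    sheet: SampleSheet,
    support: Mapping[int, EdgeSupport] | None = None,
) -> pd.DataFrame:
    """Cut at the root and label the two clusters by their references.

    The cluster containing all alpha references is subtype A, the one
    containing all beta references subtype B. Tumors inherit the label
    of their cluster. Errors if the references co-cluster or either
    reference type is split across the two clusters.
    """
    (node_a, set_a), (node_b, set_b) = dendrogram.root_split()
    leaves = set_a | set_b
    alphas = {s for s in sheet.samples_in_group("alpha") if s in leaves}
    betas = {s for s in sheet.samples_in_group("beta") if s in leaves}
    if not alphas or not betas:
        raise ValueError("need >= 1 alpha and >= 1 beta reference among clustered samples")

    def side_of(refs: set[str]) -> int | None:
        if refs <= set_a:
            return 0
        if refs <= set_b:
            return 1
        return None

    alpha_side = side_of(alphas)
    beta_side = side_of(betas)
    if alpha_side is None or beta_side is None:
        raise ValueError("references of one type split across both top-level clusters")
    if alpha_side == beta_side:
        raise ValueError("references not separated: alpha and beta co-cluster")

    node_by_subtype = {
        "A": (node_a, set_a) if alpha_side == 0 else (node_b, set_b),
        "B": (node_b, set_b) if alpha_side == 0 else (node_a, set_a),
    }

    rows = []
    tumors = set(sheet.samples_in_group("tumor"))
    for subtype in ("A", "B"):
        node, members = node_by_subtype[subtype]
        au = np.nan
        if support is not None and node in support:
            au = support[node].au
        for sid in sorted(members):
            if sid in tumors:
                rows.append({"sample_id": sid, "subtype": subtype, "cluster_au": au})
    calls = pd.DataFrame(rows).set_index("sample_id").sort_index()
    missing = tumors & set(dendrogram.labels) - set(calls.index)
    if missing:  # cannot happen with a binary root split; defensive
        raise RuntimeError(f"tumors left unassigned: {sorted(missing)}")
    return calls


def subtype_pipeline(
    beta_df: pd.DataFrame,
    manifest: ProbeManifest,
    sheet: SampleSheet,
    config: AnalysisConfig | None = None,
    *,
    with_support: bool = True,
) -> tuple[pd.DataFrame, Dendrogram, dict[int, EdgeSupport] | None]:
    """Convenience wrapper: select region probes, cluster tumors plus
    alpha/beta references, attach support, assign subtypes."""
    from .arrays_io import platform_intersect

    config = config or AnalysisConfig()
    common = platform_intersect(manifest)
    region_probes = select_region_probes(manifest, config.pdx1_region, common)
    samples = (
        sheet.samples_in_group("tumor")
        + sheet.samples_in_group("alpha")
        + sheet.samples_in_group("beta")
    )
    samples = [s for s in samples if s in beta_df.columns]
    X = beta_df.loc[region_probes, samples].T
    dend = ward_dendrogram(X)
    support = None
    if with_support:
        support = multiscale_bootstrap_support(
            X, dend, n_boot=config.n_bootstrap, rng_seed=config.rng_seed
        )
    calls = assign_subtypes(dend, sheet, support)
    return calls, dend, support
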