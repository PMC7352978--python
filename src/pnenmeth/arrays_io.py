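"""Data model and tabular I/O for methylation-array analysis.

Containers wrap pandas DataFrames and enforce the invariants the rest of
the pipeline relies on: a probe manifest with genomic and design
annotation, beta-value and log2-intensity matrices (probes in rows,
samples in columns), and a per-sample sheet with group labels, clinical
covariates and survival. All tabular formats are plain text (TSV/CSV,
optionally gzip-compressed) so cohorts round-trip losslessly.

Coordinates are 1-based inclusive throughout; BED exports (elsewhere)
convert to 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("pnenmeth")

__all__ = [
    "ISLAND_RELATIONS",
    "FEATURES",
    "PROMOTER_FEATURES",
    "GROUPS",
    "ProbeManifest",
    "BetaMatrix",
    "IntensityMatrix",
    "SampleSheet",
    "AnalysisConfig",
    "read_manifest",
    "write_manifest",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_intensity_matrix",
    "write_intensity_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "platform_intersect",
    "chrom_sort_key",
]

# Fixed annotation vocabularies (Illumina-style manifest conventions).
ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")
FEATURES = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "ExonBnd", "3'UTR", "IGR")
# TSS1500 + TSS200 + 5'UTR together are reported as the promoter region.
PROMOTER_FEATURES = ("TSS1500", "TSS200", "5'UTR")
GROUPS = ("tumor", "islet", "alpha", "beta")
PLATFORMS = ("450k", "epic")
DESIGN_TYPES = ("I", "II")
STRANDS = ("+", "-")
WHO_GRADES = ("G1", "G2", "G3", "unknown")
FUNCTIONALITY = (
    "non-functional",
    "insulinoma",
    "gastrinoma",
    "glucagonoma",
    "VIPoma",
    "unknown",
)
YES_NO_UNKNOWN = ("yes", "no", "unknown")
GENDERS = ("F", "M")

MIN_TUMOR_PURITY = 0.60  # tumors at or below this purity are flagged excluded


def chrom_sort_key(chrom: str) -> tuple[int, float, str]:
    """Natural chromosome ordering: chr1 < chr2 < ... < chr22 < chrX < chrY."""
    m = re.fullmatch(r"(?:chr)?(\d+|[XYM]T?)", str(chrom), flags=re.IGNORECASE)
    if m:
        token = m.group(1).upper()
        if token.isdigit():
            return (0, float(token), "")
        special = {"X": 100.0, "Y": 101.0, "M": 102.0, "MT": 102.0}
        return (0, special[token], "")
    return (1, 0.0, str(chrom))


def _sort_by_position(df: pd.DataFrame) -> pd.DataFrame:
    key = df["chrom"].map(chrom_sort_key)
    order = sorted(range(len(df)), key=lambda i: (key.iloc[i], int(df["pos"].iloc[i])))
    return df.iloc[order]


# ---------------------------------------------------------------------------
# Probe manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "strand",
    "design_type",
    "island_relation",
    "feature",
    "gene",
    "on_450k",
    "on_epic",
]


@dataclass
class ProbeManifest:
    """Genomic and design annotation for every CpG probe.

    ``data`` is indexed by probe_id and sorted by (chrom, pos). ``gene``
    may be the empty string for intergenic probes.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "probe_id":
            if "probe_id" in df.columns:
                df = df.set_index("probe_id")
            else:
                raise ValueError("manifest requires a probe_id column or index")
        df = df.copy()
        df["gene"] = df["gene"].fillna("").astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        for col in ("on_450k", "on_epic"):
            df[col] = df[col].astype(bool)

        dup = df.index[df.index.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate probe_id in manifest: {dup[0]!r}")
        if (df["pos"] < 1).any():
            bad = df.index[df["pos"] < 1][0]
            raise ValueError(f"probe {bad!r} has position < 1")
        for col, vocab in (
            ("strand", STRANDS),
            ("design_type", DESIGN_TYPES),
            ("island_relation", ISLAND_RELATIONS),
            ("feature", FEATURES),
        ):
            bad = ~df[col].isin(vocab)
            if bad.any():
                probe = df.index[bad][0]
                raise ValueError(
                    f"probe {probe!r}: unknown {col} value {df.loc[probe, col]!r}"
                )
        orphan = ~(df["on_450k"] | df["on_epic"])
        if orphan.any():
            raise ValueError(
                f"probe {df.index[orphan][0]!r} is on neither platform"
            )
        df = _sort_by_position(df.reset_index()).set_index("probe_id")
        self.data = df

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, probe_ids: Iterable[str]) -> "ProbeManifest":
        keep = self.data.index.intersection(pd.Index(probe_ids))
        return ProbeManifest(self.data.loc[keep].rename_axis("probe_id").reset_index())


def read_manifest(path: str | Path) -> ProbeManifest:
    """Read a probe manifest TSV (plain or gzip)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "gene": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    return ProbeManifest(df[MANIFEST_COLUMNS])


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    out = manifest.data.reset_index()[MANIFEST_COLUMNS].copy()
    out["on_450k"] = out["on_450k"].astype(int)
    out["on_epic"] = out["on_epic"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def platform_intersect(manifest: ProbeManifest) -> list[str]:
    """Probes present on both the 450K and EPIC platforms, position-ordered."""
    df = manifest.data
    return list(df.index[df["on_450k"] & df["on_epic"]])


# ---------------------------------------------------------------------------
# Beta / intensity matrices
# ---------------------------------------------------------------------------

BETA_FLOAT_FORMAT = "%.6f"


@dataclass
class BetaMatrix:
    """Methylation fractions, probes x samples; missing values are NaN."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValueError("duplicate probe ids in beta matrix")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample ids in beta matrix")
        vals = df.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValueError(
                f"beta value {vals[i, j]} outside [0, 1] at probe "
                f"{df.index[i]!r}, sample {df.columns[j]!r}"
            )
        self.data = df.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class IntensityMatrix:
    """log2 total (methylated + unmethylated) intensities, probes x samples."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValueError("duplicate probe ids in intensity matrix")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample ids in intensity matrix")
        vals = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite intensity at probe {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )
        self.data = df.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns


def _read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={0: str})
    first = df.columns[0]
    return df.set_index(first).rename_axis("probe_id")


def read_beta_matrix(path: str | Path, manifest: ProbeManifest) -> BetaMatrix:
    """Read a beta-value TSV, keeping only probes present in the manifest."""
    df = _read_matrix(path)
    keep = df.index.isin(manifest.probe_ids)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("read_beta_matrix: dropped %d probes absent from manifest", n_dropped)
    df = df.loc[keep]
    if df.empty:
        raise ValueError(f"beta matrix {path} shares no probes with the manifest")
    return BetaMatrix(df)


def write_beta_matrix(beta: BetaMatrix, path: str | Path) -> None:
    beta.data.to_csv(path, sep="\t", na_rep="NA", float_format=BETA_FLOAT_FORMAT)


def read_intensity_matrix(path: str | Path, manifest: ProbeManifest) -> IntensityMatrix:
    df = _read_matrix(path)
    keep = df.index.isin(manifest.probe_ids)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "read_intensity_matrix: dropped %d probes absent from manifest", n_dropped
        )
    df = df.loc[keep]
    if df.empty:
        raise ValueError(f"intensity matrix {path} shares no probes with the manifest")
    return IntensityMatrix(df)


def write_intensity_matrix(intensity: IntensityMatrix, path: str | Path) -> None:
    intensity.data.to_csv(path, sep="\t", float_format="%.6f")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

SHEET_COLUMNS = [
    "sample_id",
    "group",
    "platform",
    "adm_mutated",
    "who_grade",
    "functionality",
    "lvi",
    "distant_metastasis",
    "recurrence",
    "gender",
    "age",
    "tumor_size",
    "os_time",
    "os_event",
    "tumor_purity",
]

_CATEGORICAL_VOCABS = {
    "group": GROUPS,
    "platform": PLATFORMS,
    "adm_mutated": YES_NO_UNKNOWN,
    "who_grade": WHO_GRADES,
    "functionality": FUNCTIONALITY,
    "lvi": YES_NO_UNKNOWN,
    "distant_metastasis": YES_NO_UNKNOWN,
    "recurrence": YES_NO_UNKNOWN,
}


@dataclass
class SampleSheet:
    """Per-sample group, clinical covariates and survival.

    Tumors whose purity fails the >60% requirement are flagged in the
    ``excluded`` column rather than silently dropped; unknown categorical
    values are normalized to the string ``"unknown"`` and unknown numeric
    values to NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                raise ValueError("sample sheet requires a sample_id column or index")
        df = df.copy()
        dup = df.index[df.index.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample_id in sheet: {dup[0]!r}")
        for col, vocab in _CATEGORICAL_VOCABS.items():
            if "unknown" in vocab:
                df[col] = df[col].fillna("unknown")
            df[col] = df[col].astype(str)
            bad = ~df[col].isin(vocab)
            if bad.any():
                sid = df.index[bad][0]
                raise ValueError(
                    f"sample {sid!r}: unknown {col} value {df.loc[sid, col]!r}"
                )
        bad_gender = ~(df["gender"].isin(GENDERS) | df["gender"].isna())
        if bad_gender.any():
            sid = df.index[bad_gender][0]
            raise ValueError(f"sample {sid!r}: unknown gender {df.loc[sid, 'gender']!r}")
        for col in ("age", "tumor_size", "os_time", "tumor_purity"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        df["os_event"] = pd.to_numeric(df["os_event"], errors="raise")

        if (df["os_time"].dropna() < 0).any():
            raise ValueError("negative os_time in sample sheet")
        inconsistent = (df["os_event"] == 1) & df["os_time"].isna()
        if inconsistent.any():
            raise ValueError(
                f"sample {df.index[inconsistent][0]!r}: os_event=1 with missing os_time"
            )

        is_tumor = df["group"] == "tumor"
        df["excluded"] = is_tumor & (df["tumor_purity"] <= MIN_TUMOR_PURITY)
        if df["excluded"].any():
            logger.warning(
                "sample sheet: %d tumor(s) flagged excluded for purity <= %.2f",
                int(df["excluded"].sum()),
                MIN_TUMOR_PURITY,
            )
        self.data = df

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def samples_in_group(self, group: str, include_excluded: bool = False) -> list[str]:
        df = self.data
        mask = df["group"] == group
        if not include_excluded:
            mask &= ~df["excluded"]
        return list(df.index[mask])

    @property
    def tumors(self) -> list[str]:
        return self.samples_in_group("tumor")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet CSV; empty cells and "NA" denote unknown."""
    df = pd.read_csv(path, na_values=["NA", ""], dtype={"sample_id": str})
    missing = set(SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns: {sorted(missing)}")
    return SampleSheet(df[SHEET_COLUMNS])


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    out = sheet.data.reset_index()[SHEET_COLUMNS]
    out.to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline.

    Defaults follow the published analysis choices: BH-adjusted p <= 0.05
    for significance, |delta beta| > 0.3 highlighted, DMRs require >= 3
    probes, 1000 bootstrap replicates for cluster support, the PDX1 region
    chr13:28,480,000-28,510,000, CNA gain/loss cutoffs at +-0.150 log2 and
    50 kb minimum bins.
    """

    adj_p_cutoff: float = 0.05
    delta_beta_highlight: float = 0.3
    dmr_min_probes: int = 3
    n_bootstrap: int = 1000
    pdx1_region: tuple[str, int, int] = ("chr13", 28_480_000, 28_510_000)
    cna_gain_cutoff: float = 0.150
    cna_loss_cutoff: float = -0.150
    cna_min_bin_bp: int = 50_000
    cna_min_bin_probes: int = 15
    mds_top_n: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.adj_p_cutoff < 1):
            raise ValueError("adj_p_cutoff must be in (0, 1)")
        if not (self.cna_gain_cutoff > 0 > self.cna_loss_cutoff):
            raise ValueError("require cna_gain_cutoff > 0 > cna_loss_cutoff")
        chrom, start, end = self.pdx1_region
        if not start < end:
            raise ValueError("pdx1_region start must be < end")
        self.pdx1_region = (str(chrom), int(start), int(end))
        if self.dmr_min_probes < 1:
            raise ValueError("dmr_min_probes must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["pdx1_region"] = list(self.pdx1_region)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
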