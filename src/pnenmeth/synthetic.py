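"""Synthetic two-subtype tumor cohorts with alpha/beta/islet references.

The generator emulates the statistical structure the pipeline assumes:

* a probe manifest whose probes sit in dense CpG clusters (tens to
  hundreds of bp apart) separated by multi-kb gaps, as on real arrays,
  with a contiguous block of probes inside a configurable PDX1-like
  region on chr13;
* beta values drawn from beta distributions around trimodal baselines
  (unmethylated ~0.1, intermediate ~0.5, methylated ~0.85), with
  PDX1-region probes methylated in alpha references and subtype-A tumors
  and unmethylated in beta references and subtype-B tumors;
* implanted tumor-vs-islet DMPs (85% hypomethylated by default) and
  DMRs as runs of consecutive shifted probes;
* log2 intensities carrying whole-chromosome copy-number shifts per
  subtype; and
* exponential survival with a configurable subtype-B hazard ratio
  (default 0.22) under independent exponential censoring.

Randomness uses one global seed feeding a fixed counter-based stream per
stage, so adding a stage never perturbs earlier draws and identical
configurations yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .arrays_io import (
    FEATURES,
    ISLAND_RELATIONS,
    BetaMatrix,
    IntensityMatrix,
    ProbeManifest,
    SampleSheet,
    chrom_sort_key,
    write_beta_matrix,
    write_intensity_matrix,
    write_manifest,
    write_sample_sheet,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_manifest",
    "simulate_methylation",
    "simulate_clinical",
    "simulate_cohort",
    "write_cohort",
]

# Fixed sub-stream identifiers (counter-based seeding).
_STAGE_MANIFEST = 1
_STAGE_METHYLATION = 2
_STAGE_CLINICAL = 3
_STAGE_INTENSITY = 4

# Baseline methylation states and their cohort-level mixing proportions;
# arrays are strongly bimodal with a small intermediate fraction.
_STATE_MEANS = (0.10, 0.50, 0.85)
_STATE_PROBS = (0.45, 0.10, 0.45)

# Annotation proportions approximating array composition.
_ISLAND_PROBS = (0.30, 0.23, 0.11, 0.36)
_FEATURE_PROBS = (0.14, 0.10, 0.12, 0.04, 0.36, 0.02, 0.04, 0.18)

# Clinicopathological frequencies per subtype, patterned on the published
# cohort (counts per subtype; complete-case denominators).
_CLIN_A = {
    "gender_f": 25 / 57,
    "grade": {"G1": 27 / 52, "G2": 22 / 52, "G3": 3 / 52},
    "functionality": {
        "gastrinoma": 1 / 52,
        "glucagonoma": 1 / 52,
        "insulinoma": 2 / 52,
        "non-functional": 46 / 52,
        "VIPoma": 2 / 52,
    },
    "lvi": 31 / 45,
    "distant_metastasis": 21 / 53,
    "recurrence": 13 / 27,
    "age": (57.1, 12.1),
    "tumor_size": (4.4, 2.6),
}
_CLIN_B = {
    "gender_f": 13 / 21,
    "grade": {"G1": 12 / 20, "G2": 8 / 20, "G3": 0.0},
    "functionality": {
        "gastrinoma": 1 / 20,
        "glucagonoma": 0.0,
        "insulinoma": 6 / 20,
        "non-functional": 13 / 20,
        "VIPoma": 0.0,
    },
    "lvi": 5 / 13,
    "distant_metastasis": 2 / 20,
    "recurrence": 0.0,
    "age": (53.1, 15.0),
    "tumor_size": (3.77, 3.2),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Cohort sizes default to the published study design (62 subtype-A and
    21 subtype-B tumors, 5 islets, 2 alpha and 3 beta references).
    ``beta_concentration`` is the precision of the beta-distributed noise
    (100 gives sd ~0.05 at intermediate methylation). ``hr_B_vs_A``
    defaults to the reported subtype-B hazard ratio of 0.22; the baseline
    hazard ln(2)/11.9 per year puts the subtype-A median survival at the
    reported 11.9 years, and censoring at 0.02/year yields roughly 30%
    censored observations overall.
    """

    n_tumors_A: int = 62
    n_tumors_B: int = 21
    n_islets: int = 5
    n_alpha: int = 2
    n_beta: int = 3
    n_probes: int = 11_000
    n_chromosomes: int = 22
    pdx1_region: tuple[str, int, int] = ("chr13", 28_480_000, 28_510_000)
    pdx1_n_probes: int = 10
    pdx1_separation: float = 0.7
    frac_dmp: float = 0.05
    delta_beta_effect: float = 0.3
    frac_hypo: float = 0.85
    n_dmrs: int = 5
    dmr_n_probes: int = 5
    dmr_span_bp: int = 2_000
    beta_concentration: float = 100.0
    typeII_compression: float = 1.0
    intensity_baseline: float = 13.0
    intensity_noise_sd: float = 0.15
    sample_offset_sd: float = 0.10
    cna_events_A: tuple[tuple[str, str, float], ...] = (
        ("chr6", "loss", -0.3),
        ("chr11", "loss", -0.3),
        ("chr5", "gain", 0.3),
    )
    cna_events_B: tuple[tuple[str, str, float], ...] = (
        ("chr6", "gain", 0.3),
        ("chr8", "gain", 0.3),
        ("chr11", "loss", -0.3),
    )
    hr_B_vs_A: float = 0.22
    baseline_hazard: float = float(np.log(2) / 11.9)
    censor_rate: float = 0.02
    p_adm_given_A: float = 38 / 48
    p_adm_given_B: float = 2 / 15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumors_A", "n_tumors_B", "n_islets", "n_alpha", "n_beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.frac_dmp < 1):
            raise ValueError("frac_dmp must be in [0, 1)")
        if self.n_dmrs > 0 and self.dmr_n_probes < 3:
            raise ValueError("dmr_n_probes must be >= 3")
        if self.hr_B_vs_A <= 0:
            raise ValueError("hr_B_vs_A must be > 0")
        if self.beta_concentration <= 2:
            raise ValueError("beta_concentration must exceed 2")

    def _rng(self, stage: int) -> np.random.Generator:
        seq = np.random.SeedSequence(entropy=self.rng_seed, spawn_key=(stage,))
        return np.random.default_rng(seq)


@dataclass
class GroundTruth:
    """What was implanted, keyed by the same ids as the emitted matrices."""

    subtype: dict[str, str]  # tumor sample_id -> "A" / "B"
    dmp_effects: dict[str, float]  # probe_id -> signed implanted delta beta
    dmr_regions: list[dict]  # chrom/start/end/probe_ids/effect
    cna_segments: dict[str, list[dict]] = field(default_factory=dict)
    survival: dict[str, float] = field(default_factory=dict)
    sample_ids: dict[str, list[str]] = field(default_factory=dict)
    baseline_means: pd.Series | None = None
    manifest: ProbeManifest | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subtype": self.subtype,
            "dmp_effects": self.dmp_effects,
            "dmr_regions": self.dmr_regions,
            "cna_segments": self.cna_segments,
            "survival": self.survival,
            "sample_ids": self.sample_ids,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


def simulate_manifest(cfg: SimulationConfig) -> ProbeManifest:
    """Generate a probe manifest with clustered CpG geometry.

    Probes are laid out in clusters of 1-10 probes spaced 30-200 bp
    apart, with 2-20 kb between clusters; annotation is drawn per
    cluster. A contiguous block of ``pdx1_n_probes`` probes is placed
    evenly across the configured PDX1-like region on its chromosome.
    All probes are flagged on both platforms.
    """
    if cfg.pdx1_n_probes == 0:
        raise ValueError("pdx1_n_probes must be > 0 (subtyping needs region probes)")
    rng = cfg._rng(_STAGE_MANIFEST)

    region_chrom, region_start, region_end = cfg.pdx1_region
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    if region_chrom not in chroms:
        chroms[-1] = region_chrom  # guarantee the region chromosome exists

    per_chrom = np.full(len(chroms), cfg.n_probes // len(chroms), dtype=int)
    per_chrom[: cfg.n_probes % len(chroms)] += 1

    rows: list[tuple] = []
    probe_counter = 0
    for chrom, quota in zip(chroms, per_chrom):
        pos = 10_000
        placed = 0
        cluster_idx = 0
        while placed < quota:
            size = min(int(rng.integers(1, 11)), quota - placed)
            island = str(rng.choice(ISLAND_RELATIONS, p=_ISLAND_PROBS))
            feat = str(rng.choice(FEATURES, p=_FEATURE_PROBS))
            gene = "" if feat == "IGR" else f"G{chrom[3:]}_{cluster_idx}"
            for _ in range(size):
                probe_counter += 1
                rows.append(
                    (
                        f"cg{probe_counter:08d}",
                        chrom,
                        pos,
                        str(rng.choice(["+", "-"])),
                        str(rng.choice(["I", "II"])),
                        island,
                        feat,
                        gene,
                        True,
                        True,
                    )
                )
                pos += int(rng.integers(30, 201))
                placed += 1
            pos += int(rng.integers(2_000, 20_001))
            cluster_idx += 1

    # PDX1-like block: evenly spaced probes inside the configured region.
    offsets = np.linspace(region_start, region_end, cfg.pdx1_n_probes + 2)[1:-1]
    for k, p in enumerate(offsets):
        probe_counter += 1
        rows.append(
            (
                f"cg{probe_counter:08d}",
                region_chrom,
                int(p),
                "+",
                "II" if k % 2 else "I",
                "Island",
                "TSS1500",
                "PDX1",
                True,
                True,
            )
        )

    df = pd.DataFrame(
        rows,
        columns=[
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
        ],
    )
    return ProbeManifest(df)


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------


def _beta_noise(rng: np.random.Generator, means: np.ndarray, concentration: float) -> np.ndarray:
    a = np.clip(means, 1e-3, 1 - 1e-3) * concentration
    b = concentration - a
    return rng.beta(a, b)


def _pdx1_probe_mask(cfg: SimulationConfig, manifest: ProbeManifest) -> pd.Series:
    chrom, start, end = cfg.pdx1_region
    df = manifest.data
    return (df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] <= end)


def simulate_methylation(
    cfg: SimulationConfig, manifest: ProbeManifest
) -> tuple[BetaMatrix, GroundTruth]:
    """Draw the beta-value matrix and record what was implanted.

    PDX1-region probes get mean 0.5 + separation/2 in alpha references
    and subtype-A tumors and 0.5 - separation/2 in beta references and
    subtype-B tumors (islets, a beta-dominant mixture, sit at 0.35).
    DMP shifts of +-delta_beta_effect are applied in all tumors relative
    to islets, on probes whose baseline accommodates the full shift.
    """
    rng = cfg._rng(_STAGE_METHYLATION)
    probes = manifest.probe_ids
    n_probes = len(probes)

    sample_ids = {
        "tumor": [f"tumor_{i + 1:03d}" for i in range(cfg.n_tumors_A + cfg.n_tumors_B)],
        "islet": [f"islet_{i + 1:02d}" for i in range(cfg.n_islets)],
        "alpha": [f"alpha_{i + 1:02d}" for i in range(cfg.n_alpha)],
        "beta": [f"beta_{i + 1:02d}" for i in range(cfg.n_beta)],
    }
    subtype = {
        sid: ("A" if i < cfg.n_tumors_A else "B")
        for i, sid in enumerate(sample_ids["tumor"])
    }

    # Baseline state per probe.
    state = rng.choice(3, size=n_probes, p=_STATE_PROBS)
    baseline = np.array(_STATE_MEANS)[state].astype(float)

    pdx1_mask = _pdx1_probe_mask(cfg, manifest).to_numpy()

    # --- implant DMPs ------------------------------------------------------
    delta = cfg.delta_beta_effect
    n_dmp = int(round(cfg.frac_dmp * n_probes))
    dmp_effects: dict[str, float] = {}
    dmr_regions: list[dict] = []
    eligible = np.flatnonzero(~pdx1_mask)

    if cfg.n_dmrs > 0 and n_dmp < 1:
        raise ValueError("n_dmrs > 0 requires frac_dmp * n_probes >= 1")

    if n_dmp > 0 and delta > 0:
        # DMRs first: whole probe clusters are shifted as units (CpG
        # islands move together), so region truth coincides with what a
        # within-cluster smoother can recover. Clusters of exactly
        # dmr_n_probes are preferred, larger ones used as fallback.
        df = manifest.data
        chrom_arr = df["chrom"].to_numpy()
        pos_arr = df["pos"].to_numpy()
        exact_runs: list[np.ndarray] = []
        larger_runs: list[np.ndarray] = []
        i = 0
        while i < n_probes:
            j = i
            while (
                j + 1 < n_probes
                and chrom_arr[j + 1] == chrom_arr[j]
                and pos_arr[j + 1] - pos_arr[j] <= 300
            ):
                j += 1
            if j - i + 1 >= cfg.dmr_n_probes and not pdx1_mask[i : j + 1].any():
                run = np.arange(i, j + 1)
                (exact_runs if len(run) == cfg.dmr_n_probes else larger_runs).append(run)
            i = j + 1
        run_starts = exact_runs + larger_runs
        if cfg.n_dmrs > len(run_starts):
            raise ValueError(
                f"manifest supports only {len(run_starts)} DMR-capable runs; "
                f"{cfg.n_dmrs} requested"
            )
        n_exact = min(cfg.n_dmrs, len(exact_runs))
        chosen_idx = list(rng.choice(len(exact_runs), size=n_exact, replace=False)) if n_exact else []
        chosen_runs = [exact_runs[k] for k in sorted(chosen_idx)]
        if cfg.n_dmrs > n_exact:
            extra = rng.choice(len(larger_runs), size=cfg.n_dmrs - n_exact, replace=False)
            chosen_runs += [larger_runs[k] for k in sorted(extra)]
        dmr_probe_idx: set[int] = set()
        for run in chosen_runs:
            sign = -1.0 if rng.random() < cfg.frac_hypo else 1.0
            # force a baseline that accommodates the full shift
            baseline[run] = 0.5 if rng.random() < 0.5 else (0.85 if sign < 0 else 0.10)
            for idx in run:
                dmp_effects[probes[idx]] = sign * delta
                dmr_probe_idx.add(int(idx))
            dmr_regions.append(
                {
                    "chrom": str(chrom_arr[run[0]]),
                    "start": int(pos_arr[run[0]]),
                    "end": int(pos_arr[run[-1]]),
                    "probe_ids": [probes[idx] for idx in run],
                    "effect": sign * delta,
                }
            )

        # Isolated DMPs for the remainder.
        n_single = max(n_dmp - len(dmp_effects), 0)
        pool = np.setdiff1d(eligible, np.fromiter(dmr_probe_idx, int, len(dmr_probe_idx)))
        signs = np.where(rng.random(n_single) < cfg.frac_hypo, -1.0, 1.0)
        margin = 0.02
        hypo_ok = pool[baseline[pool] - delta >= margin]
        hyper_ok = pool[baseline[pool] + delta <= 1 - margin]
        n_hypo = int((signs < 0).sum())
        n_hyper = n_single - n_hypo
        if n_hypo > len(hypo_ok) or n_hyper > len(hyper_ok):
            raise ValueError("not enough probes to implant the requested DMPs")
        chosen_hypo = rng.choice(hypo_ok, size=n_hypo, replace=False)
        remaining = np.setdiff1d(hyper_ok, chosen_hypo)
        chosen_hyper = rng.choice(remaining, size=n_hyper, replace=False)
        for idx in chosen_hypo:
            dmp_effects[probes[idx]] = -delta
        for idx in chosen_hyper:
            dmp_effects[probes[idx]] = delta

    effect_vec = np.zeros(n_probes)
    for pid, eff in dmp_effects.items():
        effect_vec[probes.get_loc(pid)] = eff

    # --- per-group mean profiles -------------------------------------------
    hi = 0.5 + cfg.pdx1_separation / 2.0
    lo = 0.5 - cfg.pdx1_separation / 2.0

    all_samples = (
        sample_ids["tumor"] + sample_ids["islet"] + sample_ids["alpha"] + sample_ids["beta"]
    )
    means = np.empty((n_probes, len(all_samples)))
    for j, sid in enumerate(all_samples):
        mu = baseline.copy()
        if sid in subtype:  # tumor
            mu = mu + effect_vec
            mu[pdx1_mask] = hi if subtype[sid] == "A" else lo
        elif sid.startswith("islet"):
            mu[pdx1_mask] = 0.35
        elif sid.startswith("alpha"):
            mu[pdx1_mask] = hi
        else:  # beta reference
            mu[pdx1_mask] = lo
        means[:, j] = np.clip(mu, 0.02, 0.98)

    values = _beta_noise(rng, means, cfg.beta_concentration)

    # Type II dynamic-range compression toward 0.5.
    type2 = (manifest.data["design_type"] == "II").to_numpy()
    if cfg.typeII_compression != 1.0:
        values[type2, :] = 0.5 + cfg.typeII_compression * (values[type2, :] - 0.5)

    beta = BetaMatrix(pd.DataFrame(values, index=probes, columns=all_samples))
    truth = GroundTruth(
        subtype=subtype,
        dmp_effects=dmp_effects,
        dmr_regions=dmr_regions,
        sample_ids=sample_ids,
        baseline_means=pd.Series(baseline, index=probes),
        manifest=manifest,
    )
    return beta, truth


# ---------------------------------------------------------------------------
# Clinical covariates, survival, intensities
# ---------------------------------------------------------------------------


def _draw_categorical(rng: np.random.Generator, probs: dict[str, float]) -> str:
    labels = list(probs)
    p = np.array([probs[l] for l in labels], dtype=float)
    rest = 1.0 - p.sum()
    if rest > 1e-9:
        labels.append("unknown")
        p = np.append(p, rest)
    p = p / p.sum()
    return str(rng.choice(labels, p=p))


def simulate_clinical(
    cfg: SimulationConfig, truth: GroundTruth
) -> tuple[SampleSheet, IntensityMatrix]:
    """Draw the sample sheet and the log2-intensity matrix.

    Covariate frequencies are subtype-conditional (patterned on the
    published cohort); survival is exponential with hazard
    baseline_hazard * hr_B_vs_A for subtype B, censored by an independent
    exponential clock. Intensities are a flat log2 baseline plus
    per-sample and per-probe noise, with each subtype's chromosome-scale
    shifts added to every probe of the affected chromosome; references
    carry no shifts.
    """
    if truth.manifest is None:
        raise ValueError("GroundTruth lacks its manifest; run simulate_methylation first")
    rng = cfg._rng(_STAGE_CLINICAL)
    manifest = truth.manifest

    rows = []
    for sid in truth.sample_ids["tumor"]:
        st = truth.subtype[sid]
        prof = _CLIN_A if st == "A" else _CLIN_B
        p_adm = cfg.p_adm_given_A if st == "A" else cfg.p_adm_given_B
        hazard = cfg.baseline_hazard * (cfg.hr_B_vs_A if st == "B" else 1.0)
        t_event = rng.exponential(1.0 / hazard)
        if cfg.censor_rate > 0:
            t_cens = rng.exponential(1.0 / cfg.censor_rate)
        else:
            t_cens = np.inf
        os_time = min(t_event, t_cens)
        os_event = int(t_event <= t_cens)
        age_mu, age_sd = prof["age"]
        size_mu, size_sd = prof["tumor_size"]
        rows.append(
            {
                "sample_id": sid,
                "group": "tumor",
                "platform": "epic",
                "adm_mutated": "yes" if rng.random() < p_adm else "no",
                "who_grade": _draw_categorical(rng, prof["grade"]),
                "functionality": _draw_categorical(rng, prof["functionality"]),
                "lvi": "yes" if rng.random() < prof["lvi"] else "no",
                "distant_metastasis": (
                    "yes" if rng.random() < prof["distant_metastasis"] else "no"
                ),
                "recurrence": "yes" if rng.random() < prof["recurrence"] else "no",
                "gender": "F" if rng.random() < prof["gender_f"] else "M",
                "age": round(float(rng.normal(age_mu, age_sd)), 1),
                "tumor_size": round(float(max(rng.normal(size_mu, size_sd), 0.3)), 1),
                "os_time": round(float(os_time), 4),
                "os_event": os_event,
                "tumor_purity": round(float(rng.uniform(0.65, 0.95)), 2),
            }
        )
    for group in ("islet", "alpha", "beta"):
        for sid in truth.sample_ids[group]:
            rows.append(
                {
                    "sample_id": sid,
                    "group": group,
                    "platform": "epic",
                    "adm_mutated": "unknown",
                    "who_grade": "unknown",
                    "functionality": "unknown",
                    "lvi": "unknown",
                    "distant_metastasis": "unknown",
                    "recurrence": "unknown",
                    "gender": "F" if rng.random() < 0.5 else "M",
                    "age": round(float(rng.normal(59, 4)), 1),
                    "tumor_size": np.nan,
                    "os_time": np.nan,
                    "os_event": 0,
                    "tumor_purity": np.nan,
                }
            )
    sheet = SampleSheet(pd.DataFrame(rows))
    truth.survival = {
        "hr_B_vs_A": cfg.hr_B_vs_A,
        "baseline_hazard": cfg.baseline_hazard,
        "censor_rate": cfg.censor_rate,
    }

    # --- intensities --------------------------------------------------------
    rng_i = cfg._rng(_STAGE_INTENSITY)
    probes = manifest.probe_ids
    chrom_arr = manifest.data["chrom"].to_numpy()
    all_samples = list(sheet.sample_ids)
    vals = np.empty((len(probes), len(all_samples)))
    cna_segments: dict[str, list[dict]] = {}
    chrom_spans = {
        c: (int(g["pos"].min()), int(g["pos"].max()))
        for c, g in manifest.data.groupby("chrom")
    }
    for j, sid in enumerate(all_samples):
        col = (
            cfg.intensity_baseline
            + rng_i.normal(0.0, cfg.sample_offset_sd)
            + rng_i.normal(0.0, cfg.intensity_noise_sd, size=len(probes))
        )
        segs: list[dict] = []
        if sid in truth.subtype:
            events = cfg.cna_events_A if truth.subtype[sid] == "A" else cfg.cna_events_B
            for chrom, direction, shift in events:
                if chrom not in chrom_spans:
                    continue
                mask = chrom_arr == chrom
                col[mask] += shift
                start, end = chrom_spans[chrom]
                segs.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "direction": direction,
                        "log2_shift": shift,
                    }
                )
        cna_segments[sid] = segs
        vals[:, j] = col
    truth.cna_segments = cna_segments

    intensity = IntensityMatrix(pd.DataFrame(vals, index=probes, columns=all_samples))
    return sheet, intensity


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[ProbeManifest, BetaMatrix, IntensityMatrix, SampleSheet, GroundTruth]:
    """Run all three generator stages under one configuration."""
    manifest = simulate_manifest(cfg)
    beta, truth = simulate_methylation(cfg, manifest)
    sheet, intensity = simulate_clinical(cfg, truth)
    return manifest, beta, intensity, sheet, truth


def write_cohort(cfg: SimulationConfig, outdir: str | Path) -> None:
    """Write manifest.tsv, beta.tsv, intensity.tsv, samples.csv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest, beta, intensity, sheet, truth = simulate_cohort(cfg)
    write_manifest(manifest, outdir / "manifest.tsv")
    write_beta_matrix(beta, outdir / "beta.tsv")
    write_intensity_matrix(intensity, outdir / "intensity.tsv")
    write_sample_sheet(sheet, outdir / "samples.csv")
    truth.to_json(outdir / "truth.json")
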