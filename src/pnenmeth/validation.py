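"""Simulation studies that quantify what the pipeline recovers.

Each study generates cohorts with the synthetic module, runs the
corresponding analysis stage, and summarizes recovery or error control
as a few scalars. Problem sizes are chosen so the full battery runs in
minutes on one core; the cohort conditions (effect sizes, noise,
sample counts) are the documented study conditions, not tuning knobs.

The printed contingency tables of the published cohort are carried here
as inputs for the exact-test checks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize_scalar

from .arrays_io import AnalysisConfig
from .clinstats import coxph_fit, fisher_exact
from .differential import dmp_test, dmr_bumphunter
from .subtyping import (
    assign_subtypes,
    multiscale_bootstrap_support,
    select_region_probes,
    ward_dendrogram,
)
from .synthetic import SimulationConfig, simulate_clinical, simulate_manifest, simulate_methylation

__all__ = [
    "TABLE1_CONTINGENCY",
    "table1_fisher",
    "subtype_recovery_study",
    "bootstrap_consistency_study",
    "dmp_error_study",
    "dmr_recovery_study",
    "dmr_null_study",
    "cna_recovery_study",
    "cox_recovery_study",
    "cox_toy_check",
]

# Published-cohort contingency tables (counts per subtype A, B).
TABLE1_CONTINGENCY = {
    "mutation": [[10, 13], [38, 2]],  # A-D-M wild type / mutated
    "functionality": [[1, 1], [1, 0], [2, 6], [46, 13], [2, 0]],
    "distant_metastasis": [[32, 18], [21, 2]],
    "recurrence": [[14, 16], [13, 0]],
    "gender": [[25, 13], [32, 8]],
    "who_grade": [[27, 12], [22, 8], [3, 0]],
}


def _child_seed(seed: int, *tags: int) -> int:
    """Derived sub-stream seed, kept below 2**31."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(tags))
    return int(ss.generate_state(1)[0] % (2**31))


def table1_fisher() -> dict[str, float]:
    """Exact two-sided p-values for the printed contingency tables."""
    return {name: fisher_exact(tab) for name, tab in TABLE1_CONTINGENCY.items()}


# ---------------------------------------------------------------------------
# Subtype recovery (clustering + AU support)
# ---------------------------------------------------------------------------


@dataclass
class SubtypeStudyResult:
    n_seeds: int
    perfect_recovery_seeds: int
    recovery_fraction: float  # over all tumors, all seeds
    min_cluster_au: float  # worst top-level AU seen across seeds
    n_tumors: int


def subtype_recovery_study(
    n_seeds: int = 20,
    *,
    n_tumors_a: int = 20,
    n_tumors_b: int = 20,
    separation: float = 0.7,
    n_boot: int = 1000,
    with_support: bool = True,
    seed: int = 0,
) -> SubtypeStudyResult:
    """Label recovery and top-level AU over seeded cohorts.

    Conditions: PDX1-region separation 0.7, beta noise sd ~0.05
    (concentration 100), 2 alpha + 3 beta references.
    """
    perfect = 0
    recovered = 0
    total = 0
    min_au = 1.0
    for s in range(n_seeds):
        cfg = SimulationConfig(
            n_tumors_A=n_tumors_a,
            n_tumors_B=n_tumors_b,
            n_islets=2,
            n_probes=300,
            n_chromosomes=4,
            pdx1_n_probes=10,
            pdx1_separation=separation,
            frac_dmp=0.0,
            n_dmrs=0,
            rng_seed=_child_seed(seed, 1, s),
        )
        manifest = simulate_manifest(cfg)
        beta, truth = simulate_methylation(cfg, manifest)
        sheet, _ = simulate_clinical(cfg, truth)

        region = select_region_probes(
            manifest, cfg.pdx1_region, set(manifest.probe_ids)
        )
        samples = (
            truth.sample_ids["tumor"] + truth.sample_ids["alpha"] + truth.sample_ids["beta"]
        )
        X = beta.data.loc[region, samples].T
        dend = ward_dendrogram(X)
        support = None
        if with_support:
            support = multiscale_bootstrap_support(
                X, dend, n_boot=n_boot, rng_seed=_child_seed(seed, 2, s)
            )
            (na, _), (nb, _) = dend.root_split()
            min_au = min(min_au, support[na].au, support[nb].au)
        calls = assign_subtypes(dend, sheet, support)
        hits = sum(
            calls.loc[sid, "subtype"] == truth.subtype[sid] for sid in calls.index
        )
        recovered += hits
        total += len(calls)
        if hits == len(calls):
            perfect += 1
    return SubtypeStudyResult(
        n_seeds=n_seeds,
        perfect_recovery_seeds=perfect,
        recovery_fraction=recovered / total,
        min_cluster_au=min_au if with_support else float("nan"),
        n_tumors=n_tumors_a + n_tumors_b,
    )


# ---------------------------------------------------------------------------
# Multiscale-bootstrap consistency
# ---------------------------------------------------------------------------


@dataclass
class BootstrapConsistencyResult:
    n_edges: int
    n_boot: int
    max_abs_se_units: float  # max |bp_multiscale - bp_plain| / SE(diff)


def bootstrap_consistency_study(
    *, n_samples: int = 10, n_probes: int = 30, n_boot: int = 1000, seed: int = 0
) -> BootstrapConsistencyResult:
    """bp at scale 1 vs an independently coded plain bootstrap.

    The sample matrix mixes two weakly separated groups so the tree has
    edges across the full support range.
    """
    rng = np.random.default_rng(_child_seed(seed, 10))
    half = n_samples // 2
    means = np.r_[np.zeros(half), np.full(n_samples - half, 0.8)]
    X = rng.normal(means[:, None], 1.0, size=(n_samples, n_probes))
    Xdf = pd.DataFrame(X, index=[f"s{i}" for i in range(n_samples)])

    dend = ward_dendrogram(Xdf)
    support = multiscale_bootstrap_support(
        Xdf, dend, n_boot=n_boot, scales=(1.0,), rng_seed=_child_seed(seed, 11)
    )

    # independent plain bootstrap, coded inline
    targets = dend.internal_leaf_sets()
    counts = {k: 0 for k in targets}
    rng2 = np.random.default_rng(_child_seed(seed, 12))
    labels = list(Xdf.index)
    for _ in range(n_boot):
        idx = rng2.integers(0, n_probes, size=n_probes)
        Z = linkage(X[:, idx], method="ward")
        sets = [frozenset([l]) for l in labels]
        for a, b in Z[:, :2].astype(int):
            sets.append(sets[int(a)] | sets[int(b)])
        found = set(sets[n_samples:])
        for k, s in targets.items():
            if s in found:
                counts[k] += 1

    worst = 0.0
    for k in targets:
        bp1 = support[k].bp
        bp2 = counts[k] / n_boot
        pooled = np.clip((bp1 + bp2) / 2.0, 1.0 / (n_boot + 1), n_boot / (n_boot + 1))
        se = np.sqrt(2.0 * pooled * (1.0 - pooled) / n_boot)
        worst = max(worst, abs(bp1 - bp2) / se)
    return BootstrapConsistencyResult(
        n_edges=len(targets), n_boot=n_boot, max_abs_se_units=worst
    )


# ---------------------------------------------------------------------------
# DMP error control and sensitivity
# ---------------------------------------------------------------------------


@dataclass
class DMPStudyResult:
    n_null_seeds: int
    null_any_significant_fraction: float
    sensitivity: float
    n_implanted: int


def _dmp_cohort(cfg: SimulationConfig):
    """Tumor/islet submatrix without the PDX1-region probes.

    The region is constitutively different between tumors and islets by
    construction (it is the subtyping anchor), so it is excluded from
    genome-wide error-control and sensitivity accounting.
    """
    manifest = simulate_manifest(cfg)
    beta, truth = simulate_methylation(cfg, manifest)
    chrom, start, end = cfg.pdx1_region
    ann = manifest.data
    in_region = (ann["chrom"] == chrom) & (ann["pos"] >= start) & (ann["pos"] <= end)
    probes = ann.index[~in_region]
    groups = {s: "tumor" for s in truth.sample_ids["tumor"]}
    groups.update({s: "islet" for s in truth.sample_ids["islet"]})
    keep = list(groups)
    return beta.data.loc[probes, keep], groups, truth


def dmp_error_study(
    n_null_seeds: int = 200,
    *,
    n_probes: int = 2000,
    n_tumors: int = 10,
    n_islets: int = 5,
    delta: float = 0.3,
    seed: int = 0,
) -> DMPStudyResult:
    """Family-wise error on null cohorts and sensitivity on implanted DMPs."""
    from .arrays_io import BetaMatrix

    any_sig = 0
    for s in range(n_null_seeds):
        cfg = SimulationConfig(
            n_tumors_A=n_tumors,
            n_tumors_B=0,
            n_islets=n_islets,
            n_alpha=1,
            n_beta=1,
            n_probes=n_probes,
            n_chromosomes=4,
            pdx1_n_probes=4,
            frac_dmp=0.0,
            delta_beta_effect=0.0,
            n_dmrs=0,
            rng_seed=_child_seed(seed, 20, s),
        )
        df, groups, _ = _dmp_cohort(cfg)
        res = dmp_test(BetaMatrix(df), groups)
        any_sig += int(res["significant"].any())

    cfg = SimulationConfig(
        n_tumors_A=n_tumors,
        n_tumors_B=0,
        n_islets=n_islets,
        n_alpha=1,
        n_beta=1,
        n_probes=n_probes,
        n_chromosomes=4,
        pdx1_n_probes=4,
        frac_dmp=0.05,
        delta_beta_effect=delta,
        n_dmrs=0,
        rng_seed=_child_seed(seed, 21),
    )
    df, groups, truth = _dmp_cohort(cfg)
    res = dmp_test(BetaMatrix(df), groups)
    implanted = list(truth.dmp_effects)
    detected = int(res.loc[implanted, "significant"].sum())
    return DMPStudyResult(
        n_null_seeds=n_null_seeds,
        null_any_significant_fraction=any_sig / n_null_seeds,
        sensitivity=detected / len(implanted),
        n_implanted=len(implanted),
    )


# ---------------------------------------------------------------------------
# DMR recovery and null behavior
# ---------------------------------------------------------------------------


@dataclass
class DMRRecoveryResult:
    n_regions: int
    mean_reciprocal_overlap: float
    min_reciprocal_overlap: float
    two_probe_implant_reported: bool


def _dmr_cfg(seed: int, **kw) -> SimulationConfig:
    base = dict(
        n_tumors_A=10,
        n_tumors_B=0,
        n_islets=5,
        n_alpha=1,
        n_beta=1,
        n_probes=600,
        n_chromosomes=3,
        pdx1_n_probes=4,
        rng_seed=seed,
    )
    base.update(kw)
    return SimulationConfig(**base)


def dmr_recovery_study(
    n_seeds: int = 3, *, n_permutations: int = 250, seed: int = 0
) -> DMRRecoveryResult:
    """Recovery of implanted 5-probe DMRs (delta 0.4) and the
    minimum-probe rule on a 2-probe implant."""
    from .arrays_io import BetaMatrix

    overlaps: list[float] = []
    for s in range(n_seeds):
        cfg = _dmr_cfg(
            _child_seed(seed, 30, s),
            frac_dmp=25 / 600,
            delta_beta_effect=0.4,
            n_dmrs=5,
            dmr_n_probes=5,
        )
        manifest = simulate_manifest(cfg)
        beta, truth = simulate_methylation(cfg, manifest)
        groups = {x: "tumor" for x in truth.sample_ids["tumor"]}
        groups.update({x: "islet" for x in truth.sample_ids["islet"]})
        res = dmr_bumphunter(
            BetaMatrix(beta.data[list(groups)]),
            groups,
            manifest,
            n_permutations=n_permutations,
            rng_seed=_child_seed(seed, 31, s),
        )
        sig = res[res["significant"]]
        for region in truth.dmr_regions:
            true_set = set(region["probe_ids"])
            best = 0.0
            for _, row in sig.iterrows():
                called = set(row["probe_ids"])
                inter = len(true_set & called)
                if inter:
                    best = max(best, min(inter / len(true_set), inter / len(called)))
            overlaps.append(best)

    # 2-probe implant must not be reported at min-probes 3
    cfg = _dmr_cfg(_child_seed(seed, 32), frac_dmp=0.0, delta_beta_effect=0.0, n_dmrs=0)
    manifest = simulate_manifest(cfg)
    beta, truth = simulate_methylation(cfg, manifest)
    ann = manifest.data
    pos = ann["pos"].to_numpy()
    chrom = ann["chrom"].to_numpy()
    pair = None
    i = 0
    while i < len(ann) - 1:
        j = i
        while (
            j + 1 < len(ann)
            and chrom[j + 1] == chrom[j]
            and pos[j + 1] - pos[j] <= 300
        ):
            j += 1
        if j - i + 1 == 2:
            pair = [ann.index[i], ann.index[j]]
            break
        i = j + 1
    assert pair is not None, "synthetic manifest lacks a 2-probe cluster"
    groups = {x: "tumor" for x in truth.sample_ids["tumor"]}
    groups.update({x: "islet" for x in truth.sample_ids["islet"]})
    df = beta.data[list(groups)].copy()
    tumor_cols = [c for c in df.columns if groups[c] == "tumor"]
    df.loc[pair, tumor_cols] = np.clip(df.loc[pair, tumor_cols] + 0.4, 0, 1)
    res = dmr_bumphunter(
        BetaMatrix(df),
        groups,
        manifest,
        n_permutations=n_permutations,
        rng_seed=_child_seed(seed, 33),
    )
    reported = any(
        set(pair) & set(row["probe_ids"]) for _, row in res[res["significant"]].iterrows()
    )
    return DMRRecoveryResult(
        n_regions=len(overlaps),
        mean_reciprocal_overlap=float(np.mean(overlaps)) if overlaps else 0.0,
        min_reciprocal_overlap=float(np.min(overlaps)) if overlaps else 0.0,
        two_probe_implant_reported=reported,
    )


@dataclass
class DMRNullResult:
    n_seeds: int
    clean_fraction: float  # runs with zero significant DMRs


def dmr_null_study(
    n_seeds: int = 100, *, n_permutations: int = 100, seed: int = 0
) -> DMRNullResult:
    """Significant-DMR rate on null cohorts (no implanted effects)."""
    from .arrays_io import BetaMatrix

    clean = 0
    for s in range(n_seeds):
        cfg = _dmr_cfg(
            _child_seed(seed, 40, s), frac_dmp=0.0, delta_beta_effect=0.0, n_dmrs=0,
            n_probes=400,
        )
        manifest = simulate_manifest(cfg)
        beta, truth = simulate_methylation(cfg, manifest)
        groups = {x: "tumor" for x in truth.sample_ids["tumor"]}
        groups.update({x: "islet" for x in truth.sample_ids["islet"]})
        res = dmr_bumphunter(
            BetaMatrix(beta.data[list(groups)]),
            groups,
            manifest,
            n_permutations=n_permutations,
            rng_seed=_child_seed(seed, 41, s),
        )
        clean += int(len(res) == 0 or not res["significant"].any())
    return DMRNullResult(n_seeds=n_seeds, clean_fraction=clean / n_seeds)


# ---------------------------------------------------------------------------
# CNA recovery
# ---------------------------------------------------------------------------


@dataclass
class CNAStudyResult:
    affected_call_rate: float
    unaffected_call_rate: float
    heldout_reference_call_rate: float
    n_bins: int


def cna_recovery_study(*, seed: int = 0) -> CNAStudyResult:
    """Detection of implanted whole-chromosome +-0.3 shifts.

    EPIC-cohort-like design: 16 subtype-A and 10 subtype-B tumors vs 5
    islet references; calls at the +-0.150 log2 thresholds.
    """
    from .cna import bin_ratios, call_states, fit_reference_baseline, make_bins

    cfg = SimulationConfig(
        n_tumors_A=16,
        n_tumors_B=10,
        n_islets=5,
        n_alpha=1,
        n_beta=1,
        n_probes=6000,
        n_chromosomes=12,
        pdx1_n_probes=4,
        frac_dmp=0.0,
        n_dmrs=0,
        rng_seed=_child_seed(seed, 50),
    )
    manifest = simulate_manifest(cfg)
    _, truth = simulate_methylation(cfg, manifest)
    sheet, intensity = simulate_clinical(cfg, truth)

    config = AnalysisConfig()
    bins = make_bins(manifest, config)
    refs = intensity.data[truth.sample_ids["islet"]]
    bin_chrom = bins.bins["chrom"]

    affected_hits = affected_total = 0
    unaffected_calls = unaffected_total = 0
    for sid in truth.sample_ids["tumor"]:
        ratio = fit_reference_baseline(intensity.data[sid], refs)
        states = call_states(bin_ratios(ratio, bins), config).iloc[:, 0]
        events = {e["chrom"]: e["direction"] for e in truth.cna_segments[sid]}
        for b in bins.bins.index:
            chrom = bin_chrom.loc[b]
            if chrom in events:
                affected_total += 1
                affected_hits += int(states.loc[b] == events[chrom])
            else:
                unaffected_total += 1
                unaffected_calls += int(states.loc[b] != "neutral")

    held = truth.sample_ids["islet"][0]
    other = refs.drop(columns=[held])
    ratio = fit_reference_baseline(intensity.data[held], other)
    states = call_states(bin_ratios(ratio, bins), config).iloc[:, 0]
    ref_rate = float((states != "neutral").mean())

    return CNAStudyResult(
        affected_call_rate=affected_hits / affected_total,
        unaffected_call_rate=unaffected_calls / unaffected_total,
        heldout_reference_call_rate=ref_rate,
        n_bins=len(bins),
    )


# ---------------------------------------------------------------------------
# Cox recovery
# ---------------------------------------------------------------------------


@dataclass
class CoxStudyResult:
    n_seeds: int
    mean_hr: float
    ci_coverage: float
    true_hr: float
    mean_censoring: float


def cox_recovery_study(n_seeds: int = 200, *, seed: int = 0) -> CoxStudyResult:
    """Hazard-ratio recovery at HR 0.22 with n = 83 and exponential
    censoring (~30% censored)."""
    hrs = []
    covered = 0
    censoring = []
    for s in range(n_seeds):
        cfg = SimulationConfig(
            n_probes=120,
            n_chromosomes=3,
            pdx1_n_probes=4,
            frac_dmp=0.0,
            n_dmrs=0,
            rng_seed=_child_seed(seed, 60, s),
        )
        manifest = simulate_manifest(cfg)
        _, truth = simulate_methylation(cfg, manifest)
        sheet, _ = simulate_clinical(cfg, truth)
        tum = sheet.data[sheet.data["group"] == "tumor"]
        x = pd.DataFrame(
            {"subtype_B": [1.0 if truth.subtype[s_] == "B" else 0.0 for s_ in tum.index]},
            index=tum.index,
        )
        fit = coxph_fit(tum["os_time"], tum["os_event"], x)
        hrs.append(float(fit.hr.iloc[0]))
        covered += int(fit.ci_lower.iloc[0] <= cfg.hr_B_vs_A <= fit.ci_upper.iloc[0])
        censoring.append(1.0 - tum["os_event"].mean())
    return CoxStudyResult(
        n_seeds=n_seeds,
        mean_hr=float(np.mean(hrs)),
        ci_coverage=covered / n_seeds,
        true_hr=SimulationConfig().hr_B_vs_A,
        mean_censoring=float(np.mean(censoring)),
    )


def cox_toy_check() -> float:
    """|Newton coefficient - brute-force partial-likelihood maximum| on a
    fixed 6-subject dataset with no ties."""
    times = np.array([1.0, 2.5, 3.0, 4.2, 5.1, 6.7])
    events = np.array([1, 1, 0, 1, 1, 1])
    x = np.array([0.5, -1.0, 0.3, 1.2, -0.7, 0.9])

    def neg_pl(beta: float) -> float:
        ll = 0.0
        for i in range(len(times)):
            if not events[i]:
                continue
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
        return -ll

    res = minimize_scalar(neg_pl, bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-10})
    fit = coxph_fit(times, events, pd.DataFrame({"x": x}))
    return float(abs(fit.coef.iloc[0] - res.x))
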