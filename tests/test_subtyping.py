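import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pnenmeth.arrays_io import ProbeManifest, SampleSheet
from pnenmeth.subtyping import (
    DEFAULT_SCALES,
    Dendrogram,
    assign_subtypes,
    multiscale_bootstrap_support,
    select_region_probes,
    subtype_pipeline,
    ward_dendrogram,
)
from pnenmeth.subtyping import _fit_au
from pnenmeth.synthetic import SimulationConfig, simulate_cohort

from conftest import manifest_frame

REGION = ("chr13", 28_480_000, 28_510_000)


class TestRegionSelection:
    def _manifest(self, positions):
        rows = [
            (f"cg{i:02d}", "chr13", p, "I", "Island", "TSS200", "PDX1", True, True)
            for i, p in enumerate(positions)
        ]
        rows.append(("cgX", "chr1", 28_490_000, "I", "Island", "Body", "", True, True))
        return ProbeManifest(manifest_frame(rows))

    def test_boundaries_inclusive(self):
        m = self._manifest([28_480_000, 28_510_000, 28_510_001, 28_479_999])
        sel = select_region_probes(m, REGION, set(m.probe_ids))
        positions = sorted(m.data.loc[sel, "pos"])
        assert positions == [28_480_000, 28_510_000]

    def test_platform_intersection_applied(self):
        m = self._manifest([28_490_000, 28_495_000])
        sel = select_region_probes(m, REGION, {"cg00"})
        assert sel == ["cg00"]

    def test_empty_selection_is_hard_error(self):
        m = self._manifest([28_479_999])
        with pytest.raises(ValueError, match="no probes"):
            select_region_probes(m, REGION, set(m.probe_ids))

    def test_matches_independent_linear_scan(self):
        rng = np.random.default_rng(0)
        pos = rng.integers(28_400_000, 28_600_000, size=40)
        m = self._manifest(sorted(set(map(int, pos))))
        common = set(rng.choice(list(m.probe_ids), size=25, replace=False))
        sel = select_region_probes(m, REGION, common)
        expected = [
            p
            for p in m.data.index
            if m.data.loc[p, "chrom"] == "chr13"
            and 28_480_000 <= m.data.loc[p, "pos"] <= 28_510_000
            and p in common
        ]
        assert sel == expected


def brute_force_ward(X: np.ndarray, labels):
    """Greedy Ward agglomeration via the Lance-Williams update on
    squared Euclidean distances; heights on the distance scale."""
    n = len(labels)
    d2 = {
        (i, j): float(((X[i] - X[j]) ** 2).sum())
        for i in range(n)
        for j in range(i + 1, n)
    }
    active = {i: (frozenset([labels[i]]), 1) for i in range(n)}
    merges = []
    next_id = n

    def get(i, j):
        return d2[(i, j) if i < j else (j, i)]

    while len(active) > 1:
        (i, j), best = min(
            ((pair, v) for pair, v in d2.items() if pair[0] in active and pair[1] in active),
            key=lambda kv: kv[1],
        )
        si, ni = active[i]
        sj, nj = active[j]
        merges.append((si | sj, np.sqrt(best)))
        for k in list(active):
            if k in (i, j):
                continue
            nk = active[k][1]
            new = (
                (ni + nk) * get(i, k) + (nj + nk) * get(j, k) - nk * best
            ) / (ni + nj + nk)
            d2[(min(i, k), max(i, k))] = np.inf
            d2[(min(j, k), max(j, k))] = np.inf
            d2[(min(next_id, k), max(next_id, k))] = new
        del active[i], active[j]
        active[next_id] = (si | sj, ni + nj)
        next_id += 1
    return merges


class TestWardDendrogram:
    def test_matches_bruteforce_lance_williams(self):
        rng = np.random.default_rng(1)
        X = rng.random((6, 4))
        labels = [f"s{i}" for i in range(6)]
        dend = ward_dendrogram(pd.DataFrame(X, index=labels))
        expected = brute_force_ward(X, labels)
        got = [
            (dend.leaf_set(node), dend.height(node)) for node in dend.internal_nodes()
        ]
        assert [s for s, _ in got] == [s for s, _ in expected]
        for (_, h1), (_, h2) in zip(got, expected):
            assert h1 == pytest.approx(h2, rel=1e-10)

    def test_identical_samples_merge_at_height_zero(self):
        X = pd.DataFrame([[0.5, 0.5], [0.5, 0.5], [0.9, 0.9]], index=["a", "b", "c"])
        dend = ward_dendrogram(X)
        first = dend.internal_nodes()[0]
        assert dend.leaf_set(first) == frozenset({"a", "b"})
        assert dend.height(first) == pytest.approx(0.0, abs=1e-12)

    def test_tight_pairs_merge_before_root(self):
        X = pd.DataFrame(
            [[0.0, 0.0], [0.01, 0.0], [1.0, 1.0], [1.01, 1.0]],
            index=["a1", "a2", "b1", "b2"],
        )
        dend = ward_dendrogram(X)
        sets = [dend.leaf_set(k) for k in dend.internal_nodes()]
        assert frozenset({"a1", "a2"}) in sets[:2]
        assert frozenset({"b1", "b2"}) in sets[:2]
        (n1, s1), (n2, s2) = dend.root_split()
        assert {s1, s2} == {frozenset({"a1", "a2"}), frozenset({"b1", "b2"})}

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.random((12, 6)), index=[f"s{i}" for i in range(12)])
        dend = ward_dendrogram(X)
        heights = [dend.height(k) for k in dend.internal_nodes()]
        assert all(np.diff(heights) >= -1e-12)


class TestMultiscaleBootstrap:
    def test_saturated_edge_gets_full_support(self):
        rng = np.random.default_rng(3)
        X = np.vstack(
            [rng.normal(0, 0.02, size=(5, 20)), rng.normal(1, 0.02, size=(5, 20))]
        )
        Xdf = pd.DataFrame(X, index=[f"s{i}" for i in range(10)])
        dend = ward_dendrogram(Xdf)
        support = multiscale_bootstrap_support(Xdf, dend, n_boot=100, rng_seed=0)
        (na, _), (nb, _) = dend.root_split()
        assert support[na].au >= 0.999
        assert support[nb].au >= 0.999
        assert support[na].bp == 1.0

    def test_probit_fit_matches_independent_wls(self):
        # synthetic bp table varying with scale; compare against a direct
        # weighted normal-equations solve of the same 10-point system
        n_boot = 1000
        v_true, c_true = 0.4, -0.9
        bp = {
            float(r): float(1 - stats.norm.cdf(v_true * np.sqrt(r) + c_true / np.sqrt(r)))
            for r in DEFAULT_SCALES
        }
        au, v, c, res, sat = _fit_au(bp, n_boot)
        assert not sat
        r = np.array(sorted(bp))
        prop = np.clip(
            np.array([bp[x] for x in r]), 1 / (n_boot + 1), n_boot / (n_boot + 1)
        )
        z = stats.norm.ppf(1 - prop)
        A = np.column_stack([np.sqrt(r), 1 / np.sqrt(r)])
        w = n_boot * stats.norm.pdf(z) ** 2 / (prop * (1 - prop))
        lhs = A.T @ (w[:, None] * A)
        rhs = A.T @ (w * z)
        v2, c2 = np.linalg.solve(lhs, rhs)
        assert v == pytest.approx(v2, rel=1e-8)
        assert c == pytest.approx(c2, rel=1e-8)
        assert v == pytest.approx(v_true, abs=1e-6)
        assert c == pytest.approx(c_true, abs=1e-6)
        assert au == pytest.approx(1 - stats.norm.cdf(v_true - c_true), abs=1e-6)

    def test_bp_at_scale_one_matches_plain_bootstrap(self):
        rng = np.random.default_rng(4)
        means = np.r_[np.zeros(5), np.full(5, 0.8)]
        X = rng.normal(means[:, None], 1.0, size=(10, 30))
        Xdf = pd.DataFrame(X, index=[f"s{i}" for i in range(10)])
        dend = ward_dendrogram(Xdf)
        n_boot = 400
        s1 = multiscale_bootstrap_support(
            Xdf, dend, n_boot=n_boot, scales=(1.0,), rng_seed=1
        )
        s2 = multiscale_bootstrap_support(
            Xdf, dend, n_boot=n_boot, scales=(1.0,), rng_seed=99
        )
        for k in dend.internal_nodes():
            p1, p2 = s1[k].bp, s2[k].bp
            pooled = np.clip((p1 + p2) / 2, 1 / (n_boot + 1), n_boot / (n_boot + 1))
            se = np.sqrt(2 * pooled * (1 - pooled) / n_boot)
            assert abs(p1 - p2) <= 4 * se


def _cohort_frames(sep=0.7, seed=0, n_a=6, n_b=5):
    cfg = SimulationConfig(
        n_tumors_A=n_a,
        n_tumors_B=n_b,
        n_islets=2,
        n_probes=250,
        n_chromosomes=3,
        pdx1_n_probes=8,
        pdx1_separation=sep,
        frac_dmp=0.0,
        n_dmrs=0,
        rng_seed=seed,
    )
    return simulate_cohort(cfg), cfg


class TestAssignSubtypes:
    def test_recovers_ground_truth_labels(self):
        (manifest, beta, _, sheet, truth), cfg = _cohort_frames()
        calls, dend, support = subtype_pipeline(beta.data, manifest, sheet)
        assert len(calls) == len(truth.subtype)
        for sid, st in truth.subtype.items():
            assert calls.loc[sid, "subtype"] == st
        assert (calls["cluster_au"] >= 0.95).all()

    def test_invariant_to_sample_and_probe_order(self):
        (manifest, beta, _, sheet, truth), cfg = _cohort_frames(seed=3)
        calls1, _, _ = subtype_pipeline(beta.data, manifest, sheet, with_support=False)
        rng = np.random.default_rng(0)
        shuffled = beta.data.iloc[
            rng.permutation(beta.data.shape[0]), rng.permutation(beta.data.shape[1])
        ]
        calls2, _, _ = subtype_pipeline(shuffled, manifest, sheet, with_support=False)
        pd.testing.assert_frame_equal(calls1[["subtype"]], calls2[["subtype"]])

    def test_identical_references_raise_not_separated(self):
        rng = np.random.default_rng(5)
        probes = [f"p{i}" for i in range(6)]
        profile = rng.random(6)
        data = {}
        for i in range(4):
            data[f"tumor_{i}"] = np.clip(profile + rng.normal(0, 0.01, 6), 0, 1)
        data["alpha_01"] = np.clip(profile + 0.3, 0, 1)
        data["beta_01"] = np.clip(profile + 0.3, 0, 1)  # identical to alpha
        X = pd.DataFrame(data, index=probes).T
        dend = ward_dendrogram(X)
        sheet = _sheet_for(list(X.index))
        with pytest.raises(ValueError, match="not separated"):
            assign_subtypes(dend, sheet)

    def test_split_references_raise(self):
        probes = [f"p{i}" for i in range(4)]
        X = pd.DataFrame(
            {
                "alpha_01": [0.9, 0.9, 0.9, 0.9],
                "alpha_02": [0.1, 0.1, 0.1, 0.1],
                "beta_01": [0.12, 0.1, 0.1, 0.1],
                "tumor_1": [0.88, 0.9, 0.9, 0.9],
            },
            index=probes,
        ).T
        dend = ward_dendrogram(X)
        sheet = _sheet_for(list(X.index))
        with pytest.raises(ValueError, match="split across"):
            assign_subtypes(dend, sheet)

    def test_single_tumor_joins_one_cluster(self):
        X = pd.DataFrame(
            {
                "alpha_01": [0.9, 0.85],
                "beta_01": [0.1, 0.15],
                "tumor_1": [0.88, 0.84],
            },
            index=["p0", "p1"],
        ).T
        dend = ward_dendrogram(X)
        calls = assign_subtypes(dend, _sheet_for(list(X.index)))
        assert list(calls.index) == ["tumor_1"]
        assert calls.loc["tumor_1", "subtype"] == "A"

    def test_newick_export_contains_support_labels(self):
        (manifest, beta, _, sheet, truth), cfg = _cohort_frames(seed=7, n_a=3, n_b=3)
        calls, dend, support = subtype_pipeline(beta.data, manifest, sheet)
        nwk = dend.to_newick(support)
        assert nwk.endswith(";")
        assert "au" in nwk and "tumor_001" in nwk


def _sheet_for(sample_ids):
    rows = []
    for sid in sample_ids:
        group = (
            "tumor"
            if sid.startswith("tumor")
            else ("alpha" if sid.startswith("alpha") else "beta")
        )
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
                "gender": "F",
                "age": 60.0,
                "tumor_size": np.nan,
                "os_time": 1.0,
                "os_event": 0,
                "tumor_purity": 0.9 if group == "tumor" else np.nan,
            }
        )
    return SampleSheet(pd.DataFrame(rows))
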