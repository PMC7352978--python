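import numpy as np
import pandas as pd
import pytest

from pnenmeth.arrays_io import ProbeManifest
from pnenmeth.synthetic import SimulationConfig, simulate_cohort


def manifest_frame(rows):
    """Build a manifest DataFrame from (probe, chrom, pos, design, island,
    feature, gene, on450, onepic) tuples; strand defaults to +."""
    return pd.DataFrame(
        [
            {
                "probe_id": p,
                "chrom": c,
                "pos": pos,
                "strand": "+",
                "design_type": d,
                "island_relation": isl,
                "feature": feat,
                "gene": gene,
                "on_450k": on450,
                "on_epic": onepic,
            }
            for (p, c, pos, d, isl, feat, gene, on450, onepic) in rows
        ]
    )


@pytest.fixture
def tiny_manifest():
    return ProbeManifest(
        manifest_frame(
            [
                ("cg01", "chr1", 100, "I", "Island", "TSS200", "G1", True, True),
                ("cg02", "chr1", 500, "II", "Shore", "Body", "G1", True, True),
                ("cg03", "chr2", 50, "I", "OpenSea", "IGR", "", False, True),
                ("cg04", "chr2", 900, "II", "Shelf", "5'UTR", "G2", True, False),
                ("cg05", "chr10", 10, "I", "Island", "1stExon", "G3", True, True),
            ]
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-subtype cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_tumors_A=8,
        n_tumors_B=6,
        n_islets=4,
        n_probes=1200,
        n_chromosomes=6,
        pdx1_n_probes=8,
        rng_seed=42,
    )
    manifest, beta, intensity, sheet, truth = simulate_cohort(cfg)
    return dict(
        cfg=cfg,
        manifest=manifest,
        beta=beta,
        intensity=intensity,
        sheet=sheet,
        truth=truth,
    )
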