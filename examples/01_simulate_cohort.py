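"""Generate a synthetic PNEN cohort and write it to disk.

Builds a two-subtype tumor cohort (62 subtype-A, 21 subtype-B) with
alpha/beta/islet references, implanted differential methylation,
subtype-specific chromosome-scale copy-number shifts and subtype-
dependent survival, then writes the five cohort files.
"""

from pathlib import Path

from pnenmeth import SimulationConfig, simulate_cohort, write_cohort

cfg = SimulationConfig(rng_seed=1)
manifest, beta, intensity, sheet, truth = simulate_cohort(cfg)

outdir = Path("scratch/cohort")
write_cohort(cfg, outdir)

n_a = sum(1 for s in truth.subtype.values() if s == "A")
n_b = len(truth.subtype) - n_a
print(f"probes:           {len(manifest)} on {manifest.data['chrom'].nunique()} chromosomes")
print(f"samples:          {beta.shape()[1]} "
      f"({n_a} subtype-A + {n_b} subtype-B tumors, "
      f"{len(truth.sample_ids['islet'])} islets, "
      f"{len(truth.sample_ids['alpha'])} alpha, {len(truth.sample_ids['beta'])} beta)")
print(f"implanted DMPs:   {len(truth.dmp_effects)} "
      f"({sum(1 for e in truth.dmp_effects.values() if e < 0)} hypomethylated)")
print(f"implanted DMRs:   {len(truth.dmr_regions)}")
print(f"files written to: {outdir}/")
# The DMP count is the ground truth the differential module must recover;
# the hypomethylated share reflects the ~85% hypomethylation of PNENs.
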