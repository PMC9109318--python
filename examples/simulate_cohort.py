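"""Generate a synthetic cohort and write it in the toolkit's TSV dialects.

The written files round-trip through the readers, so the same data can be
re-analyzed with the command-line interface:

    hrdscar score --segments simdir/segments.tsv -o scores.tsv
"""

from pathlib import Path

from hrdscar import SimParams, simulate_cohort, write_segment_table

outdir = Path("scratch/simdir")
outdir.mkdir(parents=True, exist_ok=True)

sim = simulate_cohort(SimParams(seed=7, n_samples=30))
write_segment_table(sim.profiles.values(), outdir / "segments.tsv")
sim.cohort.data.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
sim.alterations.reset_index().to_csv(outdir / "alterations.tsv", sep="\t", index=False)
sim.variants.to_csv(outdir / "brca_variants.tsv", sep="\t", index=False)

df = sim.cohort.data
print(f"wrote {len(df)} samples to {outdir}/")
print(f"HRD-positive: {int(df.hrd_positive.sum())}  "
      f"BRCA-deficient: {int((df.brca_status == 'deficient').sum())}")
print(f"planted truth for first sample: {sim.truth['planted'][df.sample_id.iloc[0]]}")
# Planted component counts equal the scores the scorer recomputes from the
# written segment table — the simulator's central contract.
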