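"""The complete study on synthetic data, end to end.

Phantom -> DWI -> global tractography with accumulation -> exhaustive ROI
selection -> density / probability / retention / masks -> FACT tract ->
per-subject v_intra -> covariate-adjusted pain statistics. Writes all
artifacts (NIfTI, TCK, TSV, manifest) to ./pipeline_run/.

Equivalent shell command:  paintract run-all --out pipeline_run --seed 0 --fast
"""

from paintract import PipelineConfig, run_pipeline
from paintract.global_tracking import AnnealSchedule

cfg = PipelineConfig(
    master_seed=0,
    schedule=AnnealSchedule(n_iter=60_000, reheat_iter=20_000),  # reduced
    out_dir="pipeline_run",
)
report = run_pipeline(cfg)

s = report["stages"]
print(f"tractogram: {s['tracking']['n_streamlines']} streamlines")
print(f"kept tracts: {s['density']['kept_tracts']} "
      f"(dropped: {s['density']['dropped_tracts']})")
print(f"FACT visualization tract: {s['fact']['n_streamlines']} streamlines")
print()
print(report["results"].to_string(index=False))
print(f"\nFDR log10 threshold: {s['stats']['fdr_log10_threshold']:.3f}")
print(f"significant under FDR<5%: {s['stats']['sig_fdr']}")
print(f"significant under Bonferroni: {s['stats']['sig_bonferroni']}")
print("\n-> the pain-coupled tracts (AP/DP/CS) are flagged; the uncoupled")
print("   control (PN) and the unconnected ROI pair (NC) are not.")
print(f"artifacts written to: {cfg.out_dir}/ (see manifest.json)")
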