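"""Run the end-to-end pipeline driver on a synthetic configuration and
inspect the output bundle it writes."""

from pathlib import Path

from twinconn import PipelineConfig, run_pipeline

config = PipelineConfig(
    seed=11,
    n_mz=30, n_dz=20,          # twin pairs in the healthy branch
    a2=0.52,                   # generative additive-genetic fraction
    n_nodes=30, n_paradigms=4, n_timepoints=150, n_sessions=2,
    mask_top_k=30,
)
outdir = Path("pipeline_out")
bundle = run_pipeline(config, outdir=outdir)

herit = bundle["heritability"]
est = herit["heritability"]
print(f"ICC (MZ/DZ) of the network score: "
      f"{herit['icc_mz']:.3f} / {herit['icc_dz']:.3f}")
print(f"selected model: {herit['selection'].best.model}; "
      f"h2 = {est.h2:.3f} (CI {est.ci_low:.3f}-{est.ci_high:.3f})")
reg = bundle["regression"]
print(f"discordant branch: proximity slope {reg.slope:.3f}, p = {reg.p_value:.4f}")
print(f"tables written to {outdir}/: "
      f"{', '.join(sorted(p.name for p in outdir.iterdir()))}")
# Every table carries a header with the config hash and seed; re-running
# with the same config reproduces the files byte for byte.
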