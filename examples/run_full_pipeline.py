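"""Run the six-stage pipeline end to end on the bundled demo configuration.

Stages: generate (RR beat files + cohort CSV) -> ingest (clean, segment)
-> features (per-segment HRV table) -> train (GA selection + ensemble,
grouped LOOCV) -> trajectory (mixed model, ΔHRV at 34 weeks) -> report
(factor/outcome tables). Every stage writes files and a manifest records
checksums, so a rerun with the same seed reproduces the run bit for bit.
"""

from pathlib import Path

from neomat.pipeline import RunConfig, run_pipeline, write_report

config = RunConfig.from_yaml(Path(__file__).parent / "demo_config.yaml")
manifest = run_pipeline(config)
report = write_report(manifest, config.outdir)

print("stages:", ", ".join(f"{k}={v}" for k, v in manifest["stages"].items()))
print(f"report: {report}")
print(report.read_text())
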