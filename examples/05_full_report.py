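"""Full pipeline run with all data exports written to disk.

Equivalent to the CLI:  stratomics generate ... && stratomics run --config ...
"""
import json
from pathlib import Path

from stratomics import RunConfig, run_pipeline
from stratomics.synthetic import CaseSpec, generate_case

outdir = Path("scratch/example_run")
manifest = generate_case(CaseSpec("case2_tamoxifen", seed=1), outdir / "inputs")
f = manifest["files"]
report = run_pipeline(RunConfig(
    clinical=f["clinical"], expression=f["expression"],
    somatic_vcf=f["somatic_vcf"], germline_vcf=f["germline_vcf"],
    seg=f["seg"], methylation=f["methylation"], seed=3, n_perm=500,
    outdir=str(outdir / "out")))

print("sections:", [k for k in report if k != "skipped"])
print("skipped stages:", report["skipped"])
print("subtype:", report["subtype"]["call"])
print("knowledge hash:", report["tool"]["knowledge_hash"][:16], "...")
print("exports:", sorted(p.name for p in (outdir / "out").iterdir()))

# report.json is the single source of truth; radar.json, sunburst.json,
# tmb.json and the embedding JSONs are visualization-ready data exports
# (the package renders no images).
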