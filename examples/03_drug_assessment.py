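"""Rule-based drug assessment on the tamoxifen-resistance case template.

Generates the case-2 synthetic tumor (HR+/HER2-, germline CYP2D6 frameshift,
somatic ESR2 frameshift, APOBEC3B up, BRCA1/2 germline loss, PARP1 up), runs
the pipeline and prints the per-drug verdicts with fired evidence.
"""
import tempfile

from stratomics import RunConfig, run_pipeline
from stratomics.synthetic import CaseSpec, generate_case

with tempfile.TemporaryDirectory() as td:
    manifest = generate_case(CaseSpec("case2_tamoxifen", seed=1), td)
    f = manifest["files"]
    report = run_pipeline(RunConfig(
        clinical=f["clinical"], expression=f["expression"],
        somatic_vcf=f["somatic_vcf"], germline_vcf=f["germline_vcf"],
        seg=f["seg"], methylation=f["methylation"], seed=3, n_perm=500))

print(f"{'drug':<28} {'verdict':>16} {'+':>3} {'-':>3}")
for a in report["drugs"]["soc"]:
    print(f"{a['drug_id']:<28} {a['verdict']:>16} {a['n_supporting']:>3} {a['n_contra']:>3}")

tamoxifen = next(a for a in report["drugs"]["soc"] if a["drug_id"] == "tamoxifen")
print("\ntamoxifen evidence against:")
for item in tamoxifen["items"]:
    if item["fired"] and item["direction"] == "contraindicates":
        print(f"  [{item['kind']}] {item['explanation']} ({item['evidence_ref']})")

print("\nconsistency warnings:", report["drugs"]["consistency_warnings"])

# Despite the favorable receptor status, tamoxifen comes out contraindicated:
# the CYP2D6 loss (no activation to endoxifen) is a decisive gatekeeper, and
# the ESR2 resistance mutation, APOBEC3B overexpression and high MAPK
# activity add further evidence. The PARP inhibitors are suggested on the
# BRCA1/2 germline loss with PARP1 upregulation.
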