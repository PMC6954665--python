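"""Tumor mutational burden and repair-gene status on the immunotherapy case.

Generates the case-3 synthetic tumor (triple-negative, 50 somatic exonic
mutations, severe TP53/RB1 and damaging ATM hits) and prints the TMB with
its cohort percentile plus the impaired DNA-repair genes.
"""
import tempfile

from stratomics import RunConfig, run_pipeline
from stratomics.synthetic import CaseSpec, generate_case

with tempfile.TemporaryDirectory() as td:
    manifest = generate_case(CaseSpec("case3_immuno", seed=2), td)
    f = manifest["files"]
    report = run_pipeline(RunConfig(
        clinical=f["clinical"], expression=f["expression"],
        somatic_vcf=f["somatic_vcf"], germline_vcf=f["germline_vcf"],
        seg=f["seg"], methylation=f["methylation"], seed=5, n_perm=500))

tmb = report["immuno"]["tmb"]
print(f"somatic exonic mutations: {tmb['n_somatic']}")
print(f"exome territory: {tmb['exome_mb']:.2f} Mb")
print(f"TMB: {tmb['tmb']:.2f} mutations/Mb "
      f"(cohort percentile {tmb['cohort_percentile']:.1f})")

print("\nimpaired DNA-repair genes:")
for entry in report["immuno"]["repair_genes"]:
    if entry["impaired"]:
        print(f"  {entry['gene_id']}: {entry['best_grade']}")

print("\ntop drivers:")
for d in report["drivers"][:5]:
    print(f"  {d['gene_id']:<8} grade={d['severity_grade']:<9} "
          f"priority={d['priority_score']:.2f} channels={','.join(d['channels'])}")

# A TMB above the 90th cohort percentile together with impaired repair
# machinery is the constellation in which checkpoint blockade is considered;
# the driver list explains the mutator phenotype (TP53/RB1/ATM loss).
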