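"""Run the whole study design from one config object.

Stages: preprocessing (SNP/sex flag removal, Greedycut, unreliable-entry
masking) -> SEM calling -> burden association -> paired differential
methylation -> shared-SEM genes. All artifacts are written to the
output directory and summarized in report.yaml. Equivalent shell usage:

    semscan run --synthetic --outdir sem_run --seed 42
"""
import semscan as ss

config = ss.PipelineConfig(synthetic={}, outdir="sem_run", seed=42, make_plots=True)
report = ss.run_pipeline(config)

sem_stage = report["stages"]["sem"]
print("median SEM totals:", sem_stage["median_sem_total"])
print("probes with fences:", sem_stage["n_fence_probes"])
assoc = report["stages"]["association"]
print("tumor vs peritumoral burden p:",
      f"{assoc['tumor_vs_peritumoral']['p_value']:.2e}")
dm = report["stages"]["diffmeth"]
print("significant sites:", dm["site_counts"]["n_significant"],
      "of", dm["site_counts"]["n_tested"])
shared = report["stages"]["shared"]
print("shared-SEM genes:", shared["genes"],
      "| planted:", shared["planted_shared_genes"])
print("outputs in sem_run/ (calls, totals, BED, tables, plots, report.yaml)")
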