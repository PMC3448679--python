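"""Run every stage end-to-end and write a stamped report.

Equivalent to `seekpaths run-all`; all artifacts (log, contacts,
profiles, power-law fits, journey models, pair statistics, regression)
land in the output directory together with report.md / report.json.
"""

from seekpaths import PipelineConfig, SyntheticConfig, run_pipeline

config = PipelineConfig(
    out_dir="scratch/pipeline_demo",
    seed=11,
    synthetic=SyntheticConfig(n_users=10_000),
    candidate_Ks=(4, 5, 6),
    n_restarts=3,
    n_permutations=300,
)
report = run_pipeline(config)

print(f"report hash {report['config_hash']}, artifacts in {config.out_dir}/")
cohort = report["stages"]["cohort"]
print(f"included {cohort['n_included']} of {cohort['n_users_total']} users")
for sev, info in report["stages"]["statehmm"]["per_severity"].items():
    if not info.get("skipped"):
        print(f"{sev}: best K = {info['selection']['best_K']}")
social = report["stages"]["social"]
if social.get("enrichment"):
    print(f"co-search fold enrichment {social['enrichment']['fold_enrichment']:.1f}")
print(f"incidence regression R^2 = {report['stages']['regress']['r2']:.2f}")
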