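"""One-shot pipeline on the default synthetic cohort.

Simulation -> step normalization -> DF distributions with
Kruskal-Wallis/Dunn -> bin-wise contrasts, all under a single seeded
config, emitting a machine-readable report.
"""

from gaitdf import CohortConfig, RunConfig, run_pipeline

config = RunConfig(synthetic=CohortConfig(), tail="two_sided", seed=0)
report = run_pipeline(config, outdir="scratch/example_run")

print(f"normalized curves: {report.data['n_curves']}")
print("\npercent of step cycle changed (control vs lesioned male rats):")
for joint in ("metatarsus", "ankle", "knee"):
    for side in ("left", "right"):
        pc = report.percent_changed(joint, side, "CMR:LMR")
        print(f"  {joint:<11} {side:<6} {pc:>3}%")

entry = next(e for e in report.df
             if e["joint"] == "metatarsus" and e["side"] == "left")
print(f"\nleft metatarsus DF: Kruskal-Wallis H = {entry['kw_H']:.1f}, "
      f"p = {entry['kw_p']:.2e} across 8 groups")
pair = "CMR|LMR"
print(f"Dunn adjusted p, {pair}: {entry['dunn'][pair]:.3g}")
print("\n-> artifacts (curves.tsv, df.tsv, per-contrast tables, report.json) "
      "written to scratch/example_run; identical config + seed reproduces "
      "them byte for byte.")
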