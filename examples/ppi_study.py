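"""End-to-end paired-pulse inhibition study.

Simulates a two-genotype in vivo field study (WT v50 41.3 ms, KO
shifted +4.5 ms, subject-level jitter, 5% noise), fits each animal's
PPI curve with the bottom-pinned Boltzmann sigmoid over interpulse
intervals up to 100 ms, gates fits at R^2 > 0.8, interpolates the
50/75/100% crossings, and compares the groups with Welch's t test —
the complete analysis chain behind the network-inhibition comparison.
"""

from dgephys import pipeline
from dgephys.pipeline import StudyConfig

cfg = StudyConfig(seed=1, out_dir="scratch/ppi_study_out")
outputs = pipeline.run_study(cfg)

fits = outputs["fits"]
print(f"fitted {len(fits)} animals; "
      f"{int(fits['included'].sum())} pass the R^2 > 0.8 gate")
print(fits[["subject", "group", "top", "v50_ms", "k_ms",
            "r_squared"]].head(6).to_string(index=False))

print("\ngroup comparison (difference oriented WT - KO):")
print(outputs["summary"].to_string(index=False))
print("\nA negative v50 difference means the KO curve is right-shifted: "
      "the second population spike needs a longer interpulse interval to "
      "recover, i.e. network inhibition is stronger in the KO group.")
print(f"\nreport bundle written to {cfg.out_dir} "
      "(per-stage CSVs + manifest.json with content hashes)")
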