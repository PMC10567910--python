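"""End-to-end run from a single config: synth -> sync -> preprocess ->
transients -> transitions -> sleep summaries, all artifacts written as
CSV/JSON into an output directory.
"""

import json
from pathlib import Path

from rhythmarousal.pipeline import run_pipeline

config = {
    "synth": {
        "seed": 5,
        "n_trials": 2,
        "trial_on_s": 300.0,
        "trial_off_s": 60.0,
        "clock_offset_s": 3.0,
        "clock_drift_ppm": 30.0,
    },
    "analysis": {"min_prominence": 2.25, "bin_s": 60.0},
}

out = Path("scratch/pipeline_demo")
paths = run_pipeline(config, out)
print("artifacts written:")
for name, p in paths.items():
    print(f"  {name:24s} {p}")

summary = json.loads(paths["summary"].read_text())
print("\nheadline numbers:")
print(f"  transients detected: {summary['n_transients']} "
      f"(generated: {summary['n_true_transients']})")
print(f"  per-state rate/min:  { {k: round(v, 2) for k, v in summary['rate_per_min'].items()} }")
print(f"  transitions:         {summary['n_transitions']}")
print(f"  clock offset fit:    {summary['clock_offset_s']:.3f} s "
      f"(true {summary['true_clock']['offset_s']} s)")
print("Re-running with the same config reproduces these files byte-for-byte.")
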