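"""End-to-end parameter recovery: generator -> analysis -> ground truth.

One call builds a synthetic threshold dataset with known condition
deflections, normalizes it, fits the hierarchical robust-t model,
computes the matched-vs-rest contrast and the model-selection Bayes
factor, and compares every estimate against the generative truth.
"""

import json

from cfskit.synthdata import EffectProfile, recovery_experiment

report = recovery_experiment(
    n_participants=20,
    profile=EffectProfile(tuning_amplitude=0.4, outlier_rate=0.02),
    design="exp1",
    seed=4,
)

print(json.dumps({k: v for k, v in report.items()
                  if k not in ("condition_labels",)}, indent=2))
print()
print("z_errors are (posterior mean - truth) / posterior SD per condition;"
      "\nvalues within a few units indicate calibrated recovery. The"
      "\nmatched-vs-rest HDI excluding zero flags the tuning peak, and the"
      "\nBayes factor >> 1 selects the mask-speed model over the null.")
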