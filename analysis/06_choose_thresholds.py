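"""Choose the presence/absence probability cutoffs.

Out-of-fold predicted probabilities from the selected model are scanned for
the cutoff maximizing Cohen's kappa and the cutoff maximizing
sensitivity + specificity; the pair brackets the gray "threshold band" used
when mapping likely vs unlikely regeneration.
"""

import json
from pathlib import Path

from regenfire.pipeline import RunConfig, run_pipeline

cfg = RunConfig.from_yaml(Path(__file__).parent / "config.yaml")
run_pipeline(cfg, stages=["simulate", "metrics", "assemble", "select",
                          "threshold"])

doc = json.loads((Path(cfg.outdir) / "thresholds.json").read_text())
for method, rec in doc.items():
    print(f"{method}: threshold {rec['threshold']:.3f}  "
          f"kappa {rec['kappa']:.3f}  sensitivity {rec['sensitivity']:.3f}  "
          f"specificity {rec['specificity']:.3f}")
lo = min(r["threshold"] for r in doc.values())
hi = max(r["threshold"] for r in doc.values())
print(f"threshold band: [{lo:.3f}, {hi:.3f}]")
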