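"""Backward model selection by grouped 10-fold cross-validated AUC.

Phase 1 greedily removes climate terms and mean-climate x postfire-climate
interactions while CV AUC improves (biophysical terms are protected);
phase 2 tests postfire-climate x severity/seed-availability interactions.
"""

import json
from pathlib import Path

from regenfire.pipeline import RunConfig, run_pipeline

cfg = RunConfig.from_yaml(Path(__file__).parent / "config.yaml")
run_pipeline(cfg, stages=["simulate", "metrics", "assemble", "select"])

trace = json.loads((Path(cfg.outdir) / "selection_trace.json").read_text())

print(f"full model CV AUC: {trace['initial_cv_auc']:.4f}")
print(f"{'action':<8}{'candidate':<48}{'cv auc':>8}  accepted")
for step in trace["steps"]:
    auc = "   -  " if step["cv_auc"] != step["cv_auc"] else f"{step['cv_auc']:.4f}"
    print(f"{step['action']:<8}{step['candidate']:<48}{auc:>8}  "
          f"{'yes' if step['accepted'] else ''}")
print(f"selected model CV AUC: {trace['final_cv_auc']:.4f}")

final = trace["final_spec"]
climate = [t["name"] for t in final["terms"]
           if t["role"] != "biophysical"]
print(f"climate terms retained: {climate if climate else 'none'}")
print(f"interactions retained: {final['interactions'] or 'none'}")
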