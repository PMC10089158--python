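"""Generate the synthetic multi-fire study.

Fires get normally distributed random intercepts and a climate site each;
plots get biophysical covariates and Bernoulli recruitment outcomes from a
logit-linear truth with a log(plot-area) offset.  The truth parameters are
written alongside the data so later stages can be judged against them.
"""

from pathlib import Path

import pandas as pd

from regenfire.pipeline import RunConfig, run_pipeline

cfg = RunConfig.from_yaml(Path(__file__).parent / "config.yaml")
run_pipeline(cfg, stages=["simulate"])

out = Path(cfg.outdir)
plots = pd.read_csv(out / "plots.csv")
fires = pd.read_csv(out / "fires.csv")

print(f"simulated {len(fires)} fires ({fires.fire_year.min()}-"
      f"{fires.fire_year.max()}), {len(plots)} plots")
print(f"observed presence rate: {plots.presence.mean():.3f}")
print(f"plot areas {plots.area_m2.min():.0f}-{plots.area_m2.max():.0f} m2, "
      f"survey delay {plots.time_since_fire.min()}-"
      f"{plots.time_since_fire.max()} y postfire")
print(f"outputs in {out}/: plots.csv fires.csv climate.csv truth.yaml")
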