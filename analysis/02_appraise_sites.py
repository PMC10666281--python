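#!/usr/bin/env python
"""Estimate the causal intervention effect at every monitoring site.

For each site: de-weather the hourly record, average to days, detect
structural change points, classify whether the site responded (change point
inside the margin period around T0), and — for responders — fit the donut
sharp RDD and summarize the total effect with Monte Carlo intervals.
Writes the effect table and detected change points.
"""

from pathlib import Path

import pandas as pd

from aqcausal.pipeline import PipelineConfig, appraise_network, estimates_to_frame
from aqcausal.synthetic import SimConfig, read_hourly_long

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 2024


def main() -> None:
    inputs = ROOT / "inputs"
    out = ROOT / "effects"
    out.mkdir(parents=True, exist_ok=True)
    sim = SimConfig(
        n_sites=6, n_areas=200,
        true_tau=[-0.25, -0.10, 0.0, -0.25, -0.10, 0.0], seed=SEED,
    )
    config = PipelineConfig(sim=sim, master_seed=SEED).fast_profile()
    # stage isolation: read the persisted stage-01 inputs rather than
    # regenerating in memory
    conc = read_hourly_long(inputs / "conc_hourly.csv")
    weather = pd.read_csv(inputs / "weather_hourly.csv", index_col="timestamp",
                          parse_dates=True)
    bundle = {"conc": conc, "weather": weather}
    estimates, diags = appraise_network(config, bundle)
    frame = estimates_to_frame(estimates)
    frame.to_csv(out / "effect_estimates.csv", index=False)
    cps = pd.DataFrame(
        [
            {"site_id": sid, "date": d, "type": ty}
            for sid, diag in diags.items()
            for d, ty in zip(diag["change_dates"], diag["change_types"])
        ]
    )
    cps.to_csv(out / "change_points.csv", index=False)
    print(frame.to_string(index=False))
    print(f"\n{frame['response'].sum()} of {len(frame)} sites responded; "
          f"true effects were -25%, -10% and 0%")


if __name__ == "__main__":
    main()
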