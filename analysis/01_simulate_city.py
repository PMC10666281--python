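#!/usr/bin/env python
"""Generate the synthetic monitoring network and write its raw inputs.

Creates a six-site city observed hourly over 2019-2020 with an intervention
on 2020-03-23: weather-driven concentrations, a -2%/yr trend, site effects
of -25%, -10% and 0%, and a 200-area feature table whose true impact
surface is a known sparse function of three features plus a spatially
correlated field. Everything downstream reads these CSVs.
"""

from pathlib import Path

from aqcausal.synthetic import SimConfig, simulate_city, write_hourly_long

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimConfig(
        n_sites=6,
        n_areas=200,
        true_tau=[-0.25, -0.10, 0.0, -0.25, -0.10, 0.0],
        seed=SEED,
    )
    bundle = simulate_city(config)
    write_hourly_long(bundle["conc"], "no2", OUT / "conc_hourly.csv")
    bundle["weather"].to_csv(OUT / "weather_hourly.csv", index_label="timestamp")
    bundle["site_meta"].to_csv(OUT / "site_meta.csv", index=False)
    bundle["areas"].to_csv(OUT / "area_features.csv", index=False)
    print(f"simulated {config.n_sites} sites x {len(bundle['conc'])} hours, "
          f"{config.n_areas} areas -> {OUT}")
    print("true site effects:", bundle["truth"]["true_tau"])


if __name__ == "__main__":
    main()
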