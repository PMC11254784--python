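#!/usr/bin/env python
"""Simulate the synthetic study data.

Generates a ground-truth world (3 regions x 6 countries, 2000-2022) from
the default generative conditions, simulates two surveys per country with
instrument mix and design noise, and writes the observation, population
and covariate tables plus the ground-truth sidecar under
results/pipeline/.
"""

from _config import pipeline_config

from inactivity import io_cli

if __name__ == "__main__":
    cfg = pipeline_config()
    result = io_cli.run_pipeline(cfg, "simulate")
    print(f"wrote {result['observations']} prevalence observations to {cfg.outdir}")
    print("tables: observations.csv, population.csv, covariate.csv, truth.json")
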