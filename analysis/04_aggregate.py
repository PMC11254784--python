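#!/usr/bin/env python
"""Aggregate posterior surfaces to crude and age-standardised estimates.

Collapses the per-sex posterior prevalence surfaces (and the combined
both-sex surface) to global, regional and country estimates with 95%
uncertainty intervals, written to results/pipeline/estimates.csv.
"""

from _config import pipeline_config

from inactivity import io_cli

if __name__ == "__main__":
    cfg = pipeline_config()
    io_cli.run_pipeline(cfg, "aggregate")
    print(f"estimates written to {cfg.outdir / 'estimates.csv'}")
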