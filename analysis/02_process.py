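#!/usr/bin/env python
"""Harmonise the simulated survey observations.

Applies the configured crosswalk adjustments (identity by default) and
writes processed_observations.csv plus a rejection log; reports how many
rows survived.
"""

from _config import pipeline_config

from inactivity import io_cli

if __name__ == "__main__":
    cfg = pipeline_config()
    result = io_cli.run_pipeline(cfg, "process")
    print(f"{result['processed']} observations harmonised, {result['rejected']} rejected")
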