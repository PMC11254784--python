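#!/usr/bin/env python
"""Project to 2030 and classify progress toward the 15%-reduction target.

Extrapolates 2010-22 trends to 2030 draw-by-draw, computes the posterior
probability of meeting the target for every grouping, classifies progress
into the four certainty categories, and renders the summary report.
"""

from _config import pipeline_config

from inactivity import io_cli

if __name__ == "__main__":
    cfg = pipeline_config()
    summary = io_cli.run_pipeline(cfg, "assess")
    print("progress categories across groupings:", summary["categories"])
    io_cli.run_pipeline(cfg, "report")
    print((cfg.outdir / "report.txt").read_text())
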