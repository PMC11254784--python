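#!/usr/bin/env python
"""Fit the hierarchical probit model, one model per sex.

Runs the collapsed Gibbs sampler (4 chains, 2000 retained draws) on the
processed observations and saves posterior draws with convergence
diagnostics under results/pipeline/.
"""

from _config import pipeline_config

from inactivity import io_cli

if __name__ == "__main__":
    cfg = pipeline_config()
    diagnostics = io_cli.run_pipeline(cfg, "fit")
    for sex, d in diagnostics.items():
        print(f"{sex}: max split-R-hat {d['max_rhat']:.4f}, min ESS {d['min_ess']:.0f}")
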