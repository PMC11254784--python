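"""Shared configuration for the analysis drivers.

One place to set the seed, the output directory (results/pipeline) and the
reduced MCMC settings used for desk-scale runs; override the seed with
INACTIVITY_SEED.
"""

import os
from pathlib import Path

from inactivity import hier_model, io_cli

RESULTS = Path(__file__).resolve().parent.parent / "results" / "pipeline"


def pipeline_config(seed: int | None = None) -> io_cli.PipelineConfig:
    seed = seed if seed is not None else int(os.environ.get("INACTIVITY_SEED", "1"))
    return io_cli.PipelineConfig(
        outdir=RESULTS,
        seed=seed,
        model=hier_model.ModelConfig(n_draws=2000, chains=4, warmup=250, seed=seed),
    )
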