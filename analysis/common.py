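"""Shared configuration for the numbered analysis drivers.

All drivers operate on one work directory (results/pipeline) with one seed,
so each script picks up where the previous one left off and reruns are
reproducible end to end.
"""

import logging
from pathlib import Path

from kre.config import PipelineConfig

REPO_ROOT = Path(__file__).resolve().parent.parent


def analysis_config(seed: int = 1) -> PipelineConfig:
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    cfg = PipelineConfig(workdir=str(REPO_ROOT / "results" / "pipeline"), seed=seed)
    cfg.validate()
    return cfg
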