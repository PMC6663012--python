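"""Shared configuration for the analysis drivers.

One seed, one study-scale configuration; every driver rebuilds its inputs
deterministically from this seed (the generators are cheap and bit-stable),
so the numbered scripts can be run independently or in order.
"""

from circaprot.config import PipelineConfig

SEED = 42
RESULTS = "results"


def config() -> PipelineConfig:
    return PipelineConfig(seed=SEED).validate()
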