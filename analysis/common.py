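"""Shared configuration of the numbered analysis scripts.

One study configuration, used by every stage so the scripts can be run in
order (01 → 05) with artifacts accumulating under ``results/study/``.
The study emulates the full sampling design (1902 cows on 397 herds, a
four-generation pedigree) with desk-scale MCMC settings.
"""

from pathlib import Path

from milknet.pipeline import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_DIR = RESULTS / "study"


def study_config(seed: int = 20) -> PipelineConfig:
    return PipelineConfig(
        seed=seed,
        k=None,  # chosen by PCA at the 90% threshold
        chains=2,
        iterations=6000,
        burn_in=1500,
        thin=5,
        sem_k=2,
    )
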