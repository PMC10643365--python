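"""Shared configuration of the demo analysis.

A desk-scale stand-in for the study: 12 subjects, both repetition tasks,
two subregional configurations (one per pOp and M1 variant pairing), 25%
measurement noise, fixed seed.  All numbered scripts operate on the same
output directory and re-use completed stages via the pipeline manifest.
"""

from pathlib import Path

from speechdcm import CohortSpec, PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "demo"


def demo_config() -> PipelineConfig:
    return PipelineConfig(
        out_dir=str(RESULTS),
        cohort=CohortSpec(
            n_subjects=12,
            tasks=("word", "pseudoword"),
            configurations=("M1-f&dpOp", "M1-tl&vpOp"),
            noise_sd=0.25,
            seed=42,
        ),
    )
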