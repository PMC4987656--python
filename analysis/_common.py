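"""Shared configuration for the numbered analysis scripts.

Every script re-runs the pipeline prefix it needs (the synthetic study is
cheap to regenerate), so each one is independently runnable; all write under
``results/``.
"""

from pathlib import Path

from kranzless.io import RunConfig
from kranzless.pipeline import run_pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20160817  # date-stamp seed for the study-scale synthetic run

# Study-scale conditions: a 100-gene, three-sub-genome transcriptome with the
# six NAD-ME genes grain-up, 31 genotypes, grain at two post-anthesis stages
# plus a seedling-stage leaf.
STUDY_CONFIG = dict(
    simulate={"n_genes": 100, "n_genotypes": 31,
              "transcript_length_range": (300, 1500)},
)


def run_stages(*stages: str):
    RESULTS.mkdir(exist_ok=True)
    cfg = RunConfig(outdir=str(RESULTS / "pipeline"), seed=SEED,
                    stages=tuple(stages), **STUDY_CONFIG)
    return run_pipeline(cfg)
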