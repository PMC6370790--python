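"""Shared study design for the analysis scripts.

Two synthetic continents with a common species-pool size but different
temperature gradients (the "east" continent is slightly colder overall),
both with a positive lightness-temperature coupling — the pattern expected
under thermal melanism.  Every script regenerates its inputs from these
seeded configs, so the scripts can be run independently and always agree.
"""

from melanomap.pipeline import PipelineConfig

SEED = 1

CONTINENTS = {
    "west": {"n_species": 120,
             "extent": (0.0, 0.0, 2_000_000.0, 1_500_000.0)},
    "east": {"n_species": 120,
             "extent": (0.0, 0.0, 2_000_000.0, 1_500_000.0),
             "tmp_south": 22.0, "tmp_north": -8.0},
}


def pipeline_config(out_dir="results/pipeline") -> PipelineConfig:
    return PipelineConfig(
        seed=SEED, out_dir=out_dir,
        continents={k: dict(v) for k, v in CONTINENTS.items()},
        gls_max_n=400, gls_variables=("TMP",))
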