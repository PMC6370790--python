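"""Render quantile choropleth maps of assemblage mean lightness.

One map per continent x side x family scope, binned into lightness
quantiles with red marking the lightest assemblages and blue the darkest.
Requires the tables written by 03_build_assemblages.py.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from worlds import pipeline_config  # noqa: E402

from melanomap.grid import grid_from_frame  # noqa: E402
from melanomap.io import read_table  # noqa: E402
from melanomap.pipeline import render_maps  # noqa: E402


def main() -> None:
    cfg = pipeline_config()
    out = Path("results")
    for name in sorted(cfg.continents):
        asm_path = out / f"assemblages_{name}.csv"
        if not asm_path.exists():
            raise SystemExit("run analysis/03_build_assemblages.py first")
        grid = grid_from_frame(read_table(out / f"grid_{name}.csv"))
        paths = render_maps(read_table(asm_path), grid, cfg.k_bins,
                            out / "maps", continent=name)
        print(f"{name}: {len(paths)} maps -> results/maps/")


if __name__ == "__main__":
    main()
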