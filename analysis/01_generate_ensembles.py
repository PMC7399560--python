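#!/usr/bin/env python
"""Generate desk-scale conformational ensembles for four bundle designs.

Emulates the four six-helix-bundle variants — untwisted (s), one
right-handed axial turn (1x-rh), one left-handed turn (1x-lh), and two
left-handed turns (2x-lh) — as wormlike-chain bundles with the designed
overtwist partitioned between duplex winding and solenoidal writhe.
Full-scale geometry (420 nm contour, l_p/l_c = 8) is used here since
ensemble generation is cheap; the DFT stages (04/05) coarse-grain and
scale down.  Writes one ensemble container per design under results/.
"""

import sys
from pathlib import Path

from chiralfil import pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"

# design overtwist (turns/um) if held straight/untwisted, axial turns
DESIGNS = {
    "2x-lh": {"overtwist": 15.07, "axial_turns": -2.0},
    "1x-lh": {"overtwist": 7.00, "axial_turns": -1.0},
    "s": {"overtwist": 0.0, "axial_turns": 0.0},
    "1x-rh": {"overtwist": -6.42, "axial_turns": 1.0},
}


def config_for(design: str, seed: int = 2024) -> dict:
    d = DESIGNS[design]
    return pipeline.load_config(overrides={
        "seed": seed,
        "outdir": str(RESULTS / design),
        "design_label": design,
        "chain": {"axial_twist_turns": d["axial_turns"]},
        "linking": {"design_overtwist": d["overtwist"]},
        "ensemble": {"n": 80},
    })


def main():
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 2024
    for design in DESIGNS:
        cfg = config_for(design, seed)
        ens = pipeline.run_generate(cfg)
        print(f"{design}: {ens.count} conformations -> "
              f"{pipeline.ensemble_path(cfg)}")


if __name__ == "__main__":
    main()
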