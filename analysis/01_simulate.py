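"""Simulate the four-sample saliva whole-ecosystem study.

Generates the 2 healthy (H, ~70% host DNA) + 2 caries-active (C, ~45%
host DNA) sample set: a 20-genome community with lognormal abundances
and abundance-linked functional repertoires, per-sample read-pair
alignment tables, gene catalogs (the C group carries a seeded 2x count
shift on five hierarchy-2 categories), a toy host gene model with
reference sequence, and two noisy variant call sets per sample.

Data land in scratch/demo_data/; downstream scripts read them from there.
"""

import sys
from pathlib import Path

from salivalink.pipeline import make_demo_dataset

SEED = 42
DATA_DIR = Path("scratch/demo_data")


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else SEED
    cfg = make_demo_dataset(DATA_DIR, seed=seed)
    files = sorted(p.name for p in DATA_DIR.iterdir())
    print(f"wrote {len(files)} files to {DATA_DIR} (seed={seed}):")
    for name in files:
        print(f"  {name}")
    print(f"pipeline config: {cfg}")


if __name__ == "__main__":
    main()
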