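#!/usr/bin/env python
"""Generate the synthetic test-retest study the downstream analyses read.

Eight subjects, two sessions each (morning/afternoon), paired 5-min water
and 30-min ammonia scans with full blood data, written as plain CSV/YAML
under results/study/.
"""

import argparse
from pathlib import Path

from petkin import io as pio
from petkin.synthetic import SyntheticConfig, generate_study


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--subjects", type=int, default=8)
    parser.add_argument("--out", type=Path, default=Path("results/study"))
    args = parser.parse_args()

    config = SyntheticConfig(seed=args.seed, n_subjects=args.subjects)
    study = generate_study(config)
    pio.write_study(study, args.out)
    n_regions = len(config.regions)
    print(f"wrote {len(study.sessions)} sessions x {n_regions} regions to {args.out}")
    print(f"config hash {pio.config_hash(config)}, seed {config.seed}")


if __name__ == "__main__":
    main()
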