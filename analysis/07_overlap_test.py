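#!/usr/bin/env python
"""Gene-set overlap significance (hypergeometric upper tail).

Tests the planted overlap between the regulated-gene list and the
super-enhancer-associated gene list against the simulated 20000-gene
universe.
"""

import argparse
import json

from splicemap.pipeline import RunConfig, run_stage


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    cfg = RunConfig(outdir=args.out, seed=args.seed)
    run_stage("overlap", cfg)
    res = json.load(open(cfg.path("overlap_result.json")))
    print(f"overlap {res['observed_overlap']} of {res['draws']} drawn genes "
          f"(K={res['successes_in_population']}, N={res['population_size']}): "
          f"P = {res['p_upper']:.2g}")


if __name__ == "__main__":
    main()
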