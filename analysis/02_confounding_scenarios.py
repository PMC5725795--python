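#!/usr/bin/env python
"""Primary analysis, confounding scenarios: which outcome is robust to which confounder?

Runs the four four-node scenarios (V pointing at ICS+GA, GA+BW, ICS+BW, or
all three) with the eight-model battery (M1..M4 plus V-adjusted forms) and
writes the summary table including the d-separation "association confounded?"
column.

Key reading of the output: confounders of the exposure-GA relationship bias
the unadjusted BW/LBW models but never the SGA model; the GA-BW confounder
biases only the GA-adjusted BW model (collider bias, eliminated by adding V);
an exposure-BW confounder biases every unadjusted model including SGA.
"""

import argparse
from pathlib import Path

from sga_mediation import RunConfig, render_table, summarize_run, write_manifest, write_markdown

SCENARIOS = ["conf1", "conf2", "conf3", "conf4"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--reps", type=int, default=1000)
    parser.add_argument("--n", type=int, default=20_000)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    summaries = []
    for name in SCENARIOS:
        print(f"running {name} (linear+homo, n={args.n}, reps={args.reps}) ...")
        summaries.extend(
            summarize_run(name, n=args.n, reps=args.reps, seed=args.seed,
                          estimates_csv=args.out / f"estimates_{name}.csv",
                          with_bias_flags=True)
        )
    table = render_table(summaries)
    table.to_csv(args.out / "confounding_scenarios.csv", index=False)
    write_markdown(table, args.out / "confounding_scenarios.md")
    write_manifest(
        RunConfig(scenarios=SCENARIOS, n=args.n, reps=args.reps, seed=args.seed,
                  out_dir=str(args.out)),
        args.out / "confounding_scenarios_manifest.json",
    )

    print(table.to_string(index=False))
    collider = table[(table.scenario == "conf2") & (table.model == "M2")].iloc[0]
    sga = table[(table.scenario == "conf2") & (table.model == "M4")].iloc[0]
    print(
        f"\nGA-BW confounder: GA-adjusted BW model M2 shows collider bias "
        f"(mean {collider['mean']:.3f} g, flagged {collider['association_confounded']}), "
        f"while the SGA model M4 stays unbiased (mean {sga['mean']:.4f}, "
        f"flagged {sga['association_confounded']})."
    )
    print(f"wrote {args.out / 'confounding_scenarios.csv'}")


if __name__ == "__main__":
    main()
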