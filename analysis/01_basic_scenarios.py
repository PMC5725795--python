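#!/usr/bin/env python
"""Primary analysis, basic scenarios: what does each outcome's ICS coefficient estimate?

Runs the four unconfounded three-node scenarios (null / fully mediated /
direct / both effects of the exposure on BW) at full study scale by default,
fits M1..M4 on every replicate, and writes the Monte-Carlo summary table.

Key reading of the output: the BW model without GA (M1) estimates the total
effect (−366.5 g when a −2-week GA shift is fully mediating); the GA-adjusted
BW model (M2) and the SGA model (M4) estimate the direct effect only, so both
sit at the null in the fully mediated scenario.
"""

import argparse
from pathlib import Path

from sga_mediation import RunConfig, render_table, summarize_run, write_manifest, write_markdown

SCENARIOS = ["basic1", "basic2", "basic3", "basic4"]


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
                          estimates_csv=args.out / f"estimates_{name}.csv")
        )
    table = render_table(summaries)
    table.to_csv(args.out / "basic_scenarios.csv", index=False)
    write_markdown(table, args.out / "basic_scenarios.md")
    write_manifest(
        RunConfig(scenarios=SCENARIOS, n=args.n, reps=args.reps, seed=args.seed,
                  out_dir=str(args.out)),
        args.out / "basic_scenarios_manifest.json",
    )

    print(table.to_string(index=False))
    mediated = table[(table.scenario == "basic2")]
    m1 = mediated[mediated.model == "M1"].iloc[0]
    m4 = mediated[mediated.model == "M4"].iloc[0]
    print(
        f"\nFully mediated scenario: M1 (total) mean {m1['mean']:.2f} g vs the "
        f"-366.50 g closed form; M4 (SGA) mean {m4['mean']:.4f} — "
        f"{'null' if m4['null_ics_effect'] == 'yes' else 'NON-null'}, i.e. SGA "
        "does not register a purely mediated effect."
    )
    print(f"wrote {args.out / 'basic_scenarios.csv'}")


if __name__ == "__main__":
    main()
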