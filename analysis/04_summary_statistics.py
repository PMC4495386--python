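#!/usr/bin/env python
"""Summary statistics of an emigration dataset.

Reports per-treatment choice proportions (with Wilson intervals), the pooled
exact binomial comparison of fluctuating vs constant choices, Poisson
log-linear accumulation slopes per nest and treatment, and the desk
quantities implied by the rate parameters.
"""

import argparse
from pathlib import Path

from nestquorum import choice_table, read_dataset, summary_report, write_report


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("dataset", nargs="?",
                        default=Path("results/experiment/dataset.csv"),
                        type=Path)
    parser.add_argument("--out", type=Path, default=Path("results/experiment"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    df = read_dataset(args.dataset)
    report = summary_report(df)
    write_report(report, args.out / "summary.json")
    choice_table(df).write_csv(args.out / "choice_table.csv")

    print("choice table (per treatment):")
    for row in report["choice_table"]:
        print(f"  {row['treatment']}: FN {row['n_FN']}, CN {row['n_CN']}, "
              f"none {row['n_none']}; P(choose FN) = {row['proportion_FN']:.3f} "
              f"[{row['ci_low']:.3f}, {row['ci_high']:.3f}]")
    pooled = report["pooled_test"]
    print(f"pooled: FN {pooled['n_FN']} vs CN {pooled['n_CN']}, one-sided "
          f"exact binomial p = {pooled['p_value_one_sided']:.3f}")
    print("accumulation slopes (per minute, log scale):")
    for treatment, nests in report["slopes"].items():
        for nest, est in nests.items():
            if "rate_per_min" in est:
                print(f"  {treatment} {nest}: {est['rate_per_min']:.4f} "
                      f"(SE {est['se_rate']:.4f})")
            else:
                print(f"  {treatment} {nest}: undefined")
    dq = report["derived_quantities"]
    print(f"positive-assessment probabilities (%): "
          f"{dq['acceptance_probability_pct']}")
    print(f"wrote {args.out / 'summary.json'}")


if __name__ == "__main__":
    main()
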