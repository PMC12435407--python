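"""Analytic accuracy baselines for the indexed AnBn task.

Computes, by enumeration through the grammar validator, the probability of
producing a fully grammatical sequence (i) by touching items uniformly at
random and (ii) under the partial "all blue, then all red" strategy, for
4-, 6- and 8-item arrays.  These are the reference lines the behavioral
accuracy summaries are compared against.
"""

from pathlib import Path

import pandas as pd

from seqmem.grammar import blue_first_baseline, chance_baseline, format_baseline_percent

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for n in (2, 3, 4):
        rows.append(
            {
                "n_pairs": n,
                "array_size": 2 * n,
                "chance": chance_baseline(n),
                "chance_pct": format_baseline_percent(chance_baseline(n), n),
                "blue_first": blue_first_baseline(n),
                "blue_first_pct": format_baseline_percent(blue_first_baseline(n), n),
            }
        )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "baselines.csv", index=False)
    print(df.to_string(index=False))
    print(
        "\nRandom responding succeeds on 8.3% of 4-item arrays but only "
        "0.8% of 6-item arrays; ordering blue before red without pair "
        "matching yields 50% / 17% / 4% at 4 / 6 / 8 items."
    )


if __name__ == "__main__":
    main()
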