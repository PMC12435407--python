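"""Operation-count schedules: the architectures' diverging RT predictions.

Tabulates the per-touch store/traverse/pop counts each architecture incurs
when producing center-embedded and cross-serial sequences.  The queue
predicts a strictly decreasing op count over the second half of
center-embedded sequences (iterative search), the stack predicts a flat
profile there but a large first-touch reversal cost for cross-serial
sequences — the signatures the fitted models are judged on.
"""

from pathlib import Path

import pandas as pd

from seqmem.architectures import retrieve_schedule
from seqmem.grammar import CENTER_EMBEDDED, CROSS_SERIAL

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for arch in ("stack", "queue"):
        for cond in (CENTER_EMBEDDED, CROSS_SERIAL):
            for n in (2, 3, 4):
                sched = retrieve_schedule(arch, cond, n)
                for pos, ops in enumerate(sched.second_half_ops, start=1):
                    rows.append(
                        {
                            "architecture": arch,
                            "condition": cond,
                            "n_pairs": n,
                            "second_half_position": pos,
                            "ops": ops,
                        }
                    )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "op_schedules.csv", index=False)
    wide = df[df["n_pairs"] == 4].pivot_table(
        index=["architecture", "condition"], columns="second_half_position", values="ops"
    )
    print("Second-half op counts, 8-item arrays:")
    print(wide.to_string())
    print(
        "\nOnly queue + center-embedded decreases across positions; that slope, "
        "scaled by the per-operation latency, is what separates the models in RT."
    )


if __name__ == "__main__":
    main()
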