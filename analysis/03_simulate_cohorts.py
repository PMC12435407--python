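"""Simulate the synthetic study: three 20-participant cohorts.

Generates queue-based cohorts for both grammar conditions and a stack-based
center-embedded cohort, each over the full further-training design (5 test +
20/40/40 training trials at 4/6/8 items), with participant parameters drawn
from the recovery ranges.  Ground-truth tables go to results/; the bulky
trial logs consumed by the downstream scripts go to scratch/.
"""

from pathlib import Path

from seqmem.cohort import CohortSpec, ExperimentDesign, simulate_cohort
from seqmem.grammar import CENTER_EMBEDDED, CROSS_SERIAL
from seqmem.io import write_trial_log

OUT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"

COHORTS = {
    "queue_ce": (CENTER_EMBEDDED, "queue", 101),
    "queue_cs": (CROSS_SERIAL, "queue", 102),
    "stack_ce": (CENTER_EMBEDDED, "stack", 103),
}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    for name, (cond, arch, seed) in COHORTS.items():
        spec = CohortSpec(
            n_participants=20,
            architecture=arch,
            design=ExperimentDesign(condition=cond),
            seed=seed,
        )
        table, truth = simulate_cohort(spec)
        write_trial_log(table, SCRATCH / f"trials_{name}.csv")
        truth.to_csv(OUT / f"truth_{name}.csv", index=False)
        n_err = table.groupby(["participant_id", "n_pairs", "phase", "trial_index"])[
            "complete"
        ].first()
        print(
            f"{name}: {len(truth)} participants, {len(n_err)} trials, "
            f"{(~n_err).mean():.0%} ending in an error"
        )


if __name__ == "__main__":
    main()
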