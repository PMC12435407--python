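"""Trial-log CSV I/O with schema validation.

Dialect: UTF-8, comma-separated, header row required, "NA" for a missing
first_error_index.  One row per touch; see REQUIRED_COLUMNS for the schema.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import TrialRecord
from .grammar import ItemToken

REQUIRED_COLUMNS = [
    "participant_id",
    "condition",
    "n_pairs",
    "phase",
    "trial_index",
    "touch_index",
    "pair_id",
    "item_class",
    "rt_ms",
    "complete",
    "first_error_index",
]

_TRIAL_KEY = ["participant_id", "condition", "n_pairs", "phase", "trial_index"]


class TrialLogSchemaError(ValueError):
    """Raised when a trial-log table violates the schema."""


def write_trial_log(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trial-log table; missing first_error_index becomes "NA"."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TrialLogSchemaError(f"table is missing required column(s): {missing}")
    out = table[REQUIRED_COLUMNS].copy()
    out["first_error_index"] = out["first_error_index"].astype("Int64")
    out.to_csv(path, index=False, na_rep="NA")


def read_trial_log(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-log CSV; errors name the offending column/row."""
    table = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TrialLogSchemaError(f"file is missing required column(s): {missing}")
    table = table[REQUIRED_COLUMNS].copy()
    table["first_error_index"] = table["first_error_index"].astype("Int64")
    table["complete"] = table["complete"].astype(bool)

    bad_rt = table.index[table["rt_ms"] <= 0]
    if len(bad_rt):
        raise TrialLogSchemaError(f"rt_ms must be > 0 (first bad row: {int(bad_rt[0])})")
    bad_class = table.index[~table["item_class"].isin(["A", "B"])]
    if len(bad_class):
        raise TrialLogSchemaError(
            f"item_class must be 'A' or 'B' (first bad row: {int(bad_class[0])})"
        )
    for key, g in table.groupby(_TRIAL_KEY, sort=False):
        idx = g["touch_index"].to_numpy()
        if not np.array_equal(np.sort(idx), np.arange(1, len(idx) + 1)):
            raise TrialLogSchemaError(f"touch_index not contiguous from 1 in trial {key}")
    for pid, g in table.groupby("participant_id", sort=False):
        if g["condition"].nunique() != 1:
            raise TrialLogSchemaError(f"condition not constant within participant {pid!r}")
    return table


def table_to_trials(table: pd.DataFrame, lengths: tuple[int, ...] | None = None) -> dict[str, list[TrialRecord]]:
    """Reconstruct per-participant TrialRecord lists from a trial-log table.

    The learning-curve clock (gompertz_t) is rebuilt as the cumulative count
    of training trials across lengths, taken in ``lengths`` order (defaults
    to ascending array size, matching the experiment's progression).
    """
    out: dict[str, list[TrialRecord]] = {}
    for pid, ptab in table.groupby("participant_id", sort=False):
        if lengths is None:
            plengths = tuple(sorted(ptab["n_pairs"].unique()))
        else:
            plengths = lengths
        trials: list[TrialRecord] = []
        t_clock = 0
        for n in plengths:
            ntab = ptab[ptab["n_pairs"] == n]
            for phase in ("test", "training"):
                sub = ntab[ntab["phase"] == phase]
                for ti in sorted(sub["trial_index"].unique()):
                    g = sub[sub["trial_index"] == ti].sort_values("touch_index")
                    fei = g["first_error_index"].iloc[0]
                    trials.append(
                        TrialRecord(
                            condition=g["condition"].iloc[0],
                            n_pairs=int(n),
                            trial_index=int(ti),
                            feedback=phase == "training",
                            touches=[
                                ItemToken(int(r.pair_id), r.item_class) for r in g.itertuples()
                            ],
                            rts=list(g["rt_ms"].astype(float)),
                            first_error_index=None if pd.isna(fei) else int(fei),
                            complete=bool(g["complete"].iloc[0]),
                            gompertz_t=float(t_clock),
                            participant_id=str(pid),
                        )
                    )
                    if phase == "training":
                        t_clock += 1
        out[str(pid)] = trials
    return out
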