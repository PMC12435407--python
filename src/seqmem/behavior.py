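"""Behavioral summaries: trial exclusions, accuracy vs analytic baselines,
and second-half response-time profiles with OLS slopes.

The RT profile is the behavioral signature that separates the architectures:
restricted to complete, grammatical training trials, the inter-touch RTs over
second-half positions (the interval into the first red item is dropped, since
it can reflect a half-switch cost rather than retrieval) slope downward under
a queue producing center-embedded sequences and stay flat otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grammar import GrammarSpec, ItemToken, blue_first_baseline, chance_baseline, is_grammatical

TRIAL_KEY = ["participant_id", "condition", "n_pairs", "phase", "trial_index"]


def exclude_trials(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop trials in which any single item was pressed more than twice.

    Returns the filtered table and the number of excluded trials.
    """
    counts = (
        table.groupby(TRIAL_KEY + ["pair_id", "item_class"], sort=False)
        .size()
        .reset_index(name="presses")
    )
    bad = counts[counts["presses"] > 2][TRIAL_KEY].drop_duplicates()
    if bad.empty:
        return table.copy(), 0
    merged = table.merge(bad.assign(_bad=True), on=TRIAL_KEY, how="left")
    kept = merged[merged["_bad"].isna()].drop(columns="_bad").reset_index(drop=True)
    return kept, len(bad)


def _trial_is_grammatical(group: pd.DataFrame) -> bool:
    n = int(group["n_pairs"].iloc[0])
    if len(group) != 2 * n:
        return False
    g = group.sort_values("touch_index")
    seq = [ItemToken(int(r.pair_id), r.item_class) for r in g.itertuples()]
    return is_grammatical(seq, GrammarSpec(group["condition"].iloc[0], n))


def accuracy_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Proportion of fully grammatical test trials per condition x length.

    Analytic chance and blue-then-red baselines are attached for comparison.
    """
    test = table[table["phase"] == "test"]
    if test.empty:
        raise ValueError("no test-phase rows in table")
    rows = []
    for (cond, n), sub in test.groupby(["condition", "n_pairs"]):
        ok = [
            _trial_is_grammatical(g)
            for _, g in sub.groupby(["participant_id", "trial_index"], sort=False)
        ]
        rows.append(
            {
                "condition": cond,
                "n_pairs": int(n),
                "n_trials": len(ok),
                "prop_correct": float(np.mean(ok)),
                "chance": chance_baseline(int(n)),
                "blue_first": blue_first_baseline(int(n)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RTProfile:
    """Second-half RT means/SEs by position and per-condition OLS slopes.

    ``profile`` has one row per condition x n_pairs x position (positions are
    second-half touch indices 2..n; position 1 is excluded); ``slopes`` has
    the OLS slope (ms per position) fit on participant-mean RTs, with its
    standard error and p-value.
    """

    profile: pd.DataFrame
    slopes: pd.DataFrame

    def slope(self, condition: str, n_pairs: int) -> float:
        row = self.slopes[
            (self.slopes["condition"] == condition) & (self.slopes["n_pairs"] == n_pairs)
        ]
        return float(row["slope"].iloc[0])


def rt_profile(table: pd.DataFrame, min_positions: int = 2) -> RTProfile:
    """Item-to-item RT profile over second-half positions of correct trials.

    Uses complete grammatical training trials only; drops the last-A -> first-B
    interval; aggregates by second-half position (2..n); slope by ordinary
    least squares on participant-mean RTs vs position.  Lengths offering
    fewer than ``min_positions`` analyzable positions are skipped; raises if
    none remain.
    """
    training = table[(table["phase"] == "training") & (table["complete"])]
    keep = []
    for key, g in training.groupby(TRIAL_KEY, sort=False):
        if _trial_is_grammatical(g):
            keep.append(g)
    if not keep:
        raise ValueError("no complete grammatical training trials")
    correct = pd.concat(keep, ignore_index=True)
    correct = correct[correct["touch_index"] > correct["n_pairs"] + 1].copy()
    correct["position"] = correct["touch_index"] - correct["n_pairs"]

    prof_rows = []
    slope_rows = []
    for (cond, n), sub in correct.groupby(["condition", "n_pairs"]):
        n = int(n)
        if n - 1 < min_positions:  # positions 2..n
            continue
        pmeans = (
            sub.groupby(["participant_id", "position"])["rt_ms"].mean().reset_index()
        )
        for pos, grp in sub.groupby("position"):
            by_p = grp.groupby("participant_id")["rt_ms"].mean()
            prof_rows.append(
                {
                    "condition": cond,
                    "n_pairs": n,
                    "position": int(pos),
                    "mean_rt": float(by_p.mean()),
                    "se_rt": float(by_p.std(ddof=1) / np.sqrt(len(by_p))) if len(by_p) > 1 else np.nan,
                    "n_participants": int(len(by_p)),
                }
            )
        X = sm.add_constant(pmeans["position"].to_numpy(dtype=float))
        ols = sm.OLS(pmeans["rt_ms"].to_numpy(dtype=float), X).fit()
        slope_rows.append(
            {
                "condition": cond,
                "n_pairs": n,
                "slope": float(ols.params[1]),
                "slope_se": float(ols.bse[1]),
                "p_value": float(ols.pvalues[1]),
                "n_obs": int(len(pmeans)),
            }
        )
    if not slope_rows:
        raise ValueError("fewer than 2 second-half positions at every length")
    return RTProfile(profile=pd.DataFrame(prof_rows), slopes=pd.DataFrame(slope_rows))
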