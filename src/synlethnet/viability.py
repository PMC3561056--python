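"""Normalization of raw nuclei counts to percent-of-control viability.

Every well is expressed as a percentage of the mean count of the
normalization-control wells (by default the GAPDH-silenced condition) of the
same experiment, then collapsed to a per-condition mean with its standard
error (SEM = sd / sqrt(n), sample sd). Viability above 100% (faster
proliferation than control) is reported as-is, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ViabilitySummary",
    "DEFAULT_CONTROL_CONDITIONS",
    "normalize_to_control",
    "average_experiment_sem",
    "write_summaries_tsv",
    "read_summaries_tsv",
]

#: condition ids treated as controls when averaging the experiment SEM
DEFAULT_CONTROL_CONDITIONS: tuple[str, ...] = ("GAPDH", "NS")

SUMMARY_COLUMNS = ["experiment_id", "condition_id", "genes", "mean_viability_pct", "sem_pct", "n"]


@dataclass(frozen=True)
class ViabilitySummary:
    """Per-condition viability as percent of control, with SEM."""

    condition_id: str
    genes_targeted: tuple[str, ...]
    mean_viability: float
    sem: float
    n_wells: int
    experiment_id: str


def normalize_to_control(
    wells: pd.DataFrame, control_condition: str, experiment_id: str = "exp1"
) -> pd.DataFrame:
    """Normalize well counts to the control condition's mean count.

    Each well's relative viability is ``100 * count / mean(control counts)``;
    conditions are then summarized as mean, SEM and well count. The control
    condition's own mean is 100 by construction.

    Parameters
    ----------
    wells
        Well table with columns ``condition_id, genes_targeted, nuclei_count``
        (the :mod:`synlethnet.simdata` dialect).
    control_condition
        Condition id of the normalization control (e.g. ``"GAPDH"``).
    experiment_id
        Batch label recorded on every summary row; wells passed in one call
        are normalized against this batch's own control.

    Returns
    -------
    DataFrame with columns ``experiment_id, condition_id, genes,
    mean_viability_pct, sem_pct, n``, conditions in first-appearance order.
    """
    ctrl = wells.loc[wells["condition_id"] == control_condition, "nuclei_count"]
    if len(ctrl) < 2 or ctrl.mean() <= 0:
        raise ValueError(
            f"control degenerate: condition {control_condition!r} has "
            f"{len(ctrl)} wells with mean {ctrl.mean() if len(ctrl) else 'n/a'}"
        )
    sizes = wells.groupby("condition_id", sort=False).size()
    small = sizes[sizes < 2]
    if not small.empty:
        raise ValueError(f"conditions with fewer than 2 wells: {', '.join(small.index)}")

    rel = 100.0 * wells["nuclei_count"].to_numpy(dtype=float) / float(ctrl.mean())
    df = wells[["condition_id", "genes_targeted"]].copy()
    df["rel"] = rel
    grouped = df.groupby("condition_id", sort=False)
    out = pd.DataFrame(
        {
            "experiment_id": experiment_id,
            "condition_id": sizes.index,
            "genes": grouped["genes_targeted"].first(),
            "mean_viability_pct": grouped["rel"].mean(),
            "sem_pct": grouped["rel"].std(ddof=1) / np.sqrt(sizes),
            "n": sizes,
        }
    ).reset_index(drop=True)
    return out


def average_experiment_sem(
    summaries: pd.DataFrame,
    experiment_id: str | None = None,
    control_conditions: Iterable[str] = DEFAULT_CONTROL_CONDITIONS,
    scope: str = "singles",
) -> float:
    """Arithmetic mean SEM over an experiment's conditions.

    Three times this value is the synthetic-lethality call threshold.
    Conditions listed in ``control_conditions`` (the normalization and
    non-silencing controls) are always excluded.

    ``scope="singles"`` (default) averages over the single-knockdown
    conditions only: those are unaffected by genetic interactions, so the
    noise estimate — and hence the call threshold — cannot be deflated by
    strong interactions suppressing double-knockdown viabilities (and with
    it their SEMs). ``scope="all"`` averages over every non-control
    condition, doubles included.
    """
    df = summaries
    if experiment_id is not None:
        df = df[df["experiment_id"] == experiment_id]
    if df.empty:
        raise ValueError(f"no summaries for experiment {experiment_id!r}")
    df = df[~df["condition_id"].isin(set(control_conditions))]
    if scope == "singles":
        n_genes = df["genes"].fillna("").str.split(";").map(lambda g: len([x for x in g if x]))
        singles = df[n_genes == 1]
        df = singles if not singles.empty else df  # fall back if no singles present
    elif scope != "all":
        raise ValueError(f"scope must be 'singles' or 'all', got {scope!r}")
    if df.empty:
        raise ValueError("no non-control conditions to average SEM over")
    return float(df["sem_pct"].mean())


def write_summaries_tsv(summaries: pd.DataFrame, path) -> None:
    summaries.to_csv(path, sep="\t", index=False)


def read_summaries_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"experiment_id": str, "condition_id": str})
    df["genes"] = df["genes"].fillna("")
    return df
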