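"""Synthetic-lethality calling under the multiplicative interaction model.

The null expectation for a double knockdown is the product of the two single
knockdowns' percent viabilities (``v_pred = v_a * v_b / 100``). The
interaction statistic is the proliferative defect ``v_pred - v_obs``
(positive = worse than expected). A pair is called synthetic lethal when its
defect is at least ``threshold_multiplier`` times the average SEM of the
experiment (default multiplier 3, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .viability import DEFAULT_CONTROL_CONDITIONS, average_experiment_sem

__all__ = [
    "InteractionCall",
    "predict_double_viability",
    "proliferative_defect",
    "call_interactions",
    "write_calls_tsv",
    "read_calls_tsv",
]

CALL_COLUMNS = [
    "experiment_id",
    "central",
    "cancer",
    "v_central",
    "v_cancer",
    "v_obs",
    "v_pred",
    "defect",
    "threshold",
    "call",
]


@dataclass(frozen=True)
class InteractionCall:
    """Scored gene pair: observed vs multiplicative-model viability."""

    central_gene: str
    cancer_gene: str
    v_central: float
    v_cancer: float
    v_obs: float
    v_pred: float
    defect: float
    threshold: float
    is_synthetic_lethal: bool
    experiment_id: str


def predict_double_viability(v_a: float, v_b: float) -> float:
    """Multiplicative-model prediction on the percent scale: v_a * v_b / 100."""
    if v_a < 0 or v_b < 0:
        raise ValueError(f"viabilities must be >= 0, got ({v_a}, {v_b})")
    return v_a * v_b / 100.0


def proliferative_defect(v_pred: float, v_obs: float) -> float:
    """Predicted minus observed viability; positive values flag candidate lethality."""
    return v_pred - v_obs


def call_interactions(
    summaries: pd.DataFrame,
    threshold_multiplier: float = 3.0,
    central_genes: Iterable[str] | None = None,
    control_conditions: Iterable[str] = DEFAULT_CONTROL_CONDITIONS,
    sem_scope: str = "singles",
    add_fdr: bool = False,
) -> pd.DataFrame:
    """Score every double-knockdown condition for synthetic lethality.

    Doubles are rows whose ``genes`` field holds two semicolon-joined
    symbols; both constituent single knockdowns must be present in the same
    experiment. The call threshold is recomputed per experiment as
    ``threshold_multiplier`` times that experiment's average non-control SEM.

    Parameters
    ----------
    summaries
        Viability summary table (:func:`synlethnet.viability.normalize_to_control`).
    threshold_multiplier
        Multiple of the average experiment SEM required to call lethality.
    central_genes
        If given, the member of each pair found in this set is reported as
        the central gene; otherwise the first-listed gene is taken as central.
    sem_scope
        Which conditions enter the average-SEM noise estimate
        (see :func:`synlethnet.viability.average_experiment_sem`).
    add_fdr
        Annotate each pair with a one-sided normal p-value for defect > 0
        (error propagated from the three SEMs) and a Benjamini-Hochberg
        q-value. Annotation only — the lethality call itself remains the
        fixed-threshold rule.

    Returns
    -------
    DataFrame with columns ``experiment_id, central, cancer, v_central,
    v_cancer, v_obs, v_pred, defect, threshold, call`` (plus ``p_value`` and
    ``q_value`` when ``add_fdr``).
    """
    if threshold_multiplier < 0:
        raise ValueError(f"threshold_multiplier must be >= 0, got {threshold_multiplier}")
    central_set = set(central_genes) if central_genes is not None else None

    rows = []
    for exp_id, grp in summaries.groupby("experiment_id", sort=False):
        threshold = threshold_multiplier * average_experiment_sem(
            grp, control_conditions=control_conditions, scope=sem_scope
        )
        genes_split = grp["genes"].str.split(";")
        singles = {
            g[0]: (float(r.mean_viability_pct), float(r.sem_pct))
            for g, r in zip(genes_split, grp.itertuples())
            if len(g) == 1 and g[0]
        }
        for g, r in zip(genes_split, grp.itertuples()):
            if len(g) != 2:
                continue
            a, b = g
            if central_set is not None and b in central_set and a not in central_set:
                a, b = b, a
            missing = [x for x in (a, b) if x not in singles]
            if missing:
                raise ValueError(
                    f"pair ({a}, {b}) in experiment {exp_id!r}: missing single-knockdown "
                    f"condition(s) for {', '.join(missing)}"
                )
            (v_a, sem_a), (v_b, sem_b) = singles[a], singles[b]
            v_obs = float(r.mean_viability_pct)
            v_pred = predict_double_viability(v_a, v_b)
            defect = proliferative_defect(v_pred, v_obs)
            rows.append(
                {
                    "experiment_id": exp_id,
                    "central": a,
                    "cancer": b,
                    "v_central": v_a,
                    "v_cancer": v_b,
                    "v_obs": v_obs,
                    "v_pred": v_pred,
                    "defect": defect,
                    "threshold": threshold,
                    "call": defect >= threshold,
                    "_sem_obs": float(r.sem_pct),
                    "_sem_a": sem_a,
                    "_sem_b": sem_b,
                }
            )
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS + ["_sem_obs", "_sem_a", "_sem_b"])
    if add_fdr and not calls.empty:
        # delta-method SE of the defect from the three condition SEMs
        se = np.sqrt(
            calls["_sem_obs"] ** 2
            + (calls["v_cancer"] * calls["_sem_a"] / 100.0) ** 2
            + (calls["v_central"] * calls["_sem_b"] / 100.0) ** 2
        )
        z = calls["defect"] / se.replace(0.0, np.nan)
        calls["p_value"] = stats.norm.sf(z.fillna(np.inf))
        calls["q_value"] = stats.false_discovery_control(calls["p_value"], method="bh")
    return calls.drop(columns=["_sem_obs", "_sem_a", "_sem_b"]).reset_index(drop=True)


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"experiment_id": str, "central": str, "cancer": str})
    df["call"] = df["call"].astype(bool)
    return df
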