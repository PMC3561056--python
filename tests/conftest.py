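import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from synlethnet import simdata

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_plate_config() -> simdata.PlateSimConfig:
    """2 central x 3 cancer matrix with one planted interaction."""
    return simdata.PlateSimConfig(
        central_genes=("CENA", "CENB"),
        cancer_genes=("CANX", "CANY", "CANZ"),
        single_viability={
            "CENA": 0.8, "CENB": 0.7,
            "CANX": 0.9, "CANY": 0.75, "CANZ": 0.65,
        },
        epsilon={("CENA", "CANX"): 0.5},
        baseline_count=1000,
        noise_cv=0.05,
        wells_per_condition=6,
        seed=7,
    )


def summaries_frame(rows, experiment_id="exp1"):
    """Build a viability-summary table from (condition, genes, mean, sem, n) tuples."""
    return pd.DataFrame(
        [
            {
                "experiment_id": experiment_id,
                "condition_id": cond,
                "genes": genes,
                "mean_viability_pct": mean,
                "sem_pct": sem,
                "n": n,
            }
            for cond, genes, mean, sem, n in rows
        ]
    )


def brute_force_summaries(wells: pd.DataFrame, control: str):
    """Independent per-condition mean/SEM oracle using plain Python arithmetic."""
    by_cond: dict[str, list[float]] = {}
    genes: dict[str, str] = {}
    for _, row in wells.iterrows():
        by_cond.setdefault(row["condition_id"], []).append(float(row["nuclei_count"]))
        genes[row["condition_id"]] = row["genes_targeted"]
    ctrl_mean = sum(by_cond[control]) / len(by_cond[control])
    out = {}
    for cond, counts in by_cond.items():
        rel = [100.0 * c / ctrl_mean for c in counts]
        n = len(rel)
        mean = sum(rel) / n
        var = sum((x - mean) ** 2 for x in rel) / (n - 1)
        out[cond] = (genes[cond], mean, (var ** 0.5) / n ** 0.5, n)
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
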