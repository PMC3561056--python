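"""Seeded synthetic-data generators with known ground truth.

Three generators cover the three data modalities of a cross-species
synthetic-lethal study:

* :func:`simulate_plate` — Hoechst-stained nuclei counts per well for an
  siRNA double-knockdown viability screen, with a planted multiplicative
  interaction structure (``expected = baseline * v_A * v_B * (1 - eps)``).
* :func:`simulate_kinetic_screen` — fluorescence-quench flap-endonuclease
  cleavage traces under dose-dependent inhibition, including planted
  fluorescent-artifact compounds for the counterscreen.
* :func:`make_network_fixture` — bipartite central-by-cancer edge tables
  with exact yeast-predicted / human-observed tallies.

All generators are pure functions of their config (including the seed):
identical inputs yield byte-identical tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NON_SILENCING",
    "PlateSimConfig",
    "KineticSimConfig",
    "CompoundSpec",
    "NetworkFixtureSpec",
    "simulate_plate",
    "simulate_kinetic_screen",
    "simulate_counterscreen",
    "apparent_signal_inhibition",
    "make_network_fixture",
    "double_condition_id",
    "write_wells_csv",
    "read_wells_csv",
    "write_traces_csv",
    "read_traces_csv",
]

#: condition id of the non-silencing (no siRNA target) control wells
NON_SILENCING = "NS"

_WELLS_96 = [f"{row}{col:02d}" for row in "ABCDEFGH" for col in range(1, 13)]


def double_condition_id(central: str, cancer: str) -> str:
    """Canonical condition id for a double knockdown (central listed first)."""
    return f"{central}+{cancer}"


@dataclass(frozen=True)
class PlateSimConfig:
    """Design of one simulated siRNA viability experiment.

    ``single_viability`` maps each targeted gene to its true viability
    fraction (1.0 = no proliferative effect of the single knockdown);
    ``epsilon`` maps (central, cancer) pairs to the planted interaction
    strength: 0 means the double exactly follows the multiplicative null,
    1 means full synthetic lethality.
    """

    central_genes: tuple[str, ...]
    cancer_genes: tuple[str, ...]
    single_viability: Mapping[str, float]
    epsilon: Mapping[tuple[str, str], float] = field(default_factory=dict)
    control_gene: str = "GAPDH"
    baseline_count: int = 1000
    noise_cv: float = 0.05
    wells_per_condition: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "central_genes", tuple(self.central_genes))
        object.__setattr__(self, "cancer_genes", tuple(self.cancer_genes))

    def validate(self) -> None:
        if not self.central_genes or not self.cancer_genes:
            raise ValueError("central_genes and cancer_genes must be non-empty")
        if self.baseline_count <= 0:
            raise ValueError(f"baseline_count must be > 0, got {self.baseline_count}")
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.wells_per_condition < 2:
            raise ValueError(
                "wells_per_condition must be >= 2 so the SEM is computable, "
                f"got {self.wells_per_condition}"
            )
        for gene in itertools.chain(self.central_genes, self.cancer_genes):
            if gene not in self.single_viability:
                raise ValueError(f"single_viability missing entry for gene {gene!r}")
        for gene, v in self.single_viability.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"single_viability[{gene!r}] = {v} outside [0, 1]")
        valid_pairs = set(itertools.product(self.central_genes, self.cancer_genes))
        for pair, eps in self.epsilon.items():
            if tuple(pair) not in valid_pairs:
                raise ValueError(f"epsilon key {pair!r} is not a central x cancer pair")
            if not 0.0 <= eps <= 1.0:
                raise ValueError(f"epsilon[{pair!r}] = {eps} outside [0, 1]")

    def conditions(self) -> list[tuple[str, tuple[str, ...], float]]:
        """Ordered (condition_id, genes_targeted, expected_count) triples."""
        v = self.single_viability
        out: list[tuple[str, tuple[str, ...], float]] = [
            (NON_SILENCING, (), float(self.baseline_count)),
            (self.control_gene, (self.control_gene,), float(self.baseline_count)),
        ]
        for gene in itertools.chain(self.central_genes, self.cancer_genes):
            out.append((gene, (gene,), self.baseline_count * v[gene]))
        for a, b in itertools.product(self.central_genes, self.cancer_genes):
            eps = float(self.epsilon.get((a, b), 0.0))
            mean = self.baseline_count * v[a] * v[b] * (1.0 - eps)
            out.append((double_condition_id(a, b), (a, b), mean))
        return out


def _noisy_counts(rng: np.random.Generator, means: np.ndarray, cv: float) -> np.ndarray:
    """Draw integer counts with the requested mean and CV.

    Lognormal with exact mean/CV, rounded to the nearest integer and floored
    at zero; cv = 0 degenerates to the rounded mean.
    """
    means = np.asarray(means, dtype=float)
    if cv == 0.0:
        draws = means
    else:
        sigma2 = np.log1p(cv * cv)
        with np.errstate(divide="ignore"):
            mu = np.where(means > 0, np.log(np.where(means > 0, means, 1.0)) - sigma2 / 2, -np.inf)
        draws = np.where(means > 0, np.exp(rng.normal(mu, np.sqrt(sigma2))), 0.0)
    return np.maximum(np.rint(draws), 0).astype(int)


def simulate_plate(config: PlateSimConfig) -> pd.DataFrame:
    """Simulate one viability experiment as a table of well records.

    Emits ``wells_per_condition`` wells for the non-silencing control, the
    normalization control, every single knockdown, and every central x cancer
    double knockdown. Wells are laid out row-major across as many 96-well
    plates as needed; each plate draws from its own substream of the master
    seed, so adding plates never perturbs earlier ones.

    Returns a DataFrame with columns
    ``plate_id, well_id, condition_id, genes_targeted, nuclei_count``
    (``genes_targeted`` is a semicolon-joined string, empty for the
    non-silencing control).
    """
    config.validate()
    flat: list[tuple[str, str, float]] = []
    for cond_id, genes, mean in config.conditions():
        flat.extend([(cond_id, ";".join(genes), mean)] * config.wells_per_condition)

    n_plates = -(-len(flat) // 96)
    children = np.random.SeedSequence(config.seed).spawn(n_plates)
    rows: list[tuple[str, str, str, str, int]] = []
    for plate_idx in range(n_plates):
        chunk = flat[plate_idx * 96 : (plate_idx + 1) * 96]
        rng = np.random.default_rng(children[plate_idx])
        counts = _noisy_counts(rng, np.array([m for _, _, m in chunk]), config.noise_cv)
        plate_id = f"P{plate_idx + 1:02d}"
        for (cond_id, genes, _), well, count in zip(chunk, _WELLS_96, counts):
            rows.append((plate_id, well, cond_id, genes, int(count)))
    return pd.DataFrame(
        rows, columns=["plate_id", "well_id", "condition_id", "genes_targeted", "nuclei_count"]
    )


# ---------------------------------------------------------------------------
# kinetic traces


@dataclass(frozen=True)
class CompoundSpec:
    """Ground truth for one simulated library compound.

    ``true_ic50`` is in molar. Artifact compounds do not inhibit the enzyme;
    they attenuate the fluorescence readout itself (with ``true_ic50`` acting
    as the apparent quenching potency) and emit concentration-proportional
    autofluorescence, which is what the quencherless counterscreen exposes.
    """

    compound_id: str
    true_ic50: float
    hill: float = 1.0
    is_fluorescent_artifact: bool = False


@dataclass(frozen=True)
class KineticSimConfig:
    """Parameters of the simulated flap-cleavage fluorescence assay."""

    f_max: float = 1000.0
    k_uninhibited: float = 0.2  # per minute
    baseline: float = 50.0
    read_times: tuple[float, ...] = tuple(np.round(np.arange(0.0, 10.5, 0.5), 2))
    noise_sd: float = 0.0
    compounds: tuple[CompoundSpec, ...] = ()
    artifact_rfu_per_uM: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "read_times", tuple(float(t) for t in self.read_times))
        object.__setattr__(self, "compounds", tuple(self.compounds))

    def validate(self) -> None:
        if len(self.read_times) == 0:
            raise ValueError("read_times must be non-empty")
        t = np.asarray(self.read_times)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("read_times must be strictly increasing")
        if self.k_uninhibited <= 0:
            raise ValueError(f"k_uninhibited must be > 0, got {self.k_uninhibited}")
        for c in self.compounds:
            if c.true_ic50 <= 0:
                raise ValueError(f"true_ic50 must be > 0 for {c.compound_id!r}")
            if c.hill <= 0:
                raise ValueError(f"hill must be > 0 for {c.compound_id!r}")


def _occupancy(conc: float, ic50: float, hill: float) -> float:
    """Fractional signal retained, 1/(1 + (C/IC50)^hill); 1.0 at C = 0."""
    if conc == 0:
        return 1.0
    return 1.0 / (1.0 + (conc / ic50) ** hill)


def simulate_kinetic_screen(
    config: KineticSimConfig,
    concentrations: Sequence[float],
    quencherless: bool = False,
) -> pd.DataFrame:
    """Simulate fluorescence traces for every compound x concentration.

    Primary (quenched-substrate) assay: a genuine inhibitor slows cleavage,
    ``F(t) = baseline + f_max * (1 - exp(-k_eff t))`` with
    ``k_eff = k * / (1 + (C/IC50)^hill)``; an artifact compound leaves the
    enzyme alone but attenuates the kinetic amplitude by the same occupancy
    factor (quenching) and adds a static offset proportional to concentration
    (autofluorescence).

    Quencherless counterscreen (``quencherless=True``): the substrate
    fluoresces regardless of cleavage, so the trace is flat at
    ``baseline + f_max``; only artifacts perturb it. Include ``0.0`` among
    ``concentrations`` to obtain vehicle traces.

    Returns a long DataFrame ``compound, conc_M, time_min, rfu``.
    """
    config.validate()
    conc = [float(c) for c in concentrations]
    if any(c < 0 for c in conc):
        raise ValueError("concentrations must be >= 0 (0 = vehicle)")
    t = np.asarray(config.read_times)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0] if quencherless else config.seed)

    frames = []
    for comp in config.compounds:
        for c in conc:
            occ = _occupancy(c, comp.true_ic50, comp.hill)
            offset = config.artifact_rfu_per_uM * c * 1e6 if comp.is_fluorescent_artifact else 0.0
            if quencherless:
                amp = occ * config.f_max if comp.is_fluorescent_artifact else config.f_max
                signal = config.baseline + amp + offset + np.zeros_like(t)
            elif comp.is_fluorescent_artifact:
                signal = config.baseline + occ * config.f_max * (1.0 - np.exp(-config.k_uninhibited * t)) + offset
            else:
                k_eff = config.k_uninhibited * occ
                signal = config.baseline + config.f_max * (1.0 - np.exp(-k_eff * t))
            if config.noise_sd > 0:
                signal = signal + rng.normal(0.0, config.noise_sd, size=t.shape)
            frames.append(
                pd.DataFrame(
                    {"compound": comp.compound_id, "conc_M": c, "time_min": t, "rfu": signal}
                )
            )
    if not frames:
        return pd.DataFrame(columns=["compound", "conc_M", "time_min", "rfu"])
    return pd.concat(frames, ignore_index=True)


def apparent_signal_inhibition(
    traces: pd.DataFrame, baseline: float = 0.0
) -> dict[str, float]:
    """Percent reduction of static signal relative to each compound's vehicle.

    For quencherless-counterscreen traces: averages ``rfu`` over each
    compound's vehicle rows (``conc_M == 0``) and its highest-dose rows, and
    reports ``100 * (1 - (dose - baseline) / (vehicle - baseline))``.
    """
    out: dict[str, float] = {}
    for compound, grp in traces.groupby("compound", sort=False):
        vehicle = grp.loc[grp["conc_M"] == 0.0, "rfu"]
        if vehicle.empty:
            raise ValueError(f"no vehicle (conc 0) trace for compound {compound!r}")
        top_dose = grp["conc_M"].max()
        if top_dose == 0.0:
            raise ValueError(f"no dosed trace for compound {compound!r}")
        dosed = grp.loc[grp["conc_M"] == top_dose, "rfu"]
        ref = vehicle.mean() - baseline
        if ref <= 0:
            raise ValueError(f"degenerate vehicle signal for compound {compound!r}")
        out[str(compound)] = float(100.0 * (1.0 - (dosed.mean() - baseline) / ref))
    return out


def simulate_counterscreen(
    config: KineticSimConfig, concentration: float
) -> dict[str, float]:
    """Quencherless counterscreen at one dose: compound -> apparent % inhibition."""
    traces = simulate_kinetic_screen(config, [0.0, concentration], quencherless=True)
    return apparent_signal_inhibition(traces, baseline=config.baseline)


# ---------------------------------------------------------------------------
# network fixtures


@dataclass(frozen=True)
class NetworkFixtureSpec:
    """Requested exact tallies for a bipartite edge-table fixture."""

    n_central: int
    n_cancer: int
    n_yeast_predicted: int
    n_conserved: int
    n_human_only: int
    seed: int = 0

    def validate(self) -> None:
        n_pairs = self.n_central * self.n_cancer
        if self.n_central < 1 or self.n_cancer < 1:
            raise ValueError("n_central and n_cancer must be >= 1")
        if not 0 <= self.n_yeast_predicted <= n_pairs:
            raise ValueError(f"n_yeast_predicted {self.n_yeast_predicted} outside [0, {n_pairs}]")
        if not 0 <= self.n_conserved <= self.n_yeast_predicted:
            raise ValueError(
                f"n_conserved {self.n_conserved} exceeds n_yeast_predicted {self.n_yeast_predicted}"
            )
        if not 0 <= self.n_human_only <= n_pairs - self.n_yeast_predicted:
            raise ValueError(
                f"n_human_only {self.n_human_only} exceeds unpredicted pairs "
                f"{n_pairs - self.n_yeast_predicted}"
            )


def make_network_fixture(spec: NetworkFixtureSpec) -> pd.DataFrame:
    """Edge table with exactly the requested flag tallies.

    Gene symbols are synthetic (``CEN1..``, ``CAN1..``). Which pairs carry
    which flags is a seeded permutation; the tallies themselves are exact,
    never stochastic. Columns: ``central, cancer, yeast_predicted,
    human_observed``.
    """
    spec.validate()
    central = [f"CEN{i + 1}" for i in range(spec.n_central)]
    cancer = [f"CAN{i + 1}" for i in range(spec.n_cancer)]
    pairs = list(itertools.product(central, cancer))
    n_pairs = len(pairs)

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n_pairs)
    predicted = np.zeros(n_pairs, dtype=bool)
    observed = np.zeros(n_pairs, dtype=bool)
    pred_idx = order[: spec.n_yeast_predicted]
    predicted[pred_idx] = True
    observed[pred_idx[: spec.n_conserved]] = True
    observed[order[spec.n_yeast_predicted : spec.n_yeast_predicted + spec.n_human_only]] = True

    return pd.DataFrame(
        {
            "central": [a for a, _ in pairs],
            "cancer": [b for _, b in pairs],
            "yeast_predicted": predicted,
            "human_observed": observed,
        }
    )


# ---------------------------------------------------------------------------
# file dialects


def write_wells_csv(wells: pd.DataFrame, path) -> None:
    wells.to_csv(path, index=False)


def read_wells_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plate_id": str, "well_id": str, "condition_id": str})
    df["genes_targeted"] = df["genes_targeted"].fillna("")
    df["nuclei_count"] = df["nuclei_count"].astype(int)
    return df


def write_traces_csv(traces: pd.DataFrame, path) -> None:
    traces.to_csv(path, index=False)


def read_traces_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"compound": str})
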