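"""End-to-end orchestration: simulate -> normalize -> call -> network -> screen.

A single :class:`RunConfig` (YAML-loadable) drives the stages; every stage
writes its table into the output directory, and a consolidated JSON report
captures row counts, the conservation summary, the interaction calls and the
screening-funnel tallies. Re-running with an identical config and seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import enzymology, network, simdata, slcall, viability
from ._version import __version__

__all__ = ["RunConfig", "RunReport", "demo_config", "validate_config", "run_pipeline"]

logger = logging.getLogger("synlethnet")

ALL_STAGES = ("simulate", "normalize", "call", "network", "screen")


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one pipeline run."""

    seed: int = 0
    out_dir: str = "synlethnet_run"
    stages: tuple[str, ...] = ALL_STAGES
    experiment_id: str = "exp1"
    threshold_multiplier: float = 3.0
    plate: simdata.PlateSimConfig | None = None
    wells_path: str | None = None
    predicted_pairs: tuple[tuple[str, str], ...] = ()
    kinetics: simdata.KineticSimConfig | None = None
    concentrations: tuple[float, ...] = ()
    screening_conc: float | None = None
    counterscreen_conc: float | None = None
    hit_threshold: float = 50.0
    counterscreen_threshold: float = 50.0
    descriptors: tuple[Mapping[str, Any], ...] = ()

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.plate is not None:
            plate = dataclasses.asdict(self.plate)
            plate["epsilon"] = sorted([a, b, eps] for (a, b), eps in self.plate.epsilon.items())
            plate["single_viability"] = dict(sorted(self.plate.single_viability.items()))
            d["plate"] = plate
        if self.kinetics is not None:
            kin = dataclasses.asdict(self.kinetics)
            kin["compounds"] = [dataclasses.asdict(c) for c in self.kinetics.compounds]
            d["kinetics"] = kin
        d["predicted_pairs"] = [[a, b] for a, b in self.predicted_pairs]
        d["stages"] = list(self.stages)
        d["descriptors"] = [dict(x) for x in self.descriptors]
        d["concentrations"] = list(self.concentrations)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def config_from_dict(d: Mapping[str, Any]) -> RunConfig:
    d = dict(d)
    if d.get("plate"):
        p = dict(d["plate"])
        p["central_genes"] = tuple(p["central_genes"])
        p["cancer_genes"] = tuple(p["cancer_genes"])
        p["epsilon"] = {(a, b): float(e) for a, b, e in p.get("epsilon", [])}
        d["plate"] = simdata.PlateSimConfig(**p)
    if d.get("kinetics"):
        k = dict(d["kinetics"])
        k["compounds"] = tuple(simdata.CompoundSpec(**c) for c in k.get("compounds", []))
        k["read_times"] = tuple(k.get("read_times", simdata.KineticSimConfig().read_times))
        d["kinetics"] = simdata.KineticSimConfig(**k)
    if "predicted_pairs" in d:
        d["predicted_pairs"] = tuple((a, b) for a, b in d["predicted_pairs"])
    if "stages" in d:
        d["stages"] = tuple(d["stages"])
    if "concentrations" in d:
        d["concentrations"] = tuple(float(c) for c in d["concentrations"])
    if "descriptors" in d:
        d["descriptors"] = tuple(dict(x) for x in d["descriptors"])
    return RunConfig(**d)


def config_from_yaml(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class RunReport:
    """Consolidated, fully seed-determined outcome of a pipeline run."""

    seed: int
    config_hash: str
    version: str
    stage_counts: dict[str, int]
    conservation: network.ConservationSummary | None
    calls: list[dict[str, Any]]
    hub_ranking: list[tuple[str, int]]
    funnel: dict[str, Any] | None
    config: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.conservation is not None:
            d["conservation"] = dataclasses.asdict(self.conservation)
        return d


# ---------------------------------------------------------------------------
# demo configuration replicating the 3 x 10 study design


_DEMO_CENTRAL = ("WDHD1", "FEN1", "CHTF8")
_DEMO_CANCER = (
    "SMC1A", "SMC3", "NIPBL", "STAG1", "STAG3",
    "RNF20", "FBXW7", "MRE11A", "RAD54B", "BLM",
)
# genes of the six yeast-only (null) pairs sit at the low end so those pairs'
# null-defect noise is small relative to the singles-derived threshold
_DEMO_VIABILITY = {
    "WDHD1": 0.65, "FEN1": 0.70, "CHTF8": 0.60,
    "SMC1A": 0.90, "SMC3": 0.65, "NIPBL": 0.85, "STAG1": 0.90, "STAG3": 0.85,
    "RNF20": 0.60, "FBXW7": 0.90, "MRE11A": 0.60, "RAD54B": 0.65, "BLM": 0.80,
}
# pairs never reported in the yeast network (8 of 30)
_DEMO_UNPREDICTED = (
    ("FEN1", "STAG1"),
    ("WDHD1", "STAG1"), ("CHTF8", "STAG1"),
    ("WDHD1", "STAG3"), ("FEN1", "STAG3"), ("CHTF8", "STAG3"),
    ("WDHD1", "BLM"), ("CHTF8", "BLM"),
)
# predicted in yeast but planted with no human interaction (6 of 22)
_DEMO_YEAST_ONLY = (
    ("WDHD1", "RNF20"), ("WDHD1", "RAD54B"), ("WDHD1", "SMC3"),
    ("CHTF8", "RNF20"), ("CHTF8", "RAD54B"), ("CHTF8", "MRE11A"),
)


def demo_predicted_pairs() -> tuple[tuple[str, str], ...]:
    """The 22 yeast-predicted pairs of the demo's 3 x 10 matrix."""
    unpred = set(_DEMO_UNPREDICTED)
    return tuple(
        (a, b) for a in _DEMO_CENTRAL for b in _DEMO_CANCER if (a, b) not in unpred
    )


def demo_config(seed: int = 0, out_dir: str = "synlethnet_demo") -> RunConfig:
    """Pipeline config replicating the study's 3-central x 10-cancer matrix.

    Synthetic-lethal interactions (epsilon = 0.4) are planted on 16 of the 22
    yeast-predicted pairs plus one unpredicted pair (FEN1-STAG1), so the true
    network has 16 conserved, 6 yeast-only and 1 human-only edge; no
    interaction involves STAG3. The compound library plants genuine
    inhibitors, fluorescent artifacts and a rule-of-five violator to exercise
    the full screening funnel.
    """
    yeast_only = set(_DEMO_YEAST_ONLY)
    epsilon = {p: 0.4 for p in demo_predicted_pairs() if p not in yeast_only}
    epsilon[("FEN1", "STAG1")] = 0.4
    plate = simdata.PlateSimConfig(
        central_genes=_DEMO_CENTRAL,
        cancer_genes=_DEMO_CANCER,
        single_viability=dict(_DEMO_VIABILITY),
        epsilon=epsilon,
        baseline_count=1000,
        noise_cv=0.05,
        wells_per_condition=6,
        seed=seed,
    )
    compounds = (
        simdata.CompoundSpec("SLN-001", 2e-7),        # potent true inhibitor
        simdata.CompoundSpec("SLN-002", 1e-6),        # true inhibitor
        simdata.CompoundSpec("SLN-003", 5e-6, 1.2),   # true inhibitor, steeper
        simdata.CompoundSpec("SLN-004", 1e-6),        # true inhibitor, fails rule of five
        simdata.CompoundSpec("SLN-ART1", 5e-7, 1.0, True),   # fluorescent artifact
        simdata.CompoundSpec("SLN-ART2", 2e-6, 1.0, True),   # fluorescent artifact
        simdata.CompoundSpec("SLN-INACT", 1e-2),      # inactive at screening dose
    )
    kinetics = simdata.KineticSimConfig(
        f_max=1000.0,
        k_uninhibited=0.2,
        baseline=50.0,
        noise_sd=2.0,
        compounds=compounds,
        seed=seed + 1,
    )
    descriptors = (
        {"compound_id": "SLN-001", "mw": 342.4, "clogp": 2.1, "hbd": 2, "hba": 5},
        {"compound_id": "SLN-002", "mw": 418.9, "clogp": 3.4, "hbd": 1, "hba": 6},
        {"compound_id": "SLN-003", "mw": 287.3, "clogp": 1.8, "hbd": 3, "hba": 4},
        {"compound_id": "SLN-004", "mw": 612.7, "clogp": 5.9, "hbd": 4, "hba": 9},
        {"compound_id": "SLN-ART1", "mw": 380.4, "clogp": 2.9, "hbd": 1, "hba": 5},
        {"compound_id": "SLN-ART2", "mw": 455.5, "clogp": 4.2, "hbd": 2, "hba": 7},
        {"compound_id": "SLN-INACT", "mw": 310.3, "clogp": 2.5, "hbd": 2, "hba": 4},
    )
    half_log = (1e-8, 3.16e-8, 1e-7, 3.16e-7, 1e-6, 3.16e-6, 1e-5, 3.16e-5)
    return RunConfig(
        seed=seed,
        out_dir=out_dir,
        plate=plate,
        predicted_pairs=demo_predicted_pairs(),
        kinetics=kinetics,
        concentrations=(0.0,) + half_log,
        screening_conc=3.16e-5,
        counterscreen_conc=3.16e-5,
        descriptors=descriptors,
    )


# ---------------------------------------------------------------------------
# validation and execution


def validate_config(config: RunConfig) -> list[str]:
    """Return the list of problems that would prevent :func:`run_pipeline`."""
    problems: list[str] = []
    unknown = [s for s in config.stages if s not in ALL_STAGES]
    if unknown:
        problems.append(f"unknown stage(s): {', '.join(unknown)}")
    if config.threshold_multiplier < 0:
        problems.append(f"threshold_multiplier must be >= 0, got {config.threshold_multiplier}")
    stages = set(config.stages)
    if "simulate" in stages and config.plate is None and config.kinetics is None:
        problems.append("simulate stage enabled but neither plate nor kinetics config given")
    if "normalize" in stages and "simulate" not in stages and config.wells_path is None:
        problems.append("normalize stage needs wells_path when simulate is disabled")
    if config.wells_path is not None and not Path(config.wells_path).exists():
        problems.append(f"wells_path does not exist: {config.wells_path}")
    if config.plate is not None:
        try:
            config.plate.validate()
        except ValueError as exc:
            problems.append(f"plate: {exc}")
    if config.kinetics is not None:
        try:
            config.kinetics.validate()
        except ValueError as exc:
            problems.append(f"kinetics: {exc}")
        if "screen" in stages:
            if config.screening_conc is None:
                problems.append("screen stage needs screening_conc")
            elif config.screening_conc not in config.concentrations:
                problems.append("screening_conc must be among concentrations")
            if config.counterscreen_conc is None:
                problems.append("screen stage needs counterscreen_conc")
    return problems


def _setup_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in order and write tables plus report.json."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out)
    stages = set(config.stages)
    counts: dict[str, int] = {}
    conservation = None
    calls_records: list[dict[str, Any]] = []
    hub_ranking: list[tuple[str, int]] = []
    funnel_dict: dict[str, Any] | None = None
    try:
        wells = summaries = calls = None
        if "simulate" in stages and config.plate is not None:
            wells = simdata.simulate_plate(config.plate)
            simdata.write_wells_csv(wells, out / "wells.csv")
            counts["wells"] = len(wells)
            logger.info("simulated %d wells", len(wells))
        if "normalize" in stages:
            if wells is None:
                wells = simdata.read_wells_csv(config.wells_path or out / "wells.csv")
            control = config.plate.control_gene if config.plate else "GAPDH"
            summaries = viability.normalize_to_control(wells, control, config.experiment_id)
            viability.write_summaries_tsv(summaries, out / "summaries.tsv")
            counts["conditions"] = len(summaries)
        if "call" in stages:
            if summaries is None:
                summaries = viability.read_summaries_tsv(out / "summaries.tsv")
            control = config.plate.control_gene if config.plate else "GAPDH"
            calls = slcall.call_interactions(
                summaries,
                threshold_multiplier=config.threshold_multiplier,
                central_genes=config.plate.central_genes if config.plate else None,
                control_conditions=(control, simdata.NON_SILENCING),
            )
            slcall.write_calls_tsv(calls, out / "calls.tsv")
            counts["pairs_tested"] = len(calls)
            counts["pairs_called"] = int(calls["call"].sum())
            calls_records = json.loads(calls.to_json(orient="records"))
        if "network" in stages:
            if calls is None:
                calls = slcall.read_calls_tsv(out / "calls.tsv")
            edges = network.build_network(config.predicted_pairs, calls)
            network.write_edges_tsv(edges, out / "edges.tsv")
            network.write_sif(edges, out)
            conservation = network.conservation_summary(edges)
            network.write_summary_json(conservation, out / "network_summary.json")
            hub_ranking = network.rank_hubs(edges)
            counts["edges"] = len(edges)
            logger.info("conservation: %s", conservation)
        if "screen" in stages and config.kinetics is not None:
            traces = simdata.simulate_kinetic_screen(config.kinetics, config.concentrations)
            simdata.write_traces_csv(traces, out / "traces.csv")
            counter = simdata.simulate_counterscreen(config.kinetics, config.counterscreen_conc)
            funnel = enzymology.screen_funnel(
                traces,
                counter,
                pd.DataFrame([dict(x) for x in config.descriptors]),
                screening_conc=config.screening_conc,
                hit_threshold=config.hit_threshold,
                counterscreen_threshold=config.counterscreen_threshold,
            )
            fits = _fit_library_ic50s(traces)
            fits.to_csv(out / "fits.tsv", sep="\t", index=False)
            funnel_dict = {
                "primary_hit_ids": funnel.primary_hits,
                "after_counterscreen_ids": funnel.after_counterscreen,
                "final_hit_ids": funnel.final_hits,
                **funnel.tallies,
            }
            with open(out / "funnel.json", "w") as fh:
                json.dump(funnel_dict, fh, indent=2, sort_keys=True)
                fh.write("\n")
            counts["compounds_screened"] = funnel.tallies["screened"]
            counts["final_hits"] = funnel.tallies["final_hits"]
    except Exception:
        logger.exception("pipeline stage failed; partial outputs remain in %s", out)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    report = RunReport(
        seed=config.seed,
        config_hash=config.config_hash(),
        version=__version__,
        stage_counts=counts,
        conservation=conservation,
        calls=calls_records,
        hub_ranking=hub_ranking,
        funnel=funnel_dict,
        config=config.to_dict(),
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return report


def _fit_library_ic50s(traces: pd.DataFrame) -> pd.DataFrame:
    """Per-compound 4PL fit of percent activity (rate vs vehicle) across doses."""
    rows = []
    for compound, grp in traces.groupby("compound", sort=False):
        by_conc = {
            float(c): enzymology.initial_rate(t)
            for t in enzymology.traces_from_frame(grp)
            for c in [t.conc]
        }
        vehicle = by_conc.get(0.0)
        doses = sorted(c for c in by_conc if c > 0)
        if vehicle is None or len(doses) < 4:
            continue
        activity = [100.0 - enzymology.percent_inhibition(by_conc[c], vehicle) for c in doses]
        fit = enzymology.fit_ic50(doses, activity)
        rows.append(
            {
                "compound_id": compound,
                "ic50_M": fit.ic50,
                "hill": fit.hill,
                "top": fit.top,
                "bottom": fit.bottom,
                "rss": fit.rss,
                "converged": fit.converged,
                "ic50_in_range": fit.ic50_in_range,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["compound_id", "ic50_M", "hill", "top", "bottom", "rss", "converged", "ic50_in_range"],
    )
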