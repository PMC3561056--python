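"""Bipartite central-by-cancer interaction network and conservation tallies.

Reconciles yeast-predicted gene pairs with human synthetic-lethality calls
into a single edge table, cross-tabulates conservation (observed in both
species / yeast only / human only / neither), and ranks the central genes by
degree to identify hubs.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

__all__ = [
    "Edge",
    "ConservationSummary",
    "build_network",
    "conservation_summary",
    "rank_hubs",
    "to_networkx",
    "load_ortholog_aliases",
    "canonicalize_symbols",
    "write_edges_tsv",
    "read_edges_tsv",
    "write_sif",
    "write_summary_json",
]

EDGE_COLUMNS = ["central", "cancer", "yeast_predicted", "human_observed"]


@dataclass(frozen=True)
class Edge:
    central_gene: str
    cancer_gene: str
    yeast_predicted: bool
    human_observed: bool


@dataclass(frozen=True)
class ConservationSummary:
    """Cross-tabulation of yeast predictions against human observations.

    Percentages are of the *predicted* edges, rounded half-up to integers;
    they are ``None`` when nothing was predicted.
    """

    n_pairs: int
    n_predicted: int
    n_conserved: int
    n_yeast_only: int
    n_human_only: int
    pct_conserved: int | None
    pct_not_conserved: int | None


def _round_half_up_pct(numerator: int, denominator: int) -> int:
    import math

    return int(math.floor(100.0 * numerator / denominator + 0.5))


def build_network(
    predicted_pairs: Iterable[tuple[str, str]] | pd.DataFrame,
    calls: pd.DataFrame,
) -> pd.DataFrame:
    """Merge yeast predictions with human calls into one edge per tested pair.

    ``human_observed`` is each pair's synthetic-lethality call;
    ``yeast_predicted`` marks membership in the prediction list. Every
    predicted pair must have been tested (present in ``calls``).
    """
    if isinstance(predicted_pairs, pd.DataFrame):
        predicted = {(str(r.central), str(r.cancer)) for r in predicted_pairs.itertuples()}
    else:
        predicted = {(str(a), str(b)) for a, b in predicted_pairs}
    tested = list(zip(calls["central"].astype(str), calls["cancer"].astype(str)))
    untested = sorted(predicted - set(tested))
    if untested:
        raise ValueError(
            "predicted pairs absent from calls: "
            + ", ".join(f"({a}, {b})" for a, b in untested)
        )
    return pd.DataFrame(
        {
            "central": [a for a, _ in tested],
            "cancer": [b for _, b in tested],
            "yeast_predicted": [pair in predicted for pair in tested],
            "human_observed": calls["call"].astype(bool).to_numpy(),
        }
    )


def conservation_summary(edges: pd.DataFrame) -> ConservationSummary:
    """Tally conservation of predicted interactions across species."""
    pred = edges["yeast_predicted"].astype(bool)
    obs = edges["human_observed"].astype(bool)
    n_pairs = len(edges)
    n_predicted = int(pred.sum())
    n_conserved = int((pred & obs).sum())
    n_yeast_only = int((pred & ~obs).sum())
    n_human_only = int((~pred & obs).sum())
    if n_predicted > 0:
        pct_conserved = _round_half_up_pct(n_conserved, n_predicted)
        pct_not_conserved = 100 - pct_conserved
    else:
        pct_conserved = pct_not_conserved = None
    return ConservationSummary(
        n_pairs=n_pairs,
        n_predicted=n_predicted,
        n_conserved=n_conserved,
        n_yeast_only=n_yeast_only,
        n_human_only=n_human_only,
        pct_conserved=pct_conserved,
        pct_not_conserved=pct_not_conserved,
    )


def to_networkx(edges: pd.DataFrame, flag: str = "human_observed") -> nx.Graph:
    """Bipartite graph of the edges carrying the given flag."""
    g = nx.Graph()
    g.add_nodes_from(edges["central"].unique(), bipartite="central")
    g.add_nodes_from(edges["cancer"].unique(), bipartite="cancer")
    flagged = edges[edges[flag].astype(bool)]
    g.add_edges_from(zip(flagged["central"], flagged["cancer"]))
    return g


def rank_hubs(edges: pd.DataFrame, by: str = "human_observed") -> list[tuple[str, int]]:
    """Central genes by descending degree of the chosen flag; ties alphabetical."""
    if by not in ("human_observed", "yeast_predicted"):
        raise ValueError(f"by must be 'human_observed' or 'yeast_predicted', got {by!r}")
    g = to_networkx(edges, flag=by)
    centrals = sorted(edges["central"].unique())
    return sorted(((c, int(g.degree(c))) for c in centrals), key=lambda kv: (-kv[1], kv[0]))


# ---------------------------------------------------------------------------
# gene-symbol aliases


def load_ortholog_aliases() -> pd.DataFrame:
    """Packaged yeast-to-human ortholog alias table (columns ``yeast, human``)."""
    ref = importlib.resources.files("synlethnet").joinpath("data/yeast_human_orthologs.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def canonicalize_symbols(genes: Iterable[str]) -> list[str]:
    """Map yeast symbols to canonical human symbols; unknowns pass through.

    An unknown symbol (neither a yeast alias nor a known human symbol)
    triggers a warning, never an error. A yeast gene with several human
    paralogs maps to the first listed.
    """
    table = load_ortholog_aliases()
    yeast_to_human = dict(zip(table["yeast"], table["human"]))  # first paralog wins
    known_human = set(table["human"])
    out = []
    for gene in genes:
        if gene in yeast_to_human:
            out.append(yeast_to_human[gene])
        else:
            if gene not in known_human:
                warnings.warn(f"unknown gene symbol {gene!r}; passing through", stacklevel=2)
            out.append(gene)
    return out


# ---------------------------------------------------------------------------
# serialization


def write_edges_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edges_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"central": str, "cancer": str})
    for col in ("yeast_predicted", "human_observed"):
        df[col] = df[col].astype(bool)
    return df


def write_sif(edges: pd.DataFrame, out_dir) -> dict[str, Path]:
    """One SIF file (``central<TAB>sl<TAB>cancer``) per conservation class."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pred = edges["yeast_predicted"].astype(bool)
    obs = edges["human_observed"].astype(bool)
    classes = {
        "conserved": edges[pred & obs],
        "yeast_only": edges[pred & ~obs],
        "human_only": edges[~pred & obs],
    }
    paths = {}
    for name, subset in classes.items():
        path = out_dir / f"edges_{name}.sif"
        with open(path, "w") as fh:
            for r in subset.itertuples():
                fh.write(f"{r.central}\tsl\t{r.cancer}\n")
        paths[name] = path
    return paths


def write_summary_json(summary: ConservationSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
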