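# synlethnet

Synthetic-lethal interaction scoring, cross-species network conservation,
and flap-endonuclease inhibitor-screen analytics.

## The problem

Tumors accumulate mutations — for instance in chromosome-instability (CIN)
genes frequently hit in colorectal cancer — that genotypically distinguish
cancer cells from normal cells. A *synthetic-lethal* partner of such a
mutated gene is an attractive drug target: inhibiting it kills the mutant
cells while sparing wild-type tissue. One route to finding such partners is
cross-species: take synthetic-lethal interactions known from budding-yeast
genetics, test the orthologous gene pairs in human cells by double siRNA
knockdown, and rank the "central" genes that interact with many
cancer-mutated genes as broad-spectrum targets. A highly connected hub that
happens to encode an enzyme (such as the flap endonuclease FEN1, which
cleaves 5′ DNA flaps during Okazaki-fragment maturation) can then be carried
into biochemical small-molecule screening.

`synlethnet` implements that analysis pipeline end to end, for
computational biologists and screening groups who want a tested, seeded,
reusable version of it:

1. **viability** — normalize imaged nuclei counts per well to the
   GAPDH-silenced control, yielding per-condition percent viability with SEM;
2. **slcall** — score each double knockdown against the multiplicative
   genetic-interaction null and call synthetic lethality with a
   3×-average-SEM threshold;
3. **network** — reconcile the human calls with yeast predictions into a
   bipartite conservation network, with tallies and hub-degree rankings;
4. **enzymology** — analyze fluorescence-quench enzyme kinetics: initial
   rates, percent inhibition, four-parameter-logistic IC50 fits, the
   quencherless-substrate counterscreen, Lipinski rule-of-five triage, and
   ANOVA + Tukey selectivity comparisons between genotypes;
5. **simdata** — seeded generators for all of the above with planted ground
   truth, so every stage is testable without any external data;
6. **pipeline / CLI** — one-config orchestration with a consolidated,
   byte-reproducible JSON report.

## The model

Let `v_A` and `v_B` be single-knockdown viabilities as percent of control.
The multiplicative null expectation for the double knockdown is

    v_pred = v_A × v_B / 100

and the interaction statistic is the proliferative defect

    δ = v_pred − v_obs

(positive = the double does worse than expected). A pair is called
synthetic lethal when

    δ ≥ m × SEM̄,   m = 3 by default,

where `SEM̄` is the mean SEM across the experiment's single-knockdown
conditions (see `docs/methods.md` for why singles). Conservation of a
yeast-predicted edge means it is also called in the human assay; percentages
are reported relative to the predicted edges, rounded half-up.

Dose-response curves are fit as a four-parameter logistic,

    activity(C) = bottom + (top − bottom) / (1 + (C / IC50)^h),

with relative (1/Y²-style) weighting by default.

## Worked example

The built-in demo configuration replicates a 3-central × 10-cancer-gene
study design: interactions are planted on 16 of 22 yeast-predicted pairs
plus one unpredicted pair, and a seven-compound library with planted genuine
inhibitors, fluorescence artifacts and one rule-of-five violator exercises
the screening funnel.

```python
from synlethnet import demo_config, run_pipeline

report = run_pipeline(demo_config(seed=0, out_dir="demo_run"))
c = report.conservation
print(f"pairs tested:     {c.n_pairs}")
print(f"yeast-predicted:  {c.n_predicted}")
print(f"conserved:        {c.n_conserved} ({c.pct_conserved}%)")
print(f"yeast-only:       {c.n_yeast_only} ({c.pct_not_conserved}%)")
print(f"human-only:       {c.n_human_only}")
print(f"hub ranking:      {report.hub_ranking}")
print(f"screen funnel:    {report.funnel['screened']} screened -> "
      f"{report.funnel['primary_hits']} primary hits -> "
      f"{report.funnel['after_counterscreen']} after counterscreen -> "
      f"{report.funnel['final_hits']} drug-like hits")
```

prints

```
pairs tested:     30
yeast-predicted:  22
conserved:        16 (73%)
yeast-only:       6 (27%)
human-only:       1
hub ranking:      [('FEN1', 9), ('CHTF8', 4), ('WDHD1', 4)]
screen funnel:    7 screened -> 6 primary hits -> 4 after counterscreen -> 3 drug-like hits
```

Reading: of the 30 tested gene pairs, all 16 pairs carrying a planted
interaction among the 22 yeast-predicted ones are recovered (73% conserved,
27% yeast-only), plus the one planted unpredicted (human-only) interaction —
and FEN1, carrying that extra edge, tops the hub ranking. In the compound
funnel, the counterscreen strips the two fluorescence artifacts from the six
primary hits and the rule-of-five filter strips the non-drug-like inhibitor,
leaving exactly the three planted drug-like true inhibitors.

The same run is available from the shell, along with per-stage subcommands
(`simulate`, `normalize`, `call`, `network`, `screen`, `report`):

```
synlethnet run --demo --seed 0 --out demo_run
```

All outputs (well table, viability summaries, interaction calls, edge
tables, SIF files, IC50 fits, funnel and consolidated `report.json`) land in
the output directory and are byte-identical under a fixed seed.

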