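"""Benchmark scenarios with known ground truth.

Self-contained replicable experiments used to validate the pipeline
against analytic expectations and planted structure: Monte-Carlo detection
rates versus the closed-form detection probability, neutral-drift
martingale checks, linkage (cohort) recovery with exact binomial
sequencing noise, and planted hard/soft sweep regimes for the gene-level
classifier.  Both the test suite and the reproduction script run these.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popsim import PlantedLineage, TruthTable, generations_per_day, planted_lineage_truth
from .seqsim import SeqConfig, make_sample, sequence_truth
from .sweepscan import classify_gene_sweep, detect_cohorts
from .trajdyn import build_table
from .varcall import CallPolicy, call_table, detection_probability

SAMPLE_DAYS = (5, 7, 14, 20, 28, 35, 40, 45, 50, 56, 60)


def detection_pass_rate(
    f: float,
    n_draws: int,
    rng: np.random.Generator,
    mean_depth: float = 800.0,
    policy: CallPolicy = CallPolicy(),
) -> float:
    """Monte-Carlo fraction of error-free fixed-depth sites that get called.

    Matches the sampling model of :func:`~chemosweep.varcall.detection_probability`:
    fixed depth, Bernoulli(1/2) strand split, X ~ Binomial(D, f) alt reads.
    """
    cfg = SeqConfig(mean_depth=mean_depth, depth_law="fixed", base_error_rate=0.0)
    truth = pd.Series(np.full(n_draws, f), index=[f"d{i}" for i in range(n_draws)])
    counts = make_sample(truth, 0.0, cfg, rng)
    calls = call_table(counts, policy)
    return float(calls["passed"].mean())


def neutral_final_frequencies(
    n_replicates: int,
    rng: np.random.Generator,
    N: int = 100_000,
    init_freq: float = 0.10,
    duration_days: float = 60.0,
    dilution_rate: float = 0.1,
) -> np.ndarray:
    """Final frequency of a neutral marked lineage across replicate runs.

    Drift is a martingale, so the mean final frequency estimates the
    initial frequency.
    """
    out = np.empty(n_replicates)
    days = (duration_days,)
    for i in range(n_replicates):
        truth = planted_lineage_truth(
            [PlantedLineage(1.0, init_freq, (("marker", "neutral"),))],
            N=N, sample_days=days, dilution_rate=dilution_rate,
            duration_days=duration_days, rng=rng,
        )
        out[i] = truth.freqs.iloc[0, 0]
    return out


# ---------------------------------------------------------------------------
# cohort (linkage) recovery
# ---------------------------------------------------------------------------

#: Planted lineage panel for linkage benchmarks: three beneficial lineages
#: with well-separated dynamics plus one neutral lineage standing at 10%,
#: three private mutations each (one driver or marker, two passengers).
COHORT_PANEL = (
    PlantedLineage(1.12, 1e-3, (("gA", "driver_strong"), ("hA1", "passenger"), ("hA2", "passenger"))),
    PlantedLineage(1.06, 1e-3, (("gB", "driver_strong"), ("hB1", "passenger"), ("hB2", "passenger"))),
    PlantedLineage(1.18, 1e-3, (("gC", "driver_strong"), ("hC1", "passenger"), ("hC2", "passenger"))),
    PlantedLineage(1.00, 0.10, (("gD", "neutral"), ("hD1", "passenger"), ("hD2", "passenger"))),
)


def sequence_and_call(
    truth: TruthTable, rng: np.random.Generator, mean_depth: float = 800.0
):
    """Truth -> error-free 800x pooled sequencing -> filters -> trajectories."""
    cfg = SeqConfig(mean_depth=mean_depth, base_error_rate=0.0)
    counts = sequence_truth(truth, cfg, rng)
    calls = call_table(counts)
    return build_table(calls, truth.mutations, truth.sample_days)


def cohort_rand_index(
    rng: np.random.Generator,
    N: int = 100_000,
    mean_depth: float = 800.0,
    eps: float = 0.05,
    min_peak: float = 0.05,
) -> float | None:
    """Rand index between recovered cohorts and planted lineage linkage.

    One replicate: simulate the panel, sequence at ``mean_depth``, call,
    cluster, and score the partition of mutations with peak >= min_peak
    against their true lineage labels (unclustered mutations count as
    singleton clusters).  None when no mutation reaches the peak floor.
    """
    from sklearn.metrics import rand_score

    truth = planted_lineage_truth(list(COHORT_PANEL), N=N, sample_days=SAMPLE_DAYS, rng=rng)
    table = sequence_and_call(truth, rng, mean_depth)
    cohorts = detect_cohorts(table, eps=eps, min_peak=min_peak)
    peaks = table.freqs.max(axis=1)
    eligible = sorted(table.freqs.index[peaks >= min_peak])
    if not eligible:
        return None
    truth_labels = [int(truth.mutations.loc[m, "lineage_id"]) for m in eligible]
    assignment = {m: i for i, c in enumerate(cohorts) for m in c.members}
    pred_labels = [assignment.get(m, -1 - k) for k, m in enumerate(eligible)]
    return float(rand_score(truth_labels, pred_labels))


def linked_pair_recovery(
    rng: np.random.Generator,
    s: float = 0.2,
    N: int = 100_000,
    mean_depth: float = 800.0,
) -> bool:
    """Whether two mutations private to one sweeping lineage land in one cohort.

    The lineage is strongly beneficial (selection coefficient ``s``, the
    scale of the strongest effects in this system) so its trajectory
    traverses the frequency range within the sampled time course.
    """
    truth = planted_lineage_truth(
        [PlantedLineage(1.0 + s, 1e-3, (("gA", "driver_strong"), ("gB", "passenger")))],
        N=N, sample_days=SAMPLE_DAYS, rng=rng,
    )
    table = sequence_and_call(truth, rng, mean_depth)
    pair = {"p0_0", "p0_1"}
    return any(pair <= set(c.members) for c in detect_cohorts(table))


# ---------------------------------------------------------------------------
# planted sweep regimes for the gene classifier
# ---------------------------------------------------------------------------

def planted_gene_truth(
    kind: str,
    rng: np.random.Generator,
    N: int = 100_000,
    s_range: tuple[float, float] = (0.055, 0.085),
) -> TruthTable:
    """Truth table for one gene under a planted sweep regime.

    ``kind="hard"``: a single beneficial allele seeded at 1e-3 (large
    enough to establish almost surely, far below the 1% detection scale)
    sweeping to near fixation.  ``kind="soft"``: two co-spreading alleles
    of the same gene with equal benefit, seeded independently.
    """
    s = float(rng.uniform(*s_range))
    if kind == "hard":
        lineages = [PlantedLineage(1.0 + s, 1e-3, (("gene", "driver_late"),))]
    elif kind == "soft":
        lineages = [
            PlantedLineage(1.0 + s, 1e-3, (("gene", "driver_strong"),)),
            PlantedLineage(1.0 + s, 1e-3, (("gene", "driver_strong"),)),
        ]
    else:
        raise ValueError(f"unknown planted regime {kind!r}")
    return planted_lineage_truth(lineages, N=N, sample_days=SAMPLE_DAYS, rng=rng)


def classify_planted_gene(kind: str, rng: np.random.Generator, N: int = 100_000) -> str:
    """Verdict of the sweep classifier on one planted, sequenced gene."""
    truth = planted_gene_truth(kind, rng, N=N)
    table = sequence_and_call(truth, rng)
    return classify_gene_sweep(table.freqs, gene="gene").verdict


def classifier_accuracy(
    kind: str, n_genes: int, rng: np.random.Generator, N: int = 100_000
) -> float:
    """Fraction of planted genes of one regime recovered with that verdict."""
    hits = sum(classify_planted_gene(kind, rng, N) == kind for _ in range(n_genes))
    return hits / n_genes
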