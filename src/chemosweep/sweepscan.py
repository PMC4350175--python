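"""Cohort (linkage) detection and hard/soft sweep classification.

Mutations carried in the same genome rise and fall together, so their
estimated trajectories are near identical up to sequencing noise.  Cohorts
are recovered by single-linkage clustering under the L-infinity distance
(linked alleles must match in level, not merely in shape), restricted to
mutations that ever reach a minimum peak frequency.  Gene-level sweeps are
then classified from the trajectories of a gene's alleles:

* hard -- a single allele rises from at-or-below ~1% (or from below the
  detection limit) past 90%, with no second allele ever reaching 10%;
* soft -- two or more alleles of the gene each reach 10%;
* incomplete -- a single allele rises to [10%, 90%) and stalls, the
  signature of frequency-dependent persistence below fixation;
* none -- nothing reaches 10%.

Members of a driver-containing cohort whose own role is neutral (or
mutator) are flagged as hitchhikers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .trajdyn import TrajectoryTable

logger = logging.getLogger("chemosweep.sweepscan")

DRIVER_ROLES = ("driver_strong", "driver_late")


@dataclass
class Cohort:
    """A set of mutations moving through the population together."""

    members: tuple[str, ...]
    representative: pd.Series  # per-day mean trajectory
    driver_genes: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class SweepCall:
    gene: str
    verdict: str  # hard | soft | incomplete | none
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Hitchhiker:
    mutation_id: str
    cohort_index: int
    driver_genes: tuple[str, ...]


def trajectory_distance(a: pd.Series, b: pd.Series) -> float:
    """L-infinity distance: max over days of |a_t - b_t|."""
    if list(a.index) != list(b.index):
        raise ValueError("trajectories are on different sample-day grids")
    return float(np.max(np.abs(a.to_numpy(dtype=float) - b.to_numpy(dtype=float)))) if len(a) else 0.0


def detect_cohorts(
    table: TrajectoryTable, eps: float = 0.05, min_peak: float = 0.05
) -> list[Cohort]:
    """Single-linkage clustering of trajectories under L-infinity <= eps.

    Only mutations whose trajectory ever reaches ``min_peak`` are
    clustered; the rest are left out (too noisy to place).  Deterministic:
    mutations are processed in id order and cohorts are returned sorted by
    the id of their first member.  eps defaults to 0.05,
    roughly 3-4 binomial standard deviations of an 800x frequency estimate
    at mid frequencies.
    """
    peaks = table.freqs.max(axis=1)
    ids = sorted(table.freqs.index[peaks >= min_peak])
    if not ids:
        return []
    mat = table.freqs.loc[ids].to_numpy(dtype=float)
    if len(ids) == 1:
        labels = np.array([1])
    else:
        condensed = pdist(mat, metric="chebyshev")
        labels = fcluster(linkage(condensed, method="single"), t=eps, criterion="distance")
    roles = table.meta["role"] if "role" in table.meta.columns else None
    genes = table.meta["gene"] if "gene" in table.meta.columns else None
    cohorts = []
    for lab in np.unique(labels):
        members = tuple(m for m, l in zip(ids, labels) if l == lab)
        rep = table.freqs.loc[list(members)].mean(axis=0)
        drivers: tuple[str, ...] = ()
        if roles is not None and genes is not None:
            drivers = tuple(
                sorted({genes[m] for m in members if roles[m] in DRIVER_ROLES})
            )
        cohorts.append(Cohort(members=members, representative=rep, driver_genes=drivers))
    cohorts.sort(key=lambda c: c.members[0])
    logger.info("clustered %d mutations into %d cohorts", len(ids), len(cohorts))
    return cohorts


def classify_gene_sweep(
    allele_trajectories: pd.DataFrame,
    gene: str = "",
    hard_hi: float = 0.90,
    soft_min: float = 0.10,
    origin_max: float = 0.01,
) -> SweepCall:
    """Hard/soft/incomplete/none verdict from one gene's allele trajectories.

    ``allele_trajectories`` has one row per allele, one column per day.
    Hard requires exactly one allele ever >= hard_hi, rising from an origin
    at or below ``origin_max`` (or from below detection: absent at the
    first sampled day), and no other allele ever >= soft_min.
    """
    if len(allele_trajectories) == 0:
        raise ValueError("no allele trajectories given")
    peaks = allele_trajectories.max(axis=1)
    high = peaks[peaks >= hard_hi]
    mid = peaks[peaks >= soft_min]
    evidence = {
        "alleles": list(allele_trajectories.index),
        "peaks": {str(i): float(p) for i, p in peaks.items()},
    }
    if len(high) == 1 and len(mid) == 1:
        traj = allele_trajectories.loc[high.index[0]]
        nonzero = traj[traj > 0]
        first_freq = float(nonzero.iloc[0]) if len(nonzero) else 0.0
        absent_at_start = float(traj.iloc[0]) == 0.0
        evidence["first_detected_freq"] = first_freq
        if first_freq <= origin_max or absent_at_start:
            return SweepCall(gene, "hard", evidence)
    if len(mid) >= 2:
        return SweepCall(gene, "soft", evidence)
    if len(mid) == 1 and float(mid.iloc[0]) < hard_hi:
        return SweepCall(gene, "incomplete", evidence)
    if len(mid) == 1:
        # single near-fixed allele whose origin was already above origin_max:
        # cannot be called a de novo hard sweep
        return SweepCall(gene, "none", evidence)
    return SweepCall(gene, "none", evidence)


def classify_sweeps(
    table: TrajectoryTable,
    hard_hi: float = 0.90,
    soft_min: float = 0.10,
    origin_max: float = 0.01,
) -> list[SweepCall]:
    """Sweep verdicts for every gene with detected nonsynonymous alleles."""
    ns = table.meta["effect"] == "nonsynonymous"
    detected = (table.freqs > 0).any(axis=1)
    calls = []
    for gene in sorted(set(table.meta.loc[ns & detected, "gene"])):
        mask = ns & detected & (table.meta["gene"] == gene)
        calls.append(
            classify_gene_sweep(
                table.freqs[mask], gene=gene,
                hard_hi=hard_hi, soft_min=soft_min, origin_max=origin_max,
            )
        )
    return calls


def detect_hitchhikers(
    cohorts: list[Cohort], roles: pd.Series
) -> list[Hitchhiker]:
    """Flag non-beneficial members of driver-containing cohorts.

    ``roles`` maps mutation id -> role.  Within any cohort containing a
    driver allele, members whose own role is passenger, neutral or mutator
    ride along by linkage, not by their own benefit.
    """
    flagged = []
    for i, cohort in enumerate(cohorts):
        if not cohort.driver_genes:
            continue
        for m in cohort.members:
            if roles.get(m, "passenger") not in DRIVER_ROLES:
                flagged.append(Hitchhiker(m, i, cohort.driver_genes))
    return flagged


def dominant_allele_succession(
    allele_trajectories: pd.DataFrame, dominance_min: float = 0.10
) -> list[tuple[float, str]]:
    """Runs of the per-day dominant allele of one gene.

    For each day, the allele of maximal frequency counts as dominant if it
    is at or above ``dominance_min`` (ties broken by allele id); successive
    days with the same dominant allele collapse into one run, reported as
    (first day of the run, allele id).  Days with no dominant allele break
    runs and are omitted.
    """
    if len(allele_trajectories) == 0:
        raise ValueError("no allele trajectories given")
    order = sorted(allele_trajectories.index)
    runs: list[tuple[float, str]] = []
    current: str | None = None
    for day in allele_trajectories.columns:
        col = allele_trajectories.loc[order, day]
        best = col.idxmax()  # first max in id order
        if float(col[best]) >= dominance_min:
            if best != current:
                runs.append((float(day), str(best)))
                current = str(best)
        else:
            current = None
    return runs


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------

def cohorts_to_frame(cohorts: list[Cohort]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(cohorts):
        for m in c.members:
            rows.append(
                {
                    "cohort": i,
                    "mutation_id": m,
                    "n_members": len(c),
                    "driver_genes": ",".join(c.driver_genes),
                }
            )
    return pd.DataFrame(rows, columns=["cohort", "mutation_id", "n_members", "driver_genes"])


def sweeps_to_frame(calls: list[SweepCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "verdict": c.verdict,
                "n_alleles": len(c.evidence.get("alleles", [])),
                "max_peak": max(c.evidence.get("peaks", {"": 0.0}).values()),
            }
            for c in calls
        ],
        columns=["gene", "verdict", "n_alleles", "max_peak"],
    )


def muller_plot(table: TrajectoryTable, path, genes: list[str] | None = None) -> None:
    """Stacked-area plot of gene-level summed allele frequencies."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .trajdyn import gene_frequency_sum

    if genes is None:
        ns = table.meta["effect"] == "nonsynonymous"
        peaks = table.freqs[ns].groupby(table.meta.loc[ns, "gene"]).sum().max(axis=1)
        genes = list(peaks.sort_values(ascending=False).head(8).index)
    days = table.sample_days
    series = [gene_frequency_sum(table, g).to_numpy() for g in genes]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.stackplot(days, series, labels=genes, alpha=0.8)
    ax.set_xlabel("day")
    ax.set_ylabel("summed allele frequency")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
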