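"""Allele-frequency trajectories and their summary statistics.

Assembles per-mutation frequency trajectories across the sampled days
(ABSENT = 0, never missing), then computes the occurrence spectrum,
persistence classes (singleton / recurrent / repeated / persistent), the
per-sample mutational load split by mutation class, gene-level allele
summaries (occurrence, allele count, peak of the summed allele frequency),
and gene-level summed-frequency time series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("chemosweep.trajdyn")

META_COLUMNS = ["position", "ref", "alt", "mut_class", "gene", "effect", "role"]
PERSISTENCE_CLASSES = ("undetected", "singleton", "recurrent", "repeated", "persistent")


@dataclass
class TrajectoryTable:
    """Mutation x sample-day matrix of estimated frequencies plus metadata.

    ``meta`` is indexed by mutation id; ``freqs`` shares that index and has
    one float column per sample day.
    """

    meta: pd.DataFrame
    freqs: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.freqs.index):
            raise ValueError("meta and freqs must share the same index")
        vals = self.freqs.to_numpy(dtype=float)
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def sample_days(self) -> list[float]:
        return [float(c) for c in self.freqs.columns]

    def detected(self) -> pd.DataFrame:
        """Rows with at least one nonzero day."""
        mask = (self.freqs > 0).any(axis=1)
        return self.freqs[mask]

    def to_tsv(self, path) -> None:
        self.meta.join(self.freqs).to_csv(path, sep="\t", index_label="mutation_id")

    @classmethod
    def read_tsv(cls, path) -> "TrajectoryTable":
        df = pd.read_csv(path, sep="\t", index_col="mutation_id")
        meta_cols = [c for c in df.columns if c in META_COLUMNS or c == "lineage_id"]
        day_cols = [c for c in df.columns if c not in meta_cols]
        freqs = df[day_cols].copy()
        freqs.columns = [float(c) for c in day_cols]
        return cls(meta=df[meta_cols].copy(), freqs=freqs)


def build_table(
    calls: pd.DataFrame, mutation_meta: pd.DataFrame, sample_days
) -> TrajectoryTable:
    """Assemble the trajectory matrix from per-sample calls.

    ``calls`` holds passed calls (mutation_id, sample_day, frequency);
    ABSENT combinations become 0.  A call naming a mutation missing from
    the metadata, or a day outside ``sample_days``, is an error.
    """
    days = [float(d) for d in sample_days]
    freqs = pd.DataFrame(0.0, index=mutation_meta.index.copy(), columns=days)
    passed = calls.loc[calls["passed"].astype(bool)] if "passed" in calls.columns else calls
    unknown = set(passed["mutation_id"]) - set(mutation_meta.index)
    if unknown:
        raise KeyError(f"calls reference unknown mutations: {sorted(unknown)[:5]}")
    bad_days = set(float(d) for d in passed["sample_day"]) - set(days)
    if bad_days:
        raise ValueError(f"calls reference days outside the sample grid: {sorted(bad_days)}")
    for row in passed.itertuples():
        freqs.at[row.mutation_id, float(row.sample_day)] = min(float(row.frequency), 1.0)
    meta_cols = [c for c in mutation_meta.columns if c in META_COLUMNS + ["lineage_id"]]
    return TrajectoryTable(meta=mutation_meta[meta_cols].copy(), freqs=freqs)


def occurrence_spectrum(table: TrajectoryTable) -> pd.Series:
    """Histogram: number of nonzero days -> number of mutations.

    Only ever-detected mutations contribute, so the bins sum to the number
    of mutations detected at least once.
    """
    n_days = (table.freqs > 0).sum(axis=1)
    n_days = n_days[n_days > 0]
    spectrum = n_days.value_counts().sort_index()
    spectrum.index.name = "n_samples_detected"
    spectrum.name = "n_mutations"
    return spectrum


def spectrum_summary(spectrum: pd.Series, total: int | None = None) -> dict[str, float]:
    """Singleton/recurrent counts and whole-number percentages.

    Works on any occurrence histogram (index = number of samples detected),
    including published ones, so printed totals can be re-derived.  A
    ``total`` denominator may be supplied when the histogram does not cover
    every tallied change (percentages are then taken against it).
    """
    total = int(spectrum.sum()) if total is None else int(total)
    n_singleton = int(spectrum.get(1, 0))
    n_recurrent = int(spectrum.sum()) - n_singleton
    return {
        "total": total,
        "n_singleton": n_singleton,
        "n_recurrent": n_recurrent,
        "pct_singleton": round(100.0 * n_singleton / total) if total else 0.0,
        "pct_recurrent": round(100.0 * n_recurrent / total) if total else 0.0,
    }


def coding_effect_summary(
    n_nonsynonymous: int, n_synonymous: int, n_noncoding: int
) -> dict[str, float]:
    """Whole-number percentages of SNP effect classes out of all SNPs."""
    total = n_nonsynonymous + n_synonymous + n_noncoding
    return {
        "total": total,
        "pct_nonsynonymous": round(100.0 * n_nonsynonymous / total) if total else 0.0,
        "pct_synonymous": round(100.0 * n_synonymous / total) if total else 0.0,
        "pct_noncoding": round(100.0 * n_noncoding / total) if total else 0.0,
    }


def classify_mutation(trajectory: pd.Series) -> str:
    """Finest persistence class of one trajectory.

    singleton = detected on exactly 1 day; recurrent = on >= 2; repeated =
    on >= 3; persistent = on every sampled day.  Classes are nested
    (persistent implies repeated implies recurrent); the finest applicable
    label is returned, or "undetected" for an all-zero trajectory.
    """
    n = int((trajectory > 0).sum())
    if n == 0:
        return "undetected"
    if n == 1:
        return "singleton"
    if n == len(trajectory) and n >= 3:
        return "persistent"
    if n >= 3:
        return "repeated"
    return "recurrent"


def classify_all(table: TrajectoryTable) -> pd.Series:
    out = table.freqs.apply(classify_mutation, axis=1)
    out.name = "persistence_class"
    return out


def mutational_load(table: TrajectoryTable, day: float) -> dict[str, int]:
    """Detected-mutation counts at one day, split by mutation class."""
    day = float(day)
    if day not in [float(c) for c in table.freqs.columns]:
        raise ValueError(f"day {day} is not a sampled day {table.sample_days}")
    present = table.freqs[day] > 0
    counts = table.meta.loc[present, "mut_class"].value_counts()
    return {c: int(counts.get(c, 0)) for c in ("SNP", "S-indel", "L-indel", "duplication")}


def load_series(table: TrajectoryTable) -> pd.DataFrame:
    """Mutational load at every sampled day (rows: days, columns: classes)."""
    rows = {d: mutational_load(table, d) for d in table.sample_days}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_day"
    out["total"] = out.sum(axis=1)
    return out


def gene_frequency_sum(table: TrajectoryTable, gene: str) -> pd.Series:
    """Per-day sum of a gene's nonsynonymous allele frequencies, capped at 1.

    The raw sum can exceed 1 when one genome carries two alleles of the
    gene; that situation is logged and the series capped.
    """
    if gene not in set(table.meta["gene"]):
        raise KeyError(f"unknown gene {gene!r}")
    mask = (table.meta["gene"] == gene) & (table.meta["effect"] == "nonsynonymous")
    total = table.freqs[mask].sum(axis=0)
    if (total > 1.0).any():
        logger.warning(
            "gene %s: summed allele frequency exceeds 1 at %d day(s) "
            "(possible double alleles in one genome); capping",
            gene, int((total > 1.0).sum()),
        )
    total = total.clip(upper=1.0)
    total.name = gene
    return total


def gene_summary(table: TrajectoryTable, min_repeated_days: int = 3) -> pd.DataFrame:
    """Gene-level allele summary over repeatedly detected nonsynonymous changes.

    One row per gene with at least one nonsynonymous mutation detected on
    >= ``min_repeated_days`` days: the number of samples in which any
    nonsynonymous allele of the gene is detected, the number of distinct
    detected alleles, and the peak over days of the summed (capped) allele
    frequency.  Sorted by peak descending.
    """
    ns = table.meta["effect"] == "nonsynonymous"
    detected_days = (table.freqs > 0).sum(axis=1)
    repeated = ns & (detected_days >= min_repeated_days)
    rows = []
    for gene in sorted(set(table.meta.loc[repeated, "gene"])):
        alleles = ns & (table.meta["gene"] == gene) & (detected_days > 0)
        sub = table.freqs[alleles]
        per_day_sum = sub.sum(axis=0).clip(upper=1.0)
        rows.append(
            {
                "gene": gene,
                "n_samples_present": int(((sub > 0).any(axis=0)).sum()),
                "n_alleles": int(alleles.sum()),
                "peak_freq": float(per_day_sum.max()) if len(per_day_sum) else 0.0,
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "n_samples_present", "n_alleles", "peak_freq"])
    return out.sort_values("peak_freq", ascending=False, kind="stable").reset_index(drop=True)
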