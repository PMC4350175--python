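"""Pooled variant calling: filters and allele-frequency estimation.

A mutant allele in a population-sequencing sample is *called* when the site
is covered by reads on both the forward and reverse strand, at least three
reads support the mutant allele, and the estimated frequency
(alt reads / total depth) is at or above the 1% reporting threshold.
Sites failing any filter are ABSENT and treated as frequency 0 downstream
(an undetectably rare allele, not missing data).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

logger = logging.getLogger("chemosweep.varcall")


@dataclass(frozen=True)
class CallPolicy:
    min_alt_reads: int = 3
    require_both_strand_coverage: bool = True
    # stricter variant: demand mutant reads themselves on both strands
    require_alt_both_strands: bool = False
    min_report_freq: float = 0.01

    def __post_init__(self) -> None:
        if self.min_alt_reads < 1:
            raise ValueError("min_alt_reads must be >= 1")
        if not (0.0 < self.min_report_freq < 1.0):
            raise ValueError("min_report_freq must be in (0, 1)")


@dataclass(frozen=True)
class VariantCall:
    mutation_id: str
    sample_day: float
    alt_count: int
    depth: int
    frequency: float
    passed: bool


def call_site(site, policy: CallPolicy = CallPolicy()) -> VariantCall | None:
    """Apply the pooled-calling filters to one site; None means ABSENT."""
    depth = site.depth_fwd + site.depth_rev
    alt = site.alt_fwd + site.alt_rev
    if depth == 0:
        logger.debug("no coverage at %s day %s", site.mutation_id, site.sample_day)
        return None
    freq = alt / depth
    if policy.require_both_strand_coverage and (site.depth_fwd == 0 or site.depth_rev == 0):
        return None
    if policy.require_alt_both_strands and (site.alt_fwd == 0 or site.alt_rev == 0):
        return None
    if alt < policy.min_alt_reads:
        return None
    if freq < policy.min_report_freq:
        return None
    return VariantCall(
        mutation_id=str(site.mutation_id),
        sample_day=float(site.sample_day),
        alt_count=int(alt),
        depth=int(depth),
        frequency=freq,
        passed=True,
    )


def call_table(site_counts: pd.DataFrame, policy: CallPolicy = CallPolicy()) -> pd.DataFrame:
    """Vectorized filters over a SiteCounts table (any mix of days).

    Returns one row per input row, in order, with ``passed`` and the filter
    flags; frequency is alt/depth (0 at zero depth).
    """
    df = site_counts
    depth = (df["depth_fwd"] + df["depth_rev"]).to_numpy()
    alt = (df["alt_fwd"] + df["alt_rev"]).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    strand_ok = np.ones(len(df), dtype=bool)
    if policy.require_both_strand_coverage:
        strand_ok &= (df["depth_fwd"] > 0).to_numpy() & (df["depth_rev"] > 0).to_numpy()
    if policy.require_alt_both_strands:
        strand_ok &= (df["alt_fwd"] > 0).to_numpy() & (df["alt_rev"] > 0).to_numpy()
    support_ok = alt >= policy.min_alt_reads
    freq_ok = freq >= policy.min_report_freq
    passed = (depth > 0) & strand_ok & support_ok & freq_ok
    return pd.DataFrame(
        {
            "mutation_id": df["mutation_id"].to_numpy(),
            "sample_day": df["sample_day"].to_numpy(dtype=float),
            "alt_count": alt,
            "alt_fwd": df["alt_fwd"].to_numpy(),
            "alt_rev": df["alt_rev"].to_numpy(),
            "depth": depth,
            "frequency": freq,
            "strand_ok": strand_ok,
            "support_ok": support_ok,
            "freq_ok": freq_ok,
            "passed": passed,
        }
    )


def call_sample(
    site_counts: pd.DataFrame, policy: CallPolicy = CallPolicy()
) -> list[VariantCall]:
    """Calls for one sample's SiteCounts table (ABSENT rows omitted)."""
    days = set(site_counts["sample_day"]) if len(site_counts) else set()
    if len(days) > 1:
        raise ValueError(f"call_sample expects a single sample day, got {sorted(days)}")
    out = call_table(site_counts, policy)
    return [
        VariantCall(r.mutation_id, r.sample_day, int(r.alt_count), int(r.depth), r.frequency, True)
        for r in out[out["passed"]].itertuples()
    ]


def detection_probability(
    f: float, mean_depth: float, policy: CallPolicy = CallPolicy()
) -> float:
    """Exact probability that a site at true frequency f passes all filters.

    Companion to the filters under the error-free sequencing model with
    fixed depth D: alt reads X ~ Binomial(D, f) must reach
    max(min_alt_reads, ceil(min_report_freq * D)), and both strands must be
    covered, which for a Bernoulli(1/2) strand split happens with
    probability 1 - 2*(1/2)^D.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"frequency must be in [0,1], got {f}")
    d = int(round(mean_depth))
    if d <= 0:
        return 0.0
    k = max(policy.min_alt_reads, math.ceil(policy.min_report_freq * d))
    tail = float(binom.sf(k - 1, d, f))
    strand = 1.0 - 2.0 * 0.5**d if policy.require_both_strand_coverage else 1.0
    return tail * strand


# ---------------------------------------------------------------------------
# output formats
# ---------------------------------------------------------------------------

def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(
    calls: pd.DataFrame,
    mutations: pd.DataFrame,
    path,
    contig: str = "chrom",
    contig_length: int | None = None,
) -> None:
    """Write passed calls as a minimal VCF with DP/AF/SAF/SAR INFO fields.

    ``mutations`` (indexed by mutation id) supplies POS/REF/ALT; symbolic
    alt descriptors (indels, duplications) are emitted as symbolic ALT
    alleles.  One record per called site x day, day carried in the ID.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##source=chemosweep")
    if contig_length is not None:
        header.contigs.add(contig, length=contig_length)
    else:
        header.contigs.add(contig)
    header.info.add("DP", 1, "Integer", "Total read depth at the site")
    header.info.add("AF", "A", "Float", "Estimated alternate allele frequency")
    header.info.add("SAF", 1, "Integer", "Alternate-supporting reads, forward strand")
    header.info.add("SAR", 1, "Integer", "Alternate-supporting reads, reverse strand")
    header.info.add("DAY", 1, "Float", "Sample day")

    passed = calls.loc[calls["passed"].astype(bool)] if "passed" in calls.columns else calls
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in passed.itertuples():
            meta = mutations.loc[row.mutation_id]
            ref = str(meta["ref"])
            alt = str(meta["alt"])
            if not set(alt) <= set("ACGT"):
                alt = "<%s>" % str(meta["mut_class"]).replace("-", "_").upper()
                ref = ref[:1] if ref else "N"
            rec = vcf.new_record(
                contig=contig,
                start=int(meta["position"]) - 1,
                stop=int(meta["position"]),
                alleles=(ref, alt),
                id=f"{row.mutation_id}_d{row.sample_day:g}",
            )
            rec.info["DP"] = int(row.depth)
            rec.info["AF"] = (float(row.frequency),)
            if hasattr(row, "alt_fwd"):
                rec.info["SAF"] = int(row.alt_fwd)
                rec.info["SAR"] = int(row.alt_rev)
            rec.info["DAY"] = float(row.sample_day)
            vcf.write(rec)
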