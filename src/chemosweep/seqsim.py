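"""Pooled-sequencing evidence simulator.

Turns true allele frequencies into per-site strand-split read counts
(Poisson depth, Bernoulli strand assignment, symmetric base errors), and
generates paired-end FASTQ fixtures with planted PCR duplicates and planted
low-quality flanks for exercising the preprocessing stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("chemosweep.seqsim")

SITE_COUNT_COLUMNS = [
    "mutation_id", "sample_day", "depth_fwd", "depth_rev", "alt_fwd", "alt_rev",
]


@dataclass
class SeqConfig:
    """Pooled-sequencing model parameters.

    Depth is Poisson around ``mean_depth`` (default 800x, the coverage of a
    high-depth population library); ``depth_law="fixed"`` makes every site
    exactly ``mean_depth`` deep instead, which is what the closed-form
    detection-probability companion assumes.  Reads land on either strand with
    probability ``strand_prob``; each read misreports the site with
    per-base error ``base_error_rate``, symmetric over the three non-ref
    bases, so the effective error toward the tracked alt allele is e/3.
    """

    mean_depth: float = 800.0
    depth_law: str = "poisson"  # "poisson" | "fixed"
    strand_prob: float = 0.5
    base_error_rate: float = 0.001
    read_len: int = 101
    seed: int | None = None

    def validate(self) -> list[str]:
        errors = []
        if self.mean_depth <= 0:
            errors.append(f"mean_depth: must be > 0, got {self.mean_depth}")
        if self.depth_law not in ("poisson", "fixed"):
            errors.append(f"depth_law: must be 'poisson' or 'fixed', got {self.depth_law!r}")
        if not (0 <= self.base_error_rate < 0.25):
            errors.append(f"base_error_rate: must be in [0, 0.25), got {self.base_error_rate}")
        if not (0 <= self.strand_prob <= 1):
            errors.append("strand_prob: must be in [0, 1]")
        if self.read_len < 1:
            errors.append("read_len: must be >= 1")
        return errors

    def require_valid(self) -> "SeqConfig":
        errors = self.validate()
        if errors:
            raise ValueError("invalid SeqConfig: " + "; ".join(errors))
        return self


@dataclass(frozen=True)
class SiteCounts:
    """Strand-split sequencing evidence for one mutation in one sample."""

    mutation_id: str
    sample_day: float
    depth_fwd: int
    depth_rev: int
    alt_fwd: int
    alt_rev: int

    def __post_init__(self) -> None:
        if not (0 <= self.alt_fwd <= self.depth_fwd and 0 <= self.alt_rev <= self.depth_rev):
            raise ValueError(f"alt counts exceed depth for {self.mutation_id}")


def alt_read_probability(true_freq: float, base_error_rate: float) -> float:
    """P(one read reports the alt allele): f(1-e) + (1-f)e/3."""
    f, e = true_freq, base_error_rate
    return f * (1.0 - e) + (1.0 - f) * e / 3.0


def sample_site_counts(
    true_freq: float,
    mutation_id: str,
    sample_day: float,
    cfg: SeqConfig,
    rng: np.random.Generator,
) -> SiteCounts:
    """Draw sequencing evidence for one site at one time point."""
    if not (0.0 <= true_freq <= 1.0):
        raise ValueError(f"true frequency must be in [0,1], got {true_freq}")
    cfg.require_valid()
    depth = rng.poisson(cfg.mean_depth) if cfg.depth_law == "poisson" else int(round(cfg.mean_depth))
    depth_fwd = rng.binomial(depth, cfg.strand_prob)
    depth_rev = depth - depth_fwd
    p = alt_read_probability(true_freq, cfg.base_error_rate)
    return SiteCounts(
        mutation_id=mutation_id,
        sample_day=float(sample_day),
        depth_fwd=int(depth_fwd),
        depth_rev=int(depth_rev),
        alt_fwd=int(rng.binomial(depth_fwd, p)),
        alt_rev=int(rng.binomial(depth_rev, p)),
    )


def make_sample(
    truth_at_day: pd.Series, sample_day: float, cfg: SeqConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Sequencing evidence for every mutation at one sample day (vectorized)."""
    cfg.require_valid()
    freqs = truth_at_day.to_numpy(dtype=float)
    if freqs.size and (freqs.min() < 0 or freqs.max() > 1):
        raise ValueError("truth frequencies must lie in [0, 1]")
    n = len(freqs)
    if cfg.depth_law == "poisson":
        depth = rng.poisson(cfg.mean_depth, size=n)
    else:
        depth = np.full(n, int(round(cfg.mean_depth)))
    depth_fwd = rng.binomial(depth, cfg.strand_prob)
    depth_rev = depth - depth_fwd
    p = alt_read_probability(freqs, cfg.base_error_rate) if n else np.array([])
    alt_fwd = rng.binomial(depth_fwd, p) if n else np.array([], dtype=int)
    alt_rev = rng.binomial(depth_rev, p) if n else np.array([], dtype=int)
    return pd.DataFrame(
        {
            "mutation_id": truth_at_day.index,
            "sample_day": float(sample_day),
            "depth_fwd": depth_fwd.astype(int),
            "depth_rev": depth_rev.astype(int),
            "alt_fwd": alt_fwd.astype(int),
            "alt_rev": alt_rev.astype(int),
        }
    )


def sequence_truth(truth, cfg: SeqConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sequencing evidence for every mutation at every sample day."""
    frames = [
        make_sample(truth.freqs[day], day, cfg, rng) for day in truth.freqs.columns
    ]
    if not frames:
        return pd.DataFrame(columns=SITE_COUNT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    logger.info("sequenced %d site x day observations", len(out))
    return out


def write_site_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_site_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# read-pair fixtures for the preprocessing stage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadPair:
    """One paired-end fragment with fixture truth flags.

    ``is_duplicate_of`` points at the batch index of the original pair this
    one is an exact PCR copy of (None for originals); ``true_trim_span*``
    are the planted high-quality spans, half-open.
    """

    seq1: str
    qual1: tuple[int, ...]
    seq2: str
    qual2: tuple[int, ...]
    is_duplicate_of: int | None = None
    true_trim_span1: tuple[int, int] | None = None
    true_trim_span2: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError("sequence and quality lengths differ")


@dataclass
class ReadPairBatch:
    pairs: list[ReadPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


@dataclass(frozen=True)
class QualityProfile:
    """Planted quality structure: q_high inside the kept span, q_low flanks."""

    q_high: int = 30
    q_low: int = 2
    min_span: int = 30
    max_span: int | None = None  # default: full read length


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _planted_read(
    cfg: SeqConfig, profile: QualityProfile, rng: np.random.Generator
) -> tuple[str, tuple[int, ...], tuple[int, int]]:
    n = cfg.read_len
    hi = profile.max_span if profile.max_span is not None else n
    span_len = int(rng.integers(profile.min_span, hi + 1))
    start = int(rng.integers(0, n - span_len + 1))
    qual = [profile.q_low] * n
    qual[start : start + span_len] = [profile.q_high] * span_len
    return _random_seq(n, rng), tuple(qual), (start, start + span_len)


def make_read_pairs(
    n_fragments: int,
    dup_fraction: float,
    cfg: SeqConfig,
    quality_profile: QualityProfile | None = None,
    rng: np.random.Generator | None = None,
) -> ReadPairBatch:
    """Generate a read-pair batch with planted duplicates and trim spans.

    Exactly ``round(n_fragments * dup_fraction)`` pairs are exact copies of
    earlier pairs (identical sequence and qualities, hence identical first
    20 bases of both mates -- the key the duplicate filter must trip on).
    Originals come first, duplicates after, each flagged with the index of
    its source.
    """
    if not (0.0 <= dup_fraction < 1.0):
        raise ValueError(f"dup_fraction must be in [0, 1), got {dup_fraction}")
    cfg.require_valid()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    profile = quality_profile if quality_profile is not None else QualityProfile()

    n_dup = int(round(n_fragments * dup_fraction))
    n_orig = n_fragments - n_dup
    pairs: list[ReadPair] = []
    for _ in range(n_orig):
        s1, q1, span1 = _planted_read(cfg, profile, rng)
        s2, q2, span2 = _planted_read(cfg, profile, rng)
        pairs.append(ReadPair(s1, q1, s2, q2, None, span1, span2))
    for _ in range(n_dup):
        src = int(rng.integers(0, n_orig))
        orig = pairs[src]
        pairs.append(
            ReadPair(
                orig.seq1, orig.qual1, orig.seq2, orig.qual2,
                src, orig.true_trim_span1, orig.true_trim_span2,
            )
        )
    return ReadPairBatch(pairs)


def write_fastq(batch: ReadPairBatch, path1, path2) -> None:
    """Write the two mates of each pair as Phred+33 FASTQ files."""
    recs1, recs2 = [], []
    for i, p in enumerate(batch):
        r1 = SeqRecord(Seq(p.seq1), id=f"frag{i}/1", description="")
        r1.letter_annotations["phred_quality"] = list(p.qual1)
        r2 = SeqRecord(Seq(p.seq2), id=f"frag{i}/2", description="")
        r2.letter_annotations["phred_quality"] = list(p.qual2)
        recs1.append(r1)
        recs2.append(r2)
    SeqIO.write(recs1, str(path1), "fastq")
    SeqIO.write(recs2, str(path2), "fastq")


def read_fastq_pairs(path1, path2) -> ReadPairBatch:
    pairs = []
    for r1, r2 in zip(SeqIO.parse(str(path1), "fastq"), SeqIO.parse(str(path2), "fastq")):
        pairs.append(
            ReadPair(
                str(r1.seq), tuple(r1.letter_annotations["phred_quality"]),
                str(r2.seq), tuple(r2.letter_annotations["phred_quality"]),
            )
        )
    return ReadPairBatch(pairs)
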