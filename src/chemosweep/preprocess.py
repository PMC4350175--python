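"""Read trimming and PCR-duplicate removal for paired FASTQ.

Two rules, applied to raw paired-end reads before alignment:

* duplicate removal -- pairs whose mates share the same first 20 bases in
  both reads are PCR copies of one fragment; only the first occurrence is
  kept (mate order matters: (A,B) and (B,A) are different fragments);
* quality trimming -- each read is cut to its longest contiguous segment in
  which every base's error probability 10^(-Q/10) is at or below ``p_max``
  (0.05, i.e. Q >= 14 on the Phred scale), and discarded unless the
  segment is strictly longer than ``min_len`` (25 bp, so >= 26 kept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqsim import ReadPair, ReadPairBatch, read_fastq_pairs, write_fastq

logger = logging.getLogger("chemosweep.preprocess")

DEDUP_KEY_LEN = 20


@dataclass(frozen=True)
class TrimPolicy:
    p_max: float = 0.05  # max per-base error probability inside the kept span
    min_len: int = 25  # strict: spans of exactly min_len are rejected

    def __post_init__(self) -> None:
        if not (0.0 < self.p_max < 1.0):
            raise ValueError(f"p_max must be in (0, 1), got {self.p_max}")
        if self.min_len < 1:
            raise ValueError(f"min_len must be >= 1, got {self.min_len}")


def error_prob(q: float) -> float:
    """Per-base error probability of Phred score q: 10^(-q/10)."""
    if q < 0:
        raise ValueError(f"Phred score must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


def trim_read(
    qualities: Sequence[int], policy: TrimPolicy = TrimPolicy()
) -> tuple[int, int] | None:
    """Longest contiguous run of bases with error_prob <= p_max.

    Returns the half-open span [start, end), ties broken leftmost, or None
    (reject) when the best run is not longer than ``min_len``.
    """
    if len(qualities) == 0:
        raise ValueError("empty quality vector")
    ok = np.array([error_prob(q) <= policy.p_max for q in qualities])
    best_start, best_len = 0, 0
    run_start = None
    for i, good in enumerate(list(ok) + [False]):
        if good and run_start is None:
            run_start = i
        elif not good and run_start is not None:
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = None
    if best_len <= policy.min_len:
        return None
    return (best_start, best_start + best_len)


def dedup_pairs(batch: ReadPairBatch) -> ReadPairBatch:
    """Drop pairs sharing the same first 20 bases in both reads.

    The key is (read1[:20], read2[:20]); the first occurrence in input
    order is kept and input order is preserved.  Reads shorter than 20 bp
    contribute their whole sequence to the key.
    """
    seen: set[tuple[str, str]] = set()
    kept: list[ReadPair] = []
    for pair in batch:
        key = (pair.seq1[:DEDUP_KEY_LEN], pair.seq2[:DEDUP_KEY_LEN])
        if key in seen:
            continue
        seen.add(key)
        kept.append(pair)
    return ReadPairBatch(kept)


def trim_pairs(
    batch: ReadPairBatch, policy: TrimPolicy = TrimPolicy()
) -> tuple[ReadPairBatch, int]:
    """Trim both mates of every pair; drop the pair if either mate fails.

    Returns the trimmed batch and the number of pairs rejected.
    """
    kept: list[ReadPair] = []
    rejected = 0
    for pair in batch:
        span1 = trim_read(pair.qual1, policy)
        span2 = trim_read(pair.qual2, policy)
        if span1 is None or span2 is None:
            rejected += 1
            continue
        a1, b1 = span1
        a2, b2 = span2
        kept.append(
            ReadPair(
                pair.seq1[a1:b1], pair.qual1[a1:b1],
                pair.seq2[a2:b2], pair.qual2[a2:b2],
                pair.is_duplicate_of, None, None,
            )
        )
    return ReadPairBatch(kept), rejected


def process_fastq(
    in1, in2, out1, out2, policy: TrimPolicy = TrimPolicy()
) -> dict[str, int]:
    """Dedup then trim a FASTQ pair of files; returns a summary.

    Dedup runs first so that the duplicate key sees the untrimmed 5' ends,
    then each surviving pair is trimmed (pairs with an unrescuable mate are
    dropped whole).
    """
    batch = read_fastq_pairs(in1, in2)
    n_in = len(batch)
    deduped = dedup_pairs(batch)
    trimmed, rejected = trim_pairs(deduped, policy)
    write_fastq(trimmed, out1, out2)
    summary = {
        "pairs_in": n_in,
        "pairs_deduped": n_in - len(deduped),
        "pairs_rejected_by_trim": rejected,
        "pairs_out": len(trimmed),
    }
    logger.info(
        "preprocess: %(pairs_in)d pairs in, %(pairs_deduped)d duplicates removed, "
        "%(pairs_rejected_by_trim)d rejected by trimming, %(pairs_out)d out",
        summary,
    )
    return summary
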