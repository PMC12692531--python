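"""3'-anchored 60-mer probe design with masking and cross-hybridization screening.

The design strategy mirrors the one-probe-per-gene approach used for gene
expression arrays on heavily duplicated fish genomes: mask vector and
low-complexity sequence, enumerate 60-mer candidates inside the 3'-terminal
1000 nt of each gene's representative transcript, rank them by a declared
base-composition score with a positional bias toward the 3' end, pick one
probe per gene, and flag probes with cross-hybridization potential against
transcripts of other genes.

The candidate score is a documented surrogate for vendor base-composition
ranking (the vendor weights are proprietary):

    score = - gc_weight * |GC - gc_target|
            - homopolymer_weight * max(0, longest_run - max_homopolymer)
            - position_weight * distance_to_3prime / window

so a perfectly GC-balanced, run-free candidate flush with the 3' end scores 0,
the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .transcriptome import GeneModel, TranscriptSet, reverse_complement

__all__ = [
    "MaskedSequence",
    "ProbeCandidate",
    "ProbeRecord",
    "DesignAccounting",
    "ScoringParams",
    "XHybParams",
    "mask_sequence",
    "enumerate_candidates",
    "score_candidate",
    "design_probes",
    "cross_hyb_screen",
    "design_accounting",
]

PROBE_LENGTH = 60
WINDOW_3PRIME = 1000

_STATUSES = ("designed", "too_short", "duplicate", "masked", "design_fail")
_EXCLUSIONS = ("too_short", "duplicate", "masked", "design_fail")


@dataclass(frozen=True)
class MaskedSequence:
    """A sequence with sorted, disjoint masked intervals (0-based half-open).

    Overlapping intervals from different sources are merged; the merged
    interval keeps the highest-priority source tag
    (vector > low_complexity > ambiguous).
    """

    sequence: str
    intervals: tuple[tuple[int, int, str], ...] = ()

    @property
    def masked(self) -> tuple[tuple[int, int], ...]:
        return tuple((s, e) for s, e, _ in self.intervals)

    def is_masked(self, start: int, end: int) -> bool:
        """True if [start, end) overlaps any masked interval."""
        return any(s < end and start < e for s, e, _ in self.intervals)


@dataclass(frozen=True)
class ProbeCandidate:
    gene_id: str
    start: int
    sequence: str
    distance_to_3prime: int
    score: float = 0.0


@dataclass
class ProbeRecord:
    probe_id: str
    gene_id: str
    transcript_id: str
    sequence: str
    start: int
    status: str
    score: float = 0.0
    xhyb_flag: bool = False

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class DesignAccounting:
    """Per-reason design ledger; submitted == designed + sum(exclusions)."""

    submitted: int
    designed: int
    too_short: int
    duplicate: int
    masked: int
    design_fail: int

    def __post_init__(self) -> None:
        total = self.designed + self.too_short + self.duplicate + self.masked + self.design_fail
        if total != self.submitted:
            raise ValueError(
                f"accounting identity violated: submitted={self.submitted} "
                f"!= designed+exclusions={total}"
            )

    @classmethod
    def from_exclusions(
        cls, submitted: int, too_short: int, duplicate: int, masked: int, design_fail: int
    ) -> "DesignAccounting":
        designed = submitted - (too_short + duplicate + masked + design_fail)
        return cls(submitted, designed, too_short, duplicate, masked, design_fail)


@dataclass(frozen=True)
class ScoringParams:
    gc_target: float = 0.45
    gc_weight: float = 1.0
    homopolymer_weight: float = 0.5
    position_weight: float = 0.5
    max_homopolymer: int = 6
    score_floor: float = -4.0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must be in (0,1)")
        if min(self.gc_weight, self.homopolymer_weight, self.position_weight) < 0:
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class XHybParams:
    seed_length: int = 15
    flag_exact_run: int = 25
    flag_identity: int = 45

    def __post_init__(self) -> None:
        if not self.seed_length <= self.flag_exact_run <= PROBE_LENGTH:
            raise ValueError("need seed_length <= flag_exact_run <= 60")
        if self.flag_identity > PROBE_LENGTH:
            raise ValueError("flag_identity must be <= 60")


# ---------------------------------------------------------------------------
# masking


def _merge(intervals: list[tuple[int, int, str]]) -> tuple[tuple[int, int, str], ...]:
    priority = {"vector": 0, "low_complexity": 1, "ambiguous": 2}
    merged: list[list] = []
    for s, e, tag in sorted(intervals, key=lambda iv: (iv[0], iv[1])):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            if priority[tag] < priority[merged[-1][2]]:
                merged[-1][2] = tag
        else:
            merged.append([s, e, tag])
    return tuple((s, e, t) for s, e, t in merged)


def _vector_intervals(seq: str, vectors, min_match: int) -> list[tuple[int, int, str]]:
    # positions covered by any shared min_match-mer equal the union of all
    # maximal exact matches of length >= min_match
    kmers: set[str] = set()
    for v in vectors:
        for strand in (v, reverse_complement(v)):
            for i in range(len(strand) - min_match + 1):
                kmers.add(strand[i : i + min_match])
    if not kmers:
        return []
    covered = bytearray(len(seq))
    for i in range(len(seq) - min_match + 1):
        if seq[i : i + min_match] in kmers:
            for j in range(i, i + min_match):
                covered[j] = 1
    return _runs(covered, "vector")


def _dust_intervals(seq: str, window: int, threshold: float) -> list[tuple[int, int, str]]:
    # DUST-style triplet overrepresentation score per sliding window:
    # sum c*(c-1)/2 over triplet counts c, divided by (n_triplets - 1)
    n = len(seq)
    w = min(window, n)
    if w < 4:
        return []
    covered = bytearray(n)
    counts: dict[str, int] = {}
    pair_sum = 0  # sum of c*(c-1)/2

    def add(t: str, delta: int) -> int:
        nonlocal pair_sum
        c = counts.get(t, 0)
        pair_sum -= c * (c - 1) // 2
        c += delta
        counts[t] = c
        pair_sum += c * (c - 1) // 2
        return c

    ntrip = w - 2
    for i in range(ntrip):
        add(seq[i : i + 3], +1)
    for start in range(0, n - w + 1):
        if pair_sum / (ntrip - 1) > threshold:
            for j in range(start, start + w):
                covered[j] = 1
        if start + w < n:
            add(seq[start : start + 3], -1)
            add(seq[start + w - 2 : start + w + 1], +1)
    return _runs(covered, "low_complexity")


def _runs(covered: bytearray, tag: str) -> list[tuple[int, int, str]]:
    out = []
    start = None
    for i, c in enumerate(covered):
        if c and start is None:
            start = i
        elif not c and start is not None:
            out.append((start, i, tag))
            start = None
    if start is not None:
        out.append((start, len(covered), tag))
    return out


def mask_sequence(
    seq: str,
    vectors=(),
    dust_window: int = 64,
    dust_threshold: float = 2.0,
    vector_min_match: int = 15,
) -> MaskedSequence:
    """Mask vector matches, low-complexity windows and ambiguous bases.

    Vector intervals are all maximal exact matches of at least
    ``vector_min_match`` nt to any vector sequence or its reverse complement;
    low-complexity intervals come from a DUST-style triplet-count score over
    sliding windows; every N is masked as ambiguous.
    """
    if not seq:
        raise ValueError("empty sequence")
    intervals = _vector_intervals(seq, vectors, vector_min_match)
    intervals += _dust_intervals(seq, dust_window, dust_threshold)
    intervals += [(i, i + 1, "ambiguous") for i, b in enumerate(seq) if b == "N"]
    return MaskedSequence(seq, _merge(intervals))


# ---------------------------------------------------------------------------
# candidate enumeration and scoring


def enumerate_candidates(
    ms: MaskedSequence, window: int = WINDOW_3PRIME, probe_len: int = PROBE_LENGTH
) -> list[ProbeCandidate]:
    """All unmasked probe-length windows within the 3'-terminal region."""
    if probe_len < 1:
        raise ValueError("probe_len must be >= 1")
    n = len(ms.sequence)
    if n < probe_len:
        return []
    first_start = max(0, n - window)
    out = []
    for start in range(first_start, n - probe_len + 1):
        if ms.is_masked(start, start + probe_len):
            continue
        out.append(
            ProbeCandidate(
                gene_id="",
                start=start,
                sequence=ms.sequence[start : start + probe_len],
                distance_to_3prime=n - (start + probe_len),
            )
        )
    return out


def _longest_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def score_candidate(
    c: ProbeCandidate, p: ScoringParams, window: int = WINDOW_3PRIME
) -> float:
    gc = (c.sequence.count("G") + c.sequence.count("C")) / len(c.sequence)
    run_excess = max(0, _longest_run(c.sequence) - p.max_homopolymer)
    return (
        -p.gc_weight * abs(gc - p.gc_target)
        - p.homopolymer_weight * run_excess
        - p.position_weight * (c.distance_to_3prime / window)
    )


# ---------------------------------------------------------------------------
# probe selection


def design_probes(
    genes,
    masks: dict[str, MaskedSequence] | None = None,
    sp: ScoringParams | None = None,
    window: int = WINDOW_3PRIME,
    probe_len: int = PROBE_LENGTH,
    vectors=(),
) -> tuple[list[ProbeRecord], DesignAccounting]:
    """Select one top-scoring probe per gene with a full exclusion ledger.

    Status precedence per gene: ``too_short`` (representative shorter than the
    probe), then ``masked`` (no candidate survives enumeration), then
    ``design_fail`` (no candidate reaches the score floor); otherwise the
    top-scoring candidate is selected (ties break to the smallest start).
    ``duplicate`` is assigned afterwards, in gene_id order, to any gene whose
    selected 60-mer is identical to an earlier gene's; the first keeper is
    retained.
    """
    sp = sp or ScoringParams()
    genes = sorted(genes, key=lambda g: g.gene_id)
    records: list[ProbeRecord] = []
    for idx, gene in enumerate(genes, start=1):
        rep = gene.representative
        probe_id = f"CP{idx:06d}"
        rec = ProbeRecord(probe_id, gene.gene_id, rep.transcript_id, "", -1, "design_fail")
        if rep.length < probe_len:
            rec.status = "too_short"
            records.append(rec)
            continue
        ms = (masks or {}).get(gene.gene_id) or mask_sequence(rep.sequence, vectors)
        cands = enumerate_candidates(ms, window=window, probe_len=probe_len)
        if not cands:
            rec.status = "masked"
            records.append(rec)
            continue
        best, best_score = None, None
        for c in cands:  # enumeration order == ascending start, so first win
            s = score_candidate(c, sp, window=window)
            if best_score is None or s > best_score:
                best, best_score = c, s
        if best_score < sp.score_floor:
            rec.status = "design_fail"
            records.append(rec)
            continue
        rec.status = "designed"
        rec.sequence = best.sequence
        rec.start = best.start
        rec.score = best_score
        records.append(rec)

    seen: dict[str, str] = {}
    for rec in records:
        if rec.status != "designed":
            continue
        if rec.sequence in seen:
            rec.status = "duplicate"
            rec.sequence = ""
            rec.start = -1
        else:
            seen[rec.sequence] = rec.probe_id
    return records, design_accounting(records)


def design_accounting(probes) -> DesignAccounting:
    probes = list(probes)
    counts = {s: 0 for s in _STATUSES}
    for p in probes:
        if p.status not in counts:
            raise ValueError(f"unknown status {p.status!r}")
        counts[p.status] += 1
    return DesignAccounting(
        submitted=len(probes),
        designed=counts["designed"],
        too_short=counts["too_short"],
        duplicate=counts["duplicate"],
        masked=counts["masked"],
        design_fail=counts["design_fail"],
    )


# ---------------------------------------------------------------------------
# cross-hybridization screening


def cross_hyb_screen(
    probes: list[ProbeRecord], ts: TranscriptSet, xp: XHybParams | None = None
) -> list[ProbeRecord]:
    """Flag probes with cross-hybridization potential.

    A probe is flagged iff, against any transcript of a *different* gene, it
    has (a) an exact contiguous match of at least ``flag_exact_run`` nt, or
    (b) at least ``flag_identity`` matching positions in the best ungapped
    probe-length alignment. Same-gene isoforms never trigger flags. Probes
    are sense-strand copies of their target transcript, so the screen
    compares probe vs transcript sense sequence directly.

    Rule (a) is tested by shared ``flag_exact_run``-mer lookup; rule (b) is
    evaluated exactly on every diagonal (vectorized sliding window) because
    at the default identity threshold (45/60, i.e. up to 15 mismatches) no
    lossless seed longer than 3 nt exists, so a seeded heuristic would miss
    genuine near-threshold paralog hits. ``seed_length`` is retained as the
    granularity of the shared-k-mer prescan used to order candidate
    transcripts; it cannot cause misses.
    """
    xp = xp or XHybParams()
    run_k = xp.flag_exact_run
    tx: list[tuple[str, str, np.ndarray, set[str]]] = []  # id, gene, encoded, run-kmers
    pad = PROBE_LENGTH - 1
    for rec in ts:
        enc = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
        padded = np.zeros(rec.length + 2 * pad, dtype=np.uint8)
        padded[pad : pad + rec.length] = enc
        windows = sliding_window_view(padded, PROBE_LENGTH) if rec.length + pad >= PROBE_LENGTH else None
        runmers = {
            rec.sequence[i : i + run_k] for i in range(rec.length - run_k + 1)
        }
        tx.append((rec.transcript_id, rec.gene_id, windows, runmers))

    for probe in probes:
        if probe.status != "designed":
            continue
        pv = np.frombuffer(probe.sequence.encode("ascii"), dtype=np.uint8)
        probe_runmers = {
            probe.sequence[i : i + run_k] for i in range(PROBE_LENGTH - run_k + 1)
        }
        flagged = False
        for tid, gene, windows, runmers in tx:
            if gene == probe.gene_id:
                continue
            if probe_runmers & runmers:
                flagged = True
                break
            if windows is not None and int((windows == pv).sum(axis=1).max()) >= xp.flag_identity:
                flagged = True
                break
        probe.xhyb_flag = flagged
    return probes


def alignment_stats(probe: str, transcript: str, offset: int) -> tuple[int, int]:
    """Matches and longest exact run of ``probe`` laid on ``transcript`` at
    diagonal ``offset``; probe positions falling off the transcript count as
    mismatches."""
    matches = 0
    run = best_run = 0
    n = len(transcript)
    for j, base in enumerate(probe):
        t = offset + j
        if 0 <= t < n and transcript[t] == base:
            matches += 1
            run += 1
            best_run = max(best_run, run)
        else:
            run = 0
    return matches, best_run
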