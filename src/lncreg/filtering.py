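"""The lncRNA filtering cascade.

Two stages: (1) annotate known lncRNAs by local-alignment similarity against
a reference lncRNA set (identity > 90%, E-value < 1e-10); (2) structural
filters on the remaining candidates -- drop annotated protein-coding
transcripts, transcripts with summed raw counts <= 10 over all samples,
spliced length <= 200 nt, or a single exon. The retained set is
order-independent; the recorded removal reason is the first failing filter
in cascade order (protein_coding -> expression -> length -> exons).

The similarity engine is an internal seed-and-extend search: exact k-mer
seeds (k = 11) pre-select candidate reference sequences, which are then
aligned with an optimal local (Smith-Waterman) alignment at match +2 /
mismatch -3, affine gaps 5/2; E-values follow Karlin-Altschul
E = K * m * n * exp(-lambda * S) with the bundled ungapped parameters for
these scores and n = total reference length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align

from ._tables import KA_K, KA_LAMBDA
from .core import CountMatrix, TranscriptModel, ValidationError

SEED_K = 11
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -3, 5, 2

CASCADE_ORDER = ("annotated_protein_coding", "low_expression", "too_short", "mono_exonic")


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float

    def __post_init__(self):
        if not 0 <= self.percent_identity <= 100:
            raise ValidationError("percent identity outside [0, 100]")
        if not math.isfinite(self.e_value) or self.e_value < 0:
            raise ValidationError("E-value must be finite and >= 0")


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = MATCH
    al.mismatch_score = MISMATCH
    al.open_gap_score = -GAP_OPEN
    al.extend_gap_score = -GAP_EXTEND
    return al


def _alignment_identity(alignment) -> tuple[float, int]:
    """Percent identity over the local alignment length (gaps count)."""
    a, b = alignment[0], alignment[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    length = len(a)
    if length == 0:
        return 0.0, 0
    return 100.0 * matches / length, length


def karlin_altschul_evalue(score: float, query_len: int, database_len: int) -> float:
    """E = K * m * n * exp(-lambda * S), clipped to avoid underflow to exact 0."""
    log_e = math.log(KA_K * max(query_len, 1) * max(database_len, 1)) - KA_LAMBDA * score
    return math.exp(max(log_e, -745.0))


def similarity_search(
    queries: Mapping[str, str],
    references: Mapping[str, str],
    seed_k: int = SEED_K,
) -> list[SimilarityHit]:
    """Best local-alignment hit per query against the reference set.

    A reference is only aligned when it shares at least one exact ``seed_k``-mer
    with the query (seeding); queries with no seeded reference get no hit.
    """
    if not references:
        raise ValidationError("reference set is empty")
    index: dict[str, set[str]] = {}
    for rid, rseq in references.items():
        for i in range(len(rseq) - seed_k + 1):
            index.setdefault(rseq[i : i + seed_k], set()).add(rid)
    database_len = sum(len(s) for s in references.values())
    aligner = _aligner()

    hits = []
    for qid, qseq in queries.items():
        if not qseq:
            raise ValidationError(f"empty sequence for query {qid}")
        candidates: set[str] = set()
        for i in range(len(qseq) - seed_k + 1):
            candidates |= index.get(qseq[i : i + seed_k], set())
        best = None
        for rid in sorted(candidates):
            alns = aligner.align(qseq, references[rid])
            if len(alns) == 0:
                continue
            aln = alns[0]
            score = aln.score
            if best is None or score > best[0]:
                best = (score, rid, aln)
        if best is None:
            continue
        score, rid, aln = best
        identity, length = _alignment_identity(aln)
        bits = (KA_LAMBDA * score - math.log(KA_K)) / math.log(2)
        hits.append(
            SimilarityHit(
                query_id=qid,
                subject_id=rid,
                percent_identity=identity,
                alignment_length=length,
                e_value=karlin_altschul_evalue(score, len(qseq), database_len),
                bit_score=bits,
            )
        )
    return hits


def annotate_known_lncrnas(
    transcripts: Sequence[TranscriptModel],
    reference_lncrnas: Mapping[str, str],
    identity_threshold: float = 90.0,
    evalue_threshold: float = 1e-10,
) -> tuple[list[TranscriptModel], list[TranscriptModel], list[SimilarityHit]]:
    """Partition transcripts into (known lncRNAs, candidates) by similarity.

    A transcript is *known* iff its best reference hit has percent identity
    strictly above ``identity_threshold`` and E-value below
    ``evalue_threshold``. Known transcripts get biotype ``known_lncRNA``.
    """
    for t in transcripts:
        if not t.sequence:
            raise ValidationError(f"{t.transcript_id}: transcript has no sequence")
    hits = similarity_search({t.transcript_id: t.sequence for t in transcripts},
                             reference_lncrnas)
    best = {h.query_id: h for h in hits}
    known, candidates = [], []
    for t in transcripts:
        h = best.get(t.transcript_id)
        if h and h.percent_identity > identity_threshold and h.e_value < evalue_threshold:
            t.biotype = "known_lncRNA"
            known.append(t)
        else:
            candidates.append(t)
    return known, candidates, hits


@dataclass
class FilterReport:
    """Outcome of the structural filter cascade."""

    status: dict[str, str]          # transcript_id -> retained | removed
    reason: dict[str, str]          # removed transcript_id -> first failing filter
    stage_counts: list[tuple[str, int]]  # (stage, surviving count), monotone

    @property
    def retained(self) -> list[str]:
        return [t for t, s in self.status.items() if s == "retained"]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "transcript_id": list(self.status),
                "status": [self.status[t] for t in self.status],
                "reason": [self.reason.get(t, "") for t in self.status],
            }
        )


def apply_structural_filters(
    transcripts: Sequence[TranscriptModel],
    counts: CountMatrix | None,
    min_total_counts: int = 10,
    min_length: int = 200,
    min_exons: int = 2,
    counts_by_transcript: Mapping[str, float] | None = None,
) -> FilterReport:
    """Run the structural filter cascade and record per-transcript outcomes.

    Retained iff biotype != protein_coding AND summed counts > ``min_total_counts``
    AND spliced length > ``min_length`` AND exon count >= ``min_exons``
    (strict boundaries: exactly 200 nt or exactly 10 counts is removed).
    ``counts_by_transcript`` overrides the count lookup (e.g. when counts are
    kept at gene level); a transcript with no count row counts as zero.
    """
    if counts_by_transcript is None:
        counts_by_transcript = {}
        if counts is not None:
            totals = counts.values.sum(axis=1)
            counts_by_transcript = {f: float(totals[f]) for f in counts.feature_ids}

    status: dict[str, str] = {}
    reason: dict[str, str] = {}
    checks = [
        ("annotated_protein_coding", lambda t: t.biotype == "protein_coding"),
        ("low_expression", lambda t: counts_by_transcript.get(t.transcript_id, 0.0)
                                     <= min_total_counts),
        ("too_short", lambda t: t.spliced_length <= min_length),
        ("mono_exonic", lambda t: t.exon_count < min_exons),
    ]
    survivors = list(transcripts)
    stage_counts = [("input", len(survivors))]
    failed: dict[str, str] = {}
    for name, fails in checks:
        next_surv = []
        for t in survivors:
            if fails(t):
                failed[t.transcript_id] = name
            else:
                next_surv.append(t)
        survivors = next_surv
        stage_counts.append((name, len(survivors)))
    for t in transcripts:
        if t.transcript_id in failed:
            status[t.transcript_id] = "removed"
            reason[t.transcript_id] = failed[t.transcript_id]
        else:
            status[t.transcript_id] = "retained"
    return FilterReport(status=status, reason=reason, stage_counts=stage_counts)
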