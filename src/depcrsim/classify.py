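"""From merged reads to the primer x template observation matrix.

The classification rule is deliberately strict: a read is counted only if
its primer region matches a known primer *exactly* and its recognition
window matches a known recognition sequence *exactly* (no error
tolerance).  Because recognition sequences are designed with pairwise
Hamming distance >= 4, an exact match is unambiguous.  Two primer-matching
modes are provided: ``full_primer`` compares all 20 primer bases,
``variant_positions`` compares only the three variant bases (plus the
recognition window in both modes).
"""

from __future__ import annotations

import json
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .design import (
    InteractionSpace,
    PoolSpec,
    PRIMER_LENGTH,
    RECOGNITION_OFFSET,
    VariantSpec,
)
from .errors import InputError, PipelineError
from .reads import ReadRecord, read_fastq  # noqa: F401  (re-exported I/O surface)

ASSIGNMENT_STATUSES = (
    "assigned",
    "unassigned_primer",
    "unassigned_recognition",
    "filtered_quality",
    "excluded_not_in_design",
)

CLASSIFY_MODES = ("full_primer", "variant_positions")


@dataclass(frozen=True)
class Assignment:
    """Outcome of classifying one read."""

    read_id: str
    status: str
    primer_id: Optional[str] = None
    template_id: Optional[str] = None
    replicate_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in ASSIGNMENT_STATUSES:
            raise InputError(f"unknown assignment status {self.status!r}")
        both = self.primer_id is not None and self.template_id is not None
        if (self.status == "assigned") != both:
            raise InputError("assigned status requires exactly both ids present")


@dataclass(frozen=True)
class MappingIndex:
    """Exact-match lookup tables derived from an interaction space or mapping TSV."""

    primer_by_core: dict[str, str]
    primer_by_triple: dict[tuple[str, ...], str]
    template_by_recognition: dict[str, str]
    n_mismatches: dict[tuple[str, str], int]
    recognition_offset: int = RECOGNITION_OFFSET
    recognition_length: int = 12
    primer_length: int = PRIMER_LENGTH
    spec: VariantSpec = VariantSpec()

    @classmethod
    def from_space(cls, space: InteractionSpace) -> "MappingIndex":
        return cls(
            primer_by_core=dict(space.primer_by_core),
            primer_by_triple=dict(space.primer_by_triple),
            template_by_recognition=dict(space.template_by_recognition),
            n_mismatches={k: v.n_mismatches for k, v in space.profiles.items()},
            recognition_offset=space.recognition_offset,
            recognition_length=space.recognition_length,
            primer_length=len(space.primers[0].core),
            spec=space.spec,
        )

    @classmethod
    def from_mapping_tsv(
        cls,
        path,
        recognition_offset: int = RECOGNITION_OFFSET,
        spec: VariantSpec = VariantSpec(),
    ) -> "MappingIndex":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"primer_id", "template_id", "primer_core", "recognition_seq", "n_mismatches"}
        missing = required - set(df.columns)
        if missing:
            raise InputError(f"mapping file lacks columns: {sorted(missing)}")
        cores = {r.primer_core: r.primer_id for r in df.itertuples()}
        recs = {r.recognition_seq: r.template_id for r in df.itertuples()}
        plen = len(next(iter(cores)))
        triples = {spec.triple_of(core): pid for core, pid in cores.items()}
        return cls(
            primer_by_core=cores,
            primer_by_triple=triples,
            template_by_recognition=recs,
            n_mismatches={
                (r.primer_id, r.template_id): int(r.n_mismatches) for r in df.itertuples()
            },
            recognition_offset=recognition_offset,
            recognition_length=len(next(iter(recs))),
            primer_length=plen,
            spec=spec,
        )

    @property
    def recognition_slice(self) -> slice:
        lo = self.recognition_offset - 1
        return slice(lo, lo + self.recognition_length)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self.n_mismatches)


def _as_index(space_or_index: Union[InteractionSpace, MappingIndex]) -> MappingIndex:
    if isinstance(space_or_index, MappingIndex):
        return space_or_index
    return MappingIndex.from_space(space_or_index)


# ---------------------------------------------------------------------------
# Pair merging and quality filtering
# ---------------------------------------------------------------------------

def merge_pairs(
    r1_reads: Iterable[ReadRecord],
    r2_reads: Iterable[ReadRecord],
    min_overlap: int = 12,
    max_overlap_mismatch_fraction: float = 0.25,
) -> tuple[list[ReadRecord], Counter]:
    """Merge read pairs by their best gap-free overlap.

    R2 is reverse-complemented; all overlap lengths from ``min_overlap`` up
    are scored as matches minus mismatches, and the best-scoring overlap
    whose mismatch fraction is acceptable wins (ties go to the longer
    overlap).  Within the overlap the higher-quality call wins at
    disagreeing bases and the higher quality is kept at agreeing bases.
    Unmergeable pairs are dropped and counted.
    """
    merged: list[ReadRecord] = []
    stats: Counter = Counter()
    for r1, r2 in zip(r1_reads, r2_reads, strict=True):
        if r1.read_id != r2.read_id:
            raise InputError(f"unpaired reads: {r1.read_id!r} vs {r2.read_id!r}")
        rc2 = r2.reverse_complement()
        a, qa = r1.sequence, r1.qualities
        b, qb = rc2.sequence, rc2.qualities
        best = None  # (score, overlap_len)
        for L in range(min_overlap, min(len(a), len(b)) + 1):
            mism = sum(x != y for x, y in zip(a[-L:], b[:L]))
            if mism / L > max_overlap_mismatch_fraction:
                continue
            score = (L - mism) - mism
            if best is None or (score, L) > best:
                best = (score, L)
        if best is None:
            stats["unmerged_no_overlap"] += 1
            continue
        L = best[1]
        head, qhead = a[:-L], qa[:-L]
        tail, qtail = b[L:], qb[L:]
        ov_seq, ov_q = [], []
        for x, qx, y, qy in zip(a[-L:], qa[-L:], b[:L], qb[:L]):
            if x == y:
                ov_seq.append(x)
                ov_q.append(max(qx, qy))
            elif qy > qx:
                ov_seq.append(y)
                ov_q.append(qy)
            else:
                ov_seq.append(x)
                ov_q.append(qx)
        merged.append(
            ReadRecord(
                r1.read_id,
                head + "".join(ov_seq) + tail,
                tuple(qhead) + tuple(ov_q) + tuple(qtail),
                r1.replicate_id,
                r1.description,
            )
        )
        stats["merged"] += 1
    return merged, stats


def quality_filter(
    reads: Iterable[ReadRecord], min_mean_quality: float = 20.0
) -> tuple[list[ReadRecord], Counter]:
    """Retain reads whose mean Phred quality is >= threshold (inclusive)."""
    kept: list[ReadRecord] = []
    stats: Counter = Counter()
    for r in reads:
        if r.mean_quality >= min_mean_quality:
            kept.append(r)
            stats["retained"] += 1
        else:
            stats["filtered_quality"] += 1
    return kept, stats


# ---------------------------------------------------------------------------
# Exact-match classification
# ---------------------------------------------------------------------------

def classify_read(
    read: ReadRecord,
    space: Union[InteractionSpace, MappingIndex],
    mode: str = "full_primer",
    allowed_primers: Optional[Iterable[str]] = None,
    allowed_templates: Optional[Iterable[str]] = None,
) -> Assignment:
    """Assign one read to a (primer, template) pair by exact matching.

    The read must begin at the forward priming site.  Pairs whose primer or
    template is outside the experiment's design (the ``allowed_*`` sets)
    are reported as ``excluded_not_in_design``.
    """
    if mode not in CLASSIFY_MODES:
        raise InputError(f"unknown classification mode {mode!r}")
    idx = _as_index(space)
    rec_sl = idx.recognition_slice
    if len(read.sequence) < rec_sl.stop:
        return Assignment(read.read_id, "unassigned_recognition", replicate_id=read.replicate_id)
    if mode == "full_primer":
        pid = idx.primer_by_core.get(read.sequence[: idx.primer_length])
    else:
        triple = tuple(read.sequence[i] for i in idx.spec.indices(idx.primer_length))
        pid = idx.primer_by_triple.get(triple)
    if pid is None:
        return Assignment(read.read_id, "unassigned_primer", replicate_id=read.replicate_id)
    tid = idx.template_by_recognition.get(read.sequence[rec_sl])
    if tid is None:
        return Assignment(read.read_id, "unassigned_recognition", replicate_id=read.replicate_id)
    if allowed_primers is not None and pid not in set(allowed_primers):
        return Assignment(read.read_id, "excluded_not_in_design", replicate_id=read.replicate_id)
    if allowed_templates is not None and tid not in set(allowed_templates):
        return Assignment(read.read_id, "excluded_not_in_design", replicate_id=read.replicate_id)
    return Assignment(read.read_id, "assigned", pid, tid, read.replicate_id)


def classify_reads(
    reads: Iterable[ReadRecord],
    space: Union[InteractionSpace, MappingIndex],
    mode: str = "full_primer",
    allowed_primers: Optional[Iterable[str]] = None,
    allowed_templates: Optional[Iterable[str]] = None,
) -> list[Assignment]:
    idx = _as_index(space)
    ap = None if allowed_primers is None else set(allowed_primers)
    at = None if allowed_templates is None else set(allowed_templates)
    return [classify_read(r, idx, mode, ap, at) for r in reads]


# ---------------------------------------------------------------------------
# Matrix construction, rarefaction, margins
# ---------------------------------------------------------------------------

@dataclass
class InteractionMatrix:
    """Replicates x (primer, template) integer count matrix with metadata.

    ``counts`` has a two-level column MultiIndex (primer_id, template_id).
    ``status_counts`` is the per-replicate read-accounting sidecar (one
    column per assignment status).
    """

    counts: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    status_counts: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise InputError("interaction matrix values must be non-negative")

    def row_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def copy_with(self, counts: pd.DataFrame, **meta) -> "InteractionMatrix":
        return InteractionMatrix(counts, {**self.metadata, **meta}, self.status_counts)

    # -- serialization ----------------------------------------------------
    def to_tsv(self, path) -> None:
        df = self.counts.copy()
        df.columns = [f"{p}:{t}" for p, t in df.columns]
        df.index.name = "replicate"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, metadata: Optional[dict] = None) -> "InteractionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        cols = [tuple(c.split(":", 1)) for c in df.columns]
        df.columns = pd.MultiIndex.from_tuples(cols, names=["primer_id", "template_id"])
        return cls(df.astype(int), metadata or {})

    def to_biom_json(self, path, table_id: str = "depcrsim") -> None:
        """Minimal BIOM v1.0 (JSON, dense) serialization of the count table."""
        data = self.counts.to_numpy()
        doc = {
            "id": table_id,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "depcrsim",
            "date": "",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [data.shape[1], data.shape[0]],
            "rows": [
                {"id": f"{p}:{t}", "metadata": None} for p, t in self.counts.columns
            ],
            "columns": [{"id": str(r), "metadata": None} for r in self.counts.index],
            "data": data.T.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(doc, sort_keys=True))


def build_interaction_matrix(
    assignments: Iterable[Assignment],
    space: Union[InteractionSpace, MappingIndex],
    template_pool: Optional[PoolSpec] = None,
    primer_pool: Optional[PoolSpec] = None,
    metadata: Optional[dict] = None,
) -> InteractionMatrix:
    """Collate assigned reads into the observation matrix.

    Columns cover every design pair (primer pool x template pool when
    given, otherwise the full space), so structural zeros are explicit.
    The status sidecar accounts for every input read.
    """
    idx = _as_index(space)
    pids = list(primer_pool.members) if primer_pool else sorted({p for p, _ in idx.pairs()})
    tids = list(template_pool.members) if template_pool else sorted({t for _, t in idx.pairs()})
    columns = pd.MultiIndex.from_tuples(
        [(p, t) for p in pids for t in tids], names=["primer_id", "template_id"]
    )
    per_rep_status: dict[str, Counter] = {}
    per_rep_counts: dict[str, Counter] = {}
    for a in assignments:
        rep = a.replicate_id or "rep1"
        per_rep_status.setdefault(rep, Counter())[a.status] += 1
        if a.status == "assigned":
            per_rep_counts.setdefault(rep, Counter())[(a.primer_id, a.template_id)] += 1
    reps = sorted(per_rep_status)
    counts = pd.DataFrame(0, index=reps, columns=columns, dtype=int)
    for rep in reps:
        for pair, n in per_rep_counts.get(rep, Counter()).items():
            if pair in counts.columns:
                counts.loc[rep, pair] = n
            else:
                # assigned but outside the declared design: count as excluded
                per_rep_status[rep]["excluded_not_in_design"] += n
                per_rep_status[rep]["assigned"] -= n
    status = pd.DataFrame(
        [[per_rep_status[rep].get(s, 0) for s in ASSIGNMENT_STATUSES] for rep in reps],
        index=reps,
        columns=list(ASSIGNMENT_STATUSES),
    )
    return InteractionMatrix(counts, metadata or {}, status)


def rarefy(
    matrix: InteractionMatrix, depth: int = 7000, seed: Optional[int] = None
) -> InteractionMatrix:
    """Subsample each replicate row without replacement to exactly ``depth``.

    Rows whose total is below the depth are dropped and recorded in
    ``metadata['rarefaction_dropped']``.  Sampling is multivariate
    hypergeometric, deterministic per seed.
    """
    if depth < 1:
        raise PipelineError("rarefaction depth must be >= 1")
    totals = matrix.row_sums()
    keep = totals[totals >= depth].index
    dropped = sorted(set(matrix.counts.index) - set(keep))
    if len(keep) == 0:
        raise PipelineError(
            f"all replicates have fewer than {depth} assigned reads; cannot rarefy"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for rep in keep:
        row = matrix.counts.loc[rep].to_numpy().astype(np.int64)
        if row.sum() == depth:
            rows.append(row)
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    counts = pd.DataFrame(
        np.vstack(rows), index=list(keep), columns=matrix.counts.columns
    )
    return matrix.copy_with(
        counts, rarefaction_depth=depth, rarefaction_dropped=dropped
    )


def split_matrix(matrix: InteractionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Template and primer margins (sum over the other id).

    Returns ``(template_margin, primer_margin)``; each margin's row sums
    equal the source row sums.
    """
    template_margin = matrix.counts.T.groupby(level="template_id", sort=False).sum().T
    primer_margin = matrix.counts.T.groupby(level="primer_id", sort=False).sum().T
    return template_margin, primer_margin


def trim_linker(read: ReadRecord, linker: str) -> ReadRecord:
    """Strip a literal 5' linker prefix when present (for externally supplied reads)."""
    if linker and read.sequence.startswith(linker):
        n = len(linker)
        return ReadRecord(
            read.read_id, read.sequence[n:], read.qualities[n:],
            read.replicate_id, read.description,
        )
    return read
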