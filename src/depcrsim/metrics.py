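"""Quantitative metrics for primer utilization and template representation.

The central quantity is the Ideal Score (IS): the L1 distance between an
observed and an expected relative-abundance vector, in percent units,

    IS = sum_i |100 * o_i - 100 * e_i|,

ranging from 0 (observed equals expected) to 200 (disjoint supports).  It
is 200x the Bray-Curtis dissimilarity of the two proportion vectors.  The
Ideal Template Score (ITS) compares the observed template margin with the
input template pool proportions (higher = more distortion of the input
ratios); the Ideal Primer Score (IPS) compares primer utilization with the
input primer proportions (higher = more selective primer use).  The
expected vector is the input pool's proportions, which makes the score 0
for a run that reproduces even an uneven input staircase; a
uniform-expectation variant is available via ``expected="uniform"``.

The mismatch ratio summarizes one matrix row as (reads on mismatched
pairs) / (reads on perfect-match pairs): 0 = only perfect matches, 1 =
equal utilization, infinity = no perfect-match reads at all.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis
from scipy.stats import entropy as _entropy

from .classify import InteractionMatrix, MappingIndex, _as_index
from .design import InteractionSpace, PoolSpec
from .errors import MetricError
from .reads import ReadRecord

VectorLike = Union[pd.Series, Mapping[str, float], Sequence[float], np.ndarray]


def _as_series(v: VectorLike, name: str) -> pd.Series:
    s = pd.Series(v, dtype=float)
    if (s < 0).any():
        raise MetricError(f"{name} has negative entries")
    return s


def _align_proportions(
    observed: VectorLike, expected: VectorLike
) -> tuple[np.ndarray, np.ndarray]:
    o = _as_series(observed, "observed")
    e = _as_series(expected, "expected")
    labelled = isinstance(observed, (pd.Series, Mapping)) and isinstance(
        expected, (pd.Series, Mapping)
    )
    if labelled:
        labels = o.index.union(e.index)
        o = o.reindex(labels, fill_value=0.0)
        e = e.reindex(labels, fill_value=0.0)
    elif len(o) != len(e):
        raise MetricError("unlabelled vectors must have equal length")
    if o.sum() <= 0 or e.sum() <= 0:
        raise MetricError("cannot normalize an all-zero abundance vector")
    return (o / o.sum()).to_numpy(), (e / e.sum()).to_numpy()


def ideal_score(observed: VectorLike, expected: VectorLike) -> float:
    """L1 distance of percent relative abundances, in [0, 200].

    Inputs may be raw counts or proportions (normalized on entry); labelled
    inputs are aligned on the union of labels with missing features as 0.
    Symmetric in its arguments.
    """
    o, e = _align_proportions(observed, expected)
    return float(np.abs(100.0 * o - 100.0 * e).sum())


def _pool_expectation(
    margin_row: pd.Series, pool: PoolSpec, expected: str
) -> pd.Series:
    missing = set(margin_row.index) - set(pool.members)
    if missing:
        raise MetricError(
            f"margin features {sorted(missing)} not in pool {pool.pool_id!r}"
        )
    if expected == "pool":
        return pool.proportions
    if expected == "uniform":
        return pd.Series(1.0, index=list(pool.members)) / len(pool.members)
    raise MetricError(f"unknown expectation {expected!r}")


def ideal_template_score(
    template_margin_row: pd.Series, template_pool: PoolSpec, expected: str = "pool"
) -> float:
    """ITS: distortion of the input template ratios (0 = faithful, 200 = disjoint)."""
    return ideal_score(
        template_margin_row, _pool_expectation(template_margin_row, template_pool, expected)
    )


def ideal_primer_score(
    primer_margin_row: pd.Series, primer_pool: PoolSpec, expected: str = "pool"
) -> float:
    """IPS: selectivity of primer utilization relative to the input primer ratios."""
    return ideal_score(
        primer_margin_row, _pool_expectation(primer_margin_row, primer_pool, expected)
    )


def mismatch_ratio(
    row: pd.Series, space: Union[InteractionSpace, MappingIndex]
) -> float:
    """(reads on pairs with >= 1 mismatch) / (reads on perfect-match pairs).

    Returns ``math.inf`` when mismatched reads exist but no perfect-match
    reads do (serialized as "Inf"), and 0.0 when there are no mismatched
    reads.  Invariant under uniform scaling of the row.
    """
    idx = _as_index(space)
    total = float(row.sum())
    if len(row) == 0 or total <= 0:
        raise MetricError("mismatch ratio is undefined for an empty row")
    match = 0.0
    mismatch = 0.0
    for pair, n in row.items():
        if n == 0:
            continue
        try:
            nm = idx.n_mismatches[pair]
        except KeyError:
            raise MetricError(f"pair {pair} not present in the interaction space") from None
        if nm == 0:
            match += n
        else:
            mismatch += n
    if mismatch == 0:
        return 0.0
    if match == 0:
        return math.inf
    return mismatch / match


def format_ratio(value: float) -> str:
    """Serialize a mismatch ratio, using the 'Inf' sentinel."""
    return "Inf" if math.isinf(value) else f"{value:.6g}"


def bray_curtis(x: VectorLike, y: VectorLike) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) in [0, 1].

    Accepts counts or proportions; labelled inputs are aligned on the label
    union.  Note IS = 200 * BC when both inputs are proportion vectors.
    """
    xs = _as_series(x, "x")
    ys = _as_series(y, "y")
    if isinstance(x, (pd.Series, Mapping)) and isinstance(y, (pd.Series, Mapping)):
        labels = xs.index.union(ys.index)
        xs = xs.reindex(labels, fill_value=0.0)
        ys = ys.reindex(labels, fill_value=0.0)
    elif len(xs) != len(ys):
        raise MetricError("unlabelled vectors must have equal length")
    if xs.sum() + ys.sum() <= 0:
        raise MetricError("Bray-Curtis is undefined for two all-zero vectors")
    return float(_braycurtis(xs.to_numpy(), ys.to_numpy()))


def dissimilarity_matrix(margin: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between replicate rows."""
    reps = list(margin.index)
    n = len(reps)
    out = np.zeros((n, n))
    arr = margin.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _braycurtis(arr[i], arr[j])
    return pd.DataFrame(out, index=reps, columns=reps)


def mds_ordination(dissimilarity: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Classical (principal-coordinate) MDS embedding of a dissimilarity matrix.

    Axes are ordered by eigenvalue; each axis's sign is fixed so its first
    nonzero loading is positive.  For Euclidean-embeddable input the
    pairwise embedded distances reproduce the input.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise MetricError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise MetricError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise MetricError("dissimilarity matrix must have a zero diagonal")
    n = d.shape[0]
    # Gower double-centering of -0.5 * D^2, then spectral embedding
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = min(k, n)
    coords = np.zeros((n, k))
    for axis in range(k):
        lam = evals[axis]
        if lam > 1e-12:
            v = evecs[:, axis] * math.sqrt(lam)
            nz = np.flatnonzero(np.abs(v) > 1e-12)
            if nz.size and v[nz[0]] < 0:
                v = -v
            coords[:, axis] = v
    index = (
        dissimilarity.index
        if isinstance(dissimilarity, pd.DataFrame)
        else pd.RangeIndex(n)
    )
    return pd.DataFrame(coords, index=index, columns=[f"PCo{i + 1}" for i in range(k)])


def shannon_diversity(counts: VectorLike) -> float:
    """Shannon index H = -sum p_i ln p_i over nonzero proportions."""
    s = _as_series(counts, "counts")
    if len(s) == 0 or s.sum() <= 0:
        raise MetricError("Shannon diversity is undefined for all-zero input")
    return float(_entropy(s.to_numpy()))


def richness(counts: VectorLike) -> int:
    """Number of features with nonzero counts."""
    s = _as_series(counts, "counts")
    return int((s > 0).sum())


# ---------------------------------------------------------------------------
# Positional error profiling
# ---------------------------------------------------------------------------

DEFAULT_ERROR_WINDOWS: tuple[tuple[int, int], ...] = ((1, 20), (21, 40), (41, 100))


@dataclass
class ErrorProfile:
    """Per-position mismatch rates against truth references, plus window means."""

    per_position: pd.Series  # index: 1-based position
    windows: dict[tuple[int, int], float]


def error_profile(
    reads: Sequence[ReadRecord],
    references: Union[str, Mapping[str, str]],
    windows: Sequence[tuple[int, int]] = DEFAULT_ERROR_WINDOWS,
) -> ErrorProfile:
    """Mean per-base mismatch rate against gap-free truth references.

    ``references`` is either a single reference applied to every read or a
    read_id -> reference mapping.  Reads shorter than a window contribute
    only to the positions they cover.  Window bounds are 1-based inclusive.
    """
    if not reads:
        raise MetricError("error profile requires at least one read")
    max_pos = max(hi for _, hi in windows)
    mismatches = np.zeros(max_pos)
    coverage = np.zeros(max_pos)
    for r in reads:
        ref = references if isinstance(references, str) else references[r.read_id]
        span = min(len(r.sequence), len(ref), max_pos)
        for i in range(span):
            coverage[i] += 1
            if r.sequence[i] != ref[i]:
                mismatches[i] += 1
    with np.errstate(invalid="ignore"):
        rate = np.where(coverage > 0, mismatches / np.maximum(coverage, 1), np.nan)
    per_pos = pd.Series(rate, index=pd.RangeIndex(1, max_pos + 1, name="position"))
    win = {}
    for lo, hi in windows:
        vals = per_pos.loc[lo:hi].dropna()
        win[(lo, hi)] = float(vals.mean()) if len(vals) else float("nan")
    return ErrorProfile(per_pos, win)


# ---------------------------------------------------------------------------
# Per-replicate metric table
# ---------------------------------------------------------------------------

def replicate_metrics(
    matrix: InteractionMatrix,
    space: Union[InteractionSpace, MappingIndex],
    template_pool: PoolSpec,
    primer_pool: PoolSpec,
) -> pd.DataFrame:
    """Tidy per-replicate table of ITS, IPS and mismatch ratio."""
    from .classify import split_matrix

    template_margin, primer_margin = split_matrix(matrix)
    rows = []
    for rep in matrix.counts.index:
        rows.append(
            {
                "replicate": rep,
                "its": ideal_template_score(template_margin.loc[rep], template_pool),
                "ips": ideal_primer_score(primer_margin.loc[rep], primer_pool),
                "mismatch_ratio": mismatch_ratio(matrix.counts.loc[rep], space),
            }
        )
    return pd.DataFrame(rows).set_index("replicate")
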