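"""Stochastic models of the two amplification regimes.

Two regimes are simulated over one interaction space:

* **DePCR (deconstructed PCR)** -- two cycles of linear copying in which
  primers anneal to the *original* templates only.  The primer that anneals
  becomes part of the copied molecule, and subsequent exponential
  amplification (driven by linker-targeting primers) preserves that record,
  so every sequenced read reports the true primer-template annealing event.

* **Standard PCR** -- the same first two cycles, followed by 26 further
  cycles in which primers anneal to amplicon *copies*.  A copy's forward
  priming site carries the sequence of whichever primer founded its
  lineage's most recent forward strand, so primer usage progressively
  "scrambles" toward the input primer proportions and the sequenced primer
  region no longer reports annealing to source templates.

Annealing preference is encoded by a multiplicative per-mismatch penalty
model calibrated, by position and temperature, from head-to-head
mismatch-ratio measurements (a single mismatch with penalty p yields an
expected mismatch:match ratio of exactly p in equimolar competition).

Amplification dynamics are propagated as expected molecule counts per
(origin template, priming-site state) class; sequencing is a multinomial
draw of reads from the final class distribution, one independent stream
per replicate.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .design import (
    InteractionSpace,
    MismatchProfile,
    NUCLEOTIDES,
    PoolSpec,
    PRIMER_LENGTH,
    triple_mismatch_profile,
)
from .errors import ModelError, SimulationError
from .reads import ReadRecord, write_fastq

# Default positional penalties (annealing efficiency relative to a perfect
# match), calibrated from equimolar head-to-head mismatch ratios at the two
# study temperatures: the midpoint of the measured range per position, with
# the middle-position C-A pairing pinned to the low end of its range (it was
# the clear outlier among middle-position pairings).
DEFAULT_POSITION_PENALTIES: dict[tuple[str, float], float] = {
    ("5'", 45.0): 0.65,
    ("5'", 55.0): 0.21,
    ("M", 45.0): 0.54,
    ("M", 55.0): 0.155,
    ("3'", 45.0): 0.13,
    ("3'", 55.0): 0.01,
}

DEFAULT_PAIRING_PENALTIES: dict[tuple[str, float, str], float] = {
    ("M", 45.0, "C-A"): 0.36,
    ("M", 55.0, "C-A"): 0.10,
}


@dataclass(frozen=True)
class EfficiencyModel:
    """Per-mismatch annealing penalties, multiplicative over mismatches.

    ``pairing_penalties`` maps (position label, temperature, "P-T" pairing)
    to a penalty in (0, 1]; anything not listed falls back to the positional
    default for that (label, temperature).  A perfect match always has
    efficiency 1.
    """

    position_penalties: Mapping[tuple[str, float], float] = field(
        default_factory=lambda: dict(DEFAULT_POSITION_PENALTIES)
    )
    pairing_penalties: Mapping[tuple[str, float, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PAIRING_PENALTIES)
    )

    def __post_init__(self) -> None:
        for v in [*self.position_penalties.values(), *self.pairing_penalties.values()]:
            if not (0.0 < v <= 1.0):
                raise ModelError(f"penalties must lie in (0, 1], got {v}")

    @classmethod
    def default(cls) -> "EfficiencyModel":
        return cls()

    @classmethod
    def neutral(cls) -> "EfficiencyModel":
        """All penalties 1: mismatches do not affect annealing."""
        labels = {k[0] for k in DEFAULT_POSITION_PENALTIES}
        temps = {k[1] for k in DEFAULT_POSITION_PENALTIES}
        return cls({(l, t): 1.0 for l in labels for t in temps}, {})

    def temperatures(self) -> set[float]:
        return {t for (_, t) in self.position_penalties}

    def penalty(self, label: str, temperature: float, pairing: Optional[str] = None) -> float:
        t = float(temperature)
        if pairing is not None:
            key = (label, t, pairing)
            if key in self.pairing_penalties:
                return self.pairing_penalties[key]
        try:
            return self.position_penalties[(label, t)]
        except KeyError:
            raise ModelError(
                f"no penalty for position {label!r} at {temperature} degC and no "
                "interpolation rule; add it to the model"
            ) from None

    def efficiency(self, profile: MismatchProfile, temperature: float) -> float:
        """Product of per-mismatch penalties; 1.0 for a perfect match."""
        eff = 1.0
        for entry in profile.entries:
            eff *= self.penalty(entry.position_label, temperature, entry.pairing)
        return eff


def annealing_efficiency(
    profile: MismatchProfile, temperature: float, model: EfficiencyModel
) -> float:
    """Annealing efficiency of one primer-template profile (module-level alias)."""
    return model.efficiency(profile, temperature)


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one simulated amplification + sequencing run."""

    method: str = "depcr"  # "depcr" | "standard"
    temperature: float = 45.0
    cycles: Optional[int] = None  # default: 2 (depcr) / 28 (standard)
    n_template_molecules: int = 100_000  # nominal input scale (dynamics are scale-free)
    scrambling_mode: str = "neutral"  # "neutral" | "penalized" primer->copy annealing
    per_base_error_rate: float = 0.0
    reads_per_replicate: int = 20_000
    n_replicates: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("depcr", "standard"):
            raise SimulationError(f"unknown method {self.method!r}")
        if self.scrambling_mode not in ("neutral", "penalized"):
            raise SimulationError(f"unknown scrambling_mode {self.scrambling_mode!r}")
        if self.effective_cycles < 1:
            raise SimulationError("cycles must be >= 1")
        if not (0.0 <= self.per_base_error_rate <= 1.0):
            raise SimulationError("per_base_error_rate must lie in [0, 1]")
        if self.reads_per_replicate < 1 or self.n_replicates < 1:
            raise SimulationError("reads_per_replicate and n_replicates must be >= 1")

    @property
    def effective_cycles(self) -> int:
        if self.cycles is not None:
            return self.cycles
        return 2 if self.method == "depcr" else 28

    def replicate_ids(self) -> list[str]:
        return [f"rep{i + 1}" for i in range(self.n_replicates)]

    def replicate_rng(self, replicate_index: int, stream: int = 0) -> np.random.Generator:
        """Independent, reproducible stream per (seed, replicate, purpose)."""
        return np.random.default_rng([self.seed, replicate_index, stream])


@dataclass
class SimulationResult:
    """Per-replicate counts plus the analytic quantities behind them.

    ``counts`` is a replicates x (primer_id, template_id) integer frame.
    ``probabilities`` is the expected read distribution over the same pairs.
    For standard PCR, ``tv_trajectory`` records the total-variation distance
    between the cycle-by-cycle primer-usage distribution and the input
    primer proportions.
    """

    counts: pd.DataFrame
    probabilities: pd.Series
    config: RunConfig
    tv_trajectory: Optional[list[float]] = None

    def replicate_ids(self) -> list[str]:
        return list(self.counts.index)


def _pair_index(primer_ids: Sequence[str], template_ids: Sequence[str]) -> pd.MultiIndex:
    return pd.MultiIndex.from_tuples(
        [(p, t) for p in primer_ids for t in template_ids],
        names=["primer_id", "template_id"],
    )


def _template_annealing_weights(
    template_pool: PoolSpec,
    primer_pool: PoolSpec,
    temperature: float,
    space: InteractionSpace,
    model: EfficiencyModel,
) -> pd.DataFrame:
    """Unnormalized copy rates w[t, p] = template_prop * primer_prop * efficiency."""
    for tid in template_pool.members:
        if tid not in space.template_by_id:
            raise SimulationError(f"template {tid} not in interaction space")
    for pid in primer_pool.members:
        if pid not in space.primer_by_id:
            raise SimulationError(f"primer {pid} not in interaction space")
    tprop = template_pool.proportions
    pprop = primer_pool.proportions
    w = pd.DataFrame(0.0, index=list(template_pool.members), columns=list(primer_pool.members))
    for tid in w.index:
        for pid in w.columns:
            eff = model.efficiency(space.profiles[(pid, tid)], temperature)
            w.loc[tid, pid] = tprop[tid] * pprop[pid] * eff
    if w.to_numpy().sum() <= 0.0:
        raise SimulationError(
            "all annealing efficiencies are zero: no primer can copy any template"
        )
    return w


def depcr_event_probabilities(
    template_pool: PoolSpec,
    primer_pool: PoolSpec,
    temperature: float,
    space: InteractionSpace,
    model: EfficiencyModel,
) -> pd.Series:
    """Probability of each (primer, template) linear-copy event under DePCR.

    Each copy event pairs one template molecule with one primer with
    probability proportional to template proportion x primer proportion x
    annealing efficiency.  This is the closed form the sampler draws from.
    """
    w = _template_annealing_weights(template_pool, primer_pool, temperature, space, model)
    idx = _pair_index(list(primer_pool.members), list(template_pool.members))
    p = pd.Series(
        [w.loc[t, pr] for (pr, t) in idx], index=idx, dtype=float
    )
    return p / p.sum()


def _sample_counts(
    probabilities: pd.Series, config: RunConfig, stream: int = 0
) -> pd.DataFrame:
    p = probabilities.to_numpy()
    p = p / p.sum()
    rows = []
    for r in range(config.n_replicates):
        rng = config.replicate_rng(r, stream=stream)
        rows.append(rng.multinomial(config.reads_per_replicate, p))
    return pd.DataFrame(
        np.vstack(rows), index=config.replicate_ids(), columns=probabilities.index
    )


def simulate_depcr(
    template_pool: PoolSpec,
    primer_pool: PoolSpec,
    temperature: float,
    config: RunConfig,
    space: InteractionSpace,
    model: Optional[EfficiencyModel] = None,
) -> SimulationResult:
    """Simulate DePCR linear-copy events and sequencing.

    The recorded (primer, template) pair is fixed at the copy event;
    exponential amplification of linker-tagged products and sequencing do
    not alter it (only downstream error injection can corrupt a read), so
    reads are drawn directly from the event distribution.
    """
    model = model or EfficiencyModel.default()
    cfg = replace(config, method="depcr", temperature=temperature)
    probs = depcr_event_probabilities(template_pool, primer_pool, temperature, space, model)
    counts = _sample_counts(probs, cfg)
    return SimulationResult(counts, probs, cfg)


def standard_pcr_class_dynamics(
    template_pool: PoolSpec,
    primer_pool: PoolSpec,
    temperature: float,
    config: RunConfig,
    space: InteractionSpace,
    model: Optional[EfficiencyModel] = None,
) -> tuple[pd.DataFrame, list[float]]:
    """Expected-value branching dynamics of standard PCR.

    Molecule classes are (origin template, priming-site state); the site
    state of a copy equals the variant triple of the primer that founded its
    lineage's most recent forward strand, so states are indexed by the pool
    primers.  Cycles 1-2 copy original templates with the DePCR annealing
    rule; from cycle 3 every copy is re-copied once per cycle by a primer
    drawn from the pool -- proportionally to primer concentration in
    ``neutral`` scrambling mode, additionally weighted by the primer-vs-site
    mismatch efficiency in ``penalized`` mode (where poorly primed site
    states also replicate more slowly).  Original templates keep
    contributing one linear copy generation per cycle.

    Returns the final class mass matrix M[template, site-primer] and the
    per-cycle total-variation distance between the copy site-state
    distribution and the input primer proportions.
    """
    model = model or EfficiencyModel.default()
    w_lin = _template_annealing_weights(template_pool, primer_pool, temperature, space, model)
    pprop = primer_pool.proportions.reindex(list(primer_pool.members))
    primers = list(primer_pool.members)
    k = len(primers)
    pmap = space.primer_by_id

    # transition U[s, p]: mass a copy in site-state s contributes to state p
    if config.scrambling_mode == "neutral":
        U = np.tile(pprop.to_numpy(), (k, 1))
    else:
        U = np.zeros((k, k))
        for i, sid in enumerate(primers):
            site = pmap[sid].variant_triple
            for j, pid in enumerate(primers):
                prof = triple_mismatch_profile(pmap[pid].variant_triple, site, space.spec)
                U[i, j] = pprop[pid] * model.efficiency(prof, temperature)
        if U.sum() <= 0.0:
            raise SimulationError("all primer-to-copy annealing efficiencies are zero")

    M = pd.DataFrame(0.0, index=list(template_pool.members), columns=primers)
    L = w_lin.to_numpy()  # linear copy increment from originals, per cycle
    tv = []
    target = pprop.to_numpy()
    for cycle in range(1, config.effective_cycles + 1):
        if cycle >= 3:
            M.loc[:, :] = M.to_numpy() + M.to_numpy() @ U
        M.loc[:, :] = M.to_numpy() + L
        usage = M.to_numpy().sum(axis=0)
        usage = usage / usage.sum()
        tv.append(0.5 * float(np.abs(usage - target).sum()))
    return M, tv


def simulate_standard_pcr(
    template_pool: PoolSpec,
    primer_pool: PoolSpec,
    temperature: float,
    config: RunConfig,
    space: InteractionSpace,
    model: Optional[EfficiencyModel] = None,
) -> SimulationResult:
    """Simulate standard PCR: exponential amplification, then read sampling.

    Final reads report (site-state primer, origin template): the primer
    region of a sequenced amplicon is whichever primer's sequence its
    lineage last acquired, not the primer that annealed to the original
    template.
    """
    cfg = replace(config, method="standard", temperature=temperature)
    M, tv = standard_pcr_class_dynamics(
        template_pool, primer_pool, temperature, cfg, space, model
    )
    idx = _pair_index(list(primer_pool.members), list(template_pool.members))
    mass = pd.Series([M.loc[t, pr] for (pr, t) in idx], index=idx, dtype=float)
    probs = mass / mass.sum()
    counts = _sample_counts(probs, cfg)
    return SimulationResult(counts, probs, cfg, tv_trajectory=tv)


def run_simulation(
    template_pool: PoolSpec,
    primer_pool: PoolSpec,
    config: RunConfig,
    space: InteractionSpace,
    model: Optional[EfficiencyModel] = None,
) -> SimulationResult:
    """Dispatch on ``config.method``."""
    fn = simulate_depcr if config.method == "depcr" else simulate_standard_pcr
    return fn(template_pool, primer_pool, config.temperature, config, space, model)


# ---------------------------------------------------------------------------
# Error injection and read emission
# ---------------------------------------------------------------------------

_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}
_BASE_ARRAY = np.array(list(NUCLEOTIDES))


def apply_errors(
    sequence: str,
    per_base_rate: float,
    rng: Union[int, np.random.Generator, None] = None,
) -> str:
    """Independent per-base substitution to a uniformly chosen different base."""
    if not (0.0 <= per_base_rate <= 1.0):
        raise SimulationError("per_base_rate must lie in [0, 1]")
    if per_base_rate == 0.0 or not sequence:
        return sequence
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    arr = np.array([_BASE_INDEX[b] for b in sequence], dtype=np.int64)
    hit = rng.random(arr.size) < per_base_rate
    # shift by 1..3 (mod 4) guarantees a different base, uniformly among the three
    arr[hit] = (arr[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return "".join(_BASE_ARRAY[arr])


@dataclass(frozen=True)
class QualityModel:
    """Two-tier synthetic quality string: high head, lower tail."""

    q_head: int = 38
    q_tail: int = 28
    tail_start: int = 201  # 1-based position where the lower tier begins

    def qualities(self, length: int) -> tuple[int, ...]:
        head = min(length, self.tail_start - 1)
        return (self.q_head,) * head + (self.q_tail,) * (length - head)


def amplicon_sequence(primer_core: str, template_sequence: str) -> str:
    """Merged-read layout: the primer region replaces the forward site."""
    return primer_core + template_sequence[len(primer_core):]


def synthesize_reads(
    counts_row: pd.Series,
    space: InteractionSpace,
    method: str,
    per_base_error_rate: float,
    rng: np.random.Generator,
    replicate_id: str,
    quality: QualityModel = QualityModel(),
    debug_truth: bool = False,
) -> list[ReadRecord]:
    """Merged reads for one replicate's (primer, template) counts.

    Reads begin at the forward priming site (linkers trimmed) and span the
    amplicon.  In DePCR the primer region is itself a polymerase copy, so
    errors may hit it; in standard PCR the first 20 bases are the synthetic
    oligonucleotide itself and are emitted error-free, while all downstream
    bases receive errors in both methods.
    """
    if method not in ("depcr", "standard"):
        raise SimulationError(f"unknown method {method!r}")
    tmap = space.template_by_id
    pmap = space.primer_by_id
    out: list[ReadRecord] = []
    serial = 0
    for (pid, tid), n in counts_row.items():
        n = int(n)
        if n == 0:
            continue
        base_seq = amplicon_sequence(pmap[pid].core, tmap[tid].sequence)
        quals = quality.qualities(len(base_seq))
        for _ in range(n):
            serial += 1
            if method == "depcr":
                seq = apply_errors(base_seq, per_base_error_rate, rng)
            else:
                tail = apply_errors(base_seq[PRIMER_LENGTH:], per_base_error_rate, rng)
                seq = base_seq[:PRIMER_LENGTH] + tail
            desc = f"truth={pid}:{tid}" if debug_truth else ""
            out.append(
                ReadRecord(f"{replicate_id}:{serial}", seq, quals, replicate_id, desc)
            )
    return out


def paired_reads(read: ReadRecord, read_length: int = 153) -> tuple[ReadRecord, ReadRecord]:
    """Split a merged read into an overlapping R1/R2 pair (R2 reverse-complemented)."""
    if len(read) < read_length:
        raise SimulationError(
            f"amplicon length {len(read)} shorter than read length {read_length}; "
            "paired emission would require adapter handling"
        )
    r1 = ReadRecord(
        read.read_id, read.sequence[:read_length], read.qualities[:read_length],
        read.replicate_id, read.description,
    )
    r2 = ReadRecord(
        read.read_id, read.sequence[-read_length:], read.qualities[-read_length:],
        read.replicate_id, read.description,
    ).reverse_complement()
    return r1, r2


def emit_reads(
    result: SimulationResult,
    space: InteractionSpace,
    out_dir: Optional[Union[str, Path]] = None,
    mode: str = "merged",
    read_length: int = 153,
    quality: QualityModel = QualityModel(),
    debug_truth: bool = False,
) -> Union[dict[str, list[ReadRecord]], dict[str, list[Path]]]:
    """Emit FASTQ reads per replicate.

    With ``out_dir`` set, writes ``<replicate>.fastq`` (merged mode) or
    ``<replicate>_R1.fastq`` / ``_R2.fastq`` (paired mode) and returns the
    paths; otherwise returns the in-memory reads keyed by replicate.
    """
    if mode not in ("merged", "paired"):
        raise SimulationError(f"unknown emission mode {mode!r}")
    cfg = result.config
    by_rep: dict[str, list[ReadRecord]] = {}
    for r, rep_id in enumerate(cfg.replicate_ids()):
        rng = cfg.replicate_rng(r, stream=1)  # error stream, separate from sampling
        by_rep[rep_id] = synthesize_reads(
            result.counts.loc[rep_id],
            space,
            cfg.method,
            cfg.per_base_error_rate,
            rng,
            rep_id,
            quality=quality,
            debug_truth=debug_truth,
        )
    if out_dir is None:
        if mode == "paired":
            return {
                rep: [paired_reads(rd, read_length) for rd in rds]
                for rep, rds in by_rep.items()
            }
        return by_rep
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, list[Path]] = {}
    for rep, rds in by_rep.items():
        if mode == "merged":
            p = out_dir / f"{rep}.fastq"
            write_fastq(rds, p)
            paths[rep] = [p]
        else:
            pairs = [paired_reads(rd, read_length) for rd in rds]
            p1 = out_dir / f"{rep}_R1.fastq"
            p2 = out_dir / f"{rep}_R2.fastq"
            write_fastq((a for a, _ in pairs), p1)
            write_fastq((b for _, b in pairs), p2)
            paths[rep] = [p1, p2]
    return paths
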