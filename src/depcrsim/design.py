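"""Synthetic primer/template design space for quantifying primer-template interactions.

This module constructs the combinatorial system used throughout the package:
a set of synthetic DNA templates that are identical except at three variant
positions inside the forward priming site and at a short internal
"recognition sequence" barcode, and the full set of primer variants over
those three positions.  Because each priming-site variant is linked to a
unique recognition sequence, a sequencing read reveals both which template
was copied (recognition window) and which primer sequence it carries
(first bases of the read), so every read can be assigned to one
primer x template interaction.

The default design has 10 templates (ST0..ST9) and 64 primers (V0..V63,
all 4^3 combinations at the variant positions), giving a 640-pair
interaction space.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DesignError

NUCLEOTIDES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: 5' linker ("common sequence") carried by forward primers.
CS1_LINKER = "ACACTGACGACATGGTTCTACA"
#: 5' linker carried by reverse primers.
CS2_LINKER = "TACGGTAGCAGAGACTTGGTCT"

#: Forward priming site of the reference template ST0 (variant bases C/T/A at
#: the -14/-8/-2 positions from the 3' end).
ST0_FORWARD_SITE = "GGACTACCAGGGTATCTAAT"

PRIMER_LENGTH = 20
RECOGNITION_LENGTH = 12
RECOGNITION_OFFSET = 99  # 1-based, counted from the first base of the forward site
DEFAULT_AMPLICON_LENGTH = 250
DEFAULT_DESIGN_SEED = 806


def complement(base: str) -> str:
    """Watson-Crick complement of a single base."""
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def _check_nucleotides(seq: str, what: str) -> None:
    bad = set(seq) - set(NUCLEOTIDES)
    if bad:
        raise DesignError(f"{what} contains non-ACGT characters: {sorted(bad)}")


@dataclass(frozen=True)
class VariantSpec:
    """Locations of the variable bases within the forward priming site.

    Offsets are counted from the 3' end of the primer (-1 is the terminal
    base), so the defaults (-14, -8, -2) put one variant near the 5' end,
    one in the middle and one adjacent to the 3' terminus; the matching
    labels are the conventional "5'", "M" and "3'" tags.
    """

    offsets_from_3prime: tuple[int, ...] = (-14, -8, -2)
    labels: tuple[str, ...] = ("5'", "M", "3'")
    alphabet: tuple[str, ...] = NUCLEOTIDES

    def __post_init__(self) -> None:
        offs = self.offsets_from_3prime
        if len(offs) != len(self.labels):
            raise DesignError("labels must be the same length as offsets")
        if any(o >= 0 for o in offs):
            raise DesignError("offsets are counted from the 3' end and must be negative")
        if any(b - a <= 0 for a, b in zip(offs, offs[1:])):
            raise DesignError("offsets must be strictly increasing toward the 3' end")

    @property
    def n_positions(self) -> int:
        return len(self.offsets_from_3prime)

    def indices(self, length: int = PRIMER_LENGTH) -> tuple[int, ...]:
        """0-based indices of the variant positions in a sequence of ``length``."""
        idx = tuple(length + o for o in self.offsets_from_3prime)
        if any(i < 0 or i >= length for i in idx):
            raise DesignError(
                f"variant offsets {self.offsets_from_3prime} do not fit in length {length}"
            )
        return idx

    def triple_of(self, core: str) -> tuple[str, ...]:
        """The bases of ``core`` at the variant positions."""
        return tuple(core[i] for i in self.indices(len(core)))

    def substitute(self, core: str, triple: Sequence[str]) -> str:
        chars = list(core)
        for i, b in zip(self.indices(len(core)), triple):
            chars[i] = b
        return "".join(chars)


@dataclass(frozen=True)
class PrimerRecord:
    """A forward primer: 20-base annealing core plus optional 5' linker."""

    primer_id: str
    core: str
    variant_triple: tuple[str, ...]
    linker: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.core) != PRIMER_LENGTH:
            raise DesignError(f"primer core must be {PRIMER_LENGTH} bases, got {len(self.core)}")
        _check_nucleotides(self.core, f"primer {self.primer_id}")

    @property
    def full_sequence(self) -> str:
        return (self.linker or "") + self.core


@dataclass(frozen=True)
class TemplateRecord:
    """A synthetic template.

    The stored sequence begins at the first base of the forward priming
    site (upstream flanks carry no information in this system) and ends at
    the last base of the constant reverse priming site.  ``recognition_offset``
    is 1-based, counted from the first base of the forward site.
    """

    template_id: str
    sequence: str
    variant_triple: tuple[str, ...]
    recognition_seq: str
    recognition_offset: int = RECOGNITION_OFFSET

    def __post_init__(self) -> None:
        _check_nucleotides(self.sequence, f"template {self.template_id}")
        lo = self.recognition_offset - 1
        hi = lo + len(self.recognition_seq)
        if hi > len(self.sequence):
            raise DesignError(
                f"recognition window [{self.recognition_offset}, {hi}] exceeds "
                f"template {self.template_id} length {len(self.sequence)}"
            )
        if self.sequence[lo:hi] != self.recognition_seq:
            raise DesignError(
                f"template {self.template_id}: recognition_seq does not match the "
                f"sequence at offset {self.recognition_offset}"
            )

    @property
    def forward_site(self) -> str:
        return self.sequence[:PRIMER_LENGTH]

    @property
    def reverse_site(self) -> str:
        return self.sequence[-PRIMER_LENGTH:]

    @property
    def recognition_slice(self) -> slice:
        lo = self.recognition_offset - 1
        return slice(lo, lo + len(self.recognition_seq))


@dataclass(frozen=True)
class MismatchEntry:
    """One primer-template mismatch at a variant position.

    ``template_base`` is the sense-strand base of the template (the one
    printed in the priming-site sequence).  The annealing pairing reported
    by :attr:`pairing` is primer base vs the antisense base the primer
    actually pairs with, i.e. the complement of the sense base.
    """

    position_label: str
    offset_from_3prime: int
    primer_base: str
    template_base: str

    @property
    def pairing(self) -> str:
        return f"{self.primer_base}-{complement(self.template_base)}"


@dataclass(frozen=True)
class MismatchProfile:
    """The set of variant-position mismatches of one primer-template pair."""

    entries: tuple[MismatchEntry, ...] = ()

    @property
    def n_mismatches(self) -> int:
        return len(self.entries)

    @property
    def is_perfect(self) -> bool:
        return not self.entries

    @property
    def positions(self) -> tuple[str, ...]:
        return tuple(e.position_label for e in self.entries)

    @property
    def pairings(self) -> tuple[str, ...]:
        return tuple(e.pairing for e in self.entries)


@dataclass(frozen=True)
class PoolSpec:
    """A named pool of templates or primers with relative concentrations."""

    pool_id: str
    members: tuple[str, ...]
    relative_concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise DesignError(f"pool {self.pool_id} has no members")
        if len(set(self.members)) != len(self.members):
            raise DesignError(f"pool {self.pool_id} has duplicate members")
        if len(self.relative_concentrations) != len(self.members):
            raise DesignError(f"pool {self.pool_id}: concentrations do not match members")
        if any(c <= 0 for c in self.relative_concentrations):
            raise DesignError(f"pool {self.pool_id} has non-positive concentrations")

    @classmethod
    def from_mapping(cls, pool_id: str, members: Mapping[str, float]) -> "PoolSpec":
        return cls(pool_id, tuple(members), tuple(float(v) for v in members.values()))

    @property
    def proportions(self) -> pd.Series:
        s = pd.Series(self.relative_concentrations, index=list(self.members), dtype=float)
        return s / s.sum()

    def __contains__(self, member: str) -> bool:
        return member in self.members


def enumerate_primer_variants(
    base_core: str,
    spec: VariantSpec = VariantSpec(),
    id_prefix: str = "V",
    linker: Optional[str] = None,
) -> list[PrimerRecord]:
    """All primer variants of ``base_core`` over the variant positions.

    One primer per element of ``alphabet^k`` (k = number of variant
    positions), enumerated row-major with positions ascending toward the
    3' end and bases in A<C<G<T order; ids are assigned in that order.
    The base core's own triple is among the variants.
    """
    _check_nucleotides(base_core, "base core")
    spec.indices(len(base_core))  # validates offsets against the core length
    primers = []
    for i, triple in enumerate(itertools.product(spec.alphabet, repeat=spec.n_positions)):
        core = spec.substitute(base_core, triple)
        primers.append(PrimerRecord(f"{id_prefix}{i}", core, tuple(triple), linker=linker))
    return primers


#: Single-mismatch substitutions defining primers V1..V9 against the V0/ST0
#: triple (C, T, A): V1-V3 vary the 5' position with primer bases G, T, A
#: (in that order); V4-V6 vary the middle position with bases A, C, G
#: (pairings A-A, C-A, G-A against the antisense A); V7-V9 vary the 3'
#: position with bases C, G, T (alphabetical).
CANONICAL_SINGLE_SUBSTITUTIONS: tuple[tuple[int, str], ...] = (
    (0, "G"), (0, "T"), (0, "A"),
    (1, "A"), (1, "C"), (1, "G"),
    (2, "C"), (2, "G"), (2, "T"),
)


def canonical_primer_set(
    base_core: str = ST0_FORWARD_SITE,
    spec: VariantSpec = VariantSpec(),
    linker: Optional[str] = CS1_LINKER,
) -> list[PrimerRecord]:
    """The 64-primer set with the study's id convention.

    V0 is the perfect match to the base core; V1..V9 are the nine single
    mismatches in the canonical order (see
    :data:`CANONICAL_SINGLE_SUBSTITUTIONS`); V10..V36 are the 27 double
    mismatches and V37..V63 the 27 triple mismatches, each group in
    row-major enumeration order.  This grouping makes "pool 27" exactly
    V10-V36.
    """
    base_triple = spec.triple_of(base_core)
    singles = []
    for pos, b in CANONICAL_SINGLE_SUBSTITUTIONS:
        t = list(base_triple)
        t[pos] = b
        singles.append(tuple(t))
    ordered = [tuple(base_triple)] + singles
    seen = set(ordered)
    for n_mm in (2, 3):
        for triple in itertools.product(spec.alphabet, repeat=spec.n_positions):
            d = sum(a != b for a, b in zip(triple, base_triple))
            if d == n_mm and triple not in seen:
                ordered.append(triple)
                seen.add(triple)
    return [
        PrimerRecord(f"V{i}", spec.substitute(base_core, t), t, linker=linker)
        for i, t in enumerate(ordered)
    ]


def generate_recognition_set(
    n: int,
    length: int = RECOGNITION_LENGTH,
    min_hamming: int = 4,
    seed: Optional[int] = None,
    max_attempts: int = 10_000,
) -> list[str]:
    """Random recognition sequences with pairwise Hamming distance >= ``min_hamming``.

    Rejection sampling: candidate strings are drawn uniformly over ACGT and
    accepted when far enough from every accepted sequence; after
    ``max_attempts`` consecutive rejections for one slot the constraint is
    declared infeasible.
    """
    if n < 1 or length < 1 or min_hamming < 0:
        raise DesignError("need n >= 1, length >= 1, min_hamming >= 0")
    if min_hamming > length:
        raise DesignError(
            f"min_hamming={min_hamming} exceeds sequence length {length}: infeasible"
        )
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    while len(accepted) < n:
        for _ in range(max_attempts):
            cand = "".join(rng.choice(NUCLEOTIDES, size=length))
            if all(hamming(cand, a) >= min_hamming for a in accepted):
                accepted.append(cand)
                break
        else:
            raise DesignError(
                f"could not place sequence {len(accepted) + 1}/{n} with pairwise "
                f"Hamming >= {min_hamming} at length {length} "
                f"within {max_attempts} attempts"
            )
    return accepted


def build_template_set(
    base_sequence: str,
    variant_triples: Sequence[Sequence[str]],
    recognition_seqs: Sequence[str],
    recognition_offset: int = RECOGNITION_OFFSET,
    spec: VariantSpec = VariantSpec(),
    id_prefix: str = "ST",
) -> list[TemplateRecord]:
    """Stamp variant triples and recognition windows into a shared backbone.

    ``base_sequence`` must begin at the forward priming site.  Templates are
    identical everywhere except at the variant positions of the forward site
    and inside the recognition window; the triple <-> recognition linkage is
    bijective by construction.
    """
    if len(variant_triples) != len(recognition_seqs):
        raise DesignError("need one recognition sequence per variant triple")
    triples = [tuple(t) for t in variant_triples]
    if len(set(triples)) != len(triples):
        raise DesignError("duplicate variant triples")
    if len(set(recognition_seqs)) != len(recognition_seqs):
        raise DesignError("duplicate recognition sequences")
    _check_nucleotides(base_sequence, "base sequence")
    rec_len = len(recognition_seqs[0])
    if any(len(r) != rec_len for r in recognition_seqs):
        raise DesignError("recognition sequences must share one length")
    lo = recognition_offset - 1
    if lo < PRIMER_LENGTH or lo + rec_len > len(base_sequence) - PRIMER_LENGTH:
        raise DesignError("recognition window must lie between the priming sites")
    templates = []
    for i, (triple, rec) in enumerate(zip(triples, recognition_seqs)):
        _check_nucleotides(rec, f"recognition sequence {i}")
        # the variant offsets are relative to the 3' end of the PRIMING SITE,
        # so substitute within the first PRIMER_LENGTH bases only
        site = spec.substitute(base_sequence[:PRIMER_LENGTH], triple)
        seq = site + base_sequence[PRIMER_LENGTH:]
        seq = seq[:lo] + rec + seq[lo + rec_len:]
        templates.append(
            TemplateRecord(f"{id_prefix}{i}", seq, triple, rec, recognition_offset)
        )
    return templates


def mismatch_profile(
    primer: PrimerRecord,
    template: TemplateRecord,
    spec: VariantSpec = VariantSpec(),
) -> MismatchProfile:
    """Variant-position comparison of a primer core against a template forward site."""
    site = template.forward_site
    if len(primer.core) != len(site):
        raise DesignError(
            f"primer {primer.primer_id} and template {template.template_id} "
            "forward site differ in length"
        )
    entries = []
    for label, off, idx in zip(spec.labels, spec.offsets_from_3prime, spec.indices(len(site))):
        if primer.core[idx] != site[idx]:
            entries.append(MismatchEntry(label, off, primer.core[idx], site[idx]))
    return MismatchProfile(tuple(entries))


def triple_mismatch_profile(
    primer_triple: Sequence[str],
    site_triple: Sequence[str],
    spec: VariantSpec = VariantSpec(),
) -> MismatchProfile:
    """Mismatch profile of a primer triple against a priming-site triple.

    Used by the standard-PCR simulator, where a copy's forward site is fully
    described by the triple of the primer that created its lineage.
    """
    entries = []
    for label, off, p, t in zip(
        spec.labels, spec.offsets_from_3prime, primer_triple, site_triple
    ):
        if p != t:
            entries.append(MismatchEntry(label, off, p, t))
    return MismatchProfile(tuple(entries))


@dataclass(frozen=True)
class InteractionSpace:
    """All primer x template pairs with their mismatch profiles.

    Also carries the exact-match lookup keys used for read classification:
    primer core -> primer, variant triple -> primer, recognition sequence ->
    template.  Keys must be unique (enforced at construction).
    """

    templates: tuple[TemplateRecord, ...]
    primers: tuple[PrimerRecord, ...]
    spec: VariantSpec = VariantSpec()
    profiles: Mapping[tuple[str, str], MismatchProfile] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.templates or not self.primers:
            raise DesignError("interaction space needs at least one template and one primer")
        tids = [t.template_id for t in self.templates]
        pids = [p.primer_id for p in self.primers]
        if len(set(tids)) != len(tids) or len(set(pids)) != len(pids):
            raise DesignError("template/primer ids must be unique")
        recs = [t.recognition_seq for t in self.templates]
        if len(set(recs)) != len(recs):
            raise DesignError("two templates share a recognition sequence: lookup key collision")
        cores = [p.core for p in self.primers]
        if len(set(cores)) != len(cores):
            raise DesignError("two primers share a core sequence: lookup key collision")
        if self.profiles is None:
            prof = {
                (p.primer_id, t.template_id): mismatch_profile(p, t, self.spec)
                for p in self.primers
                for t in self.templates
            }
            object.__setattr__(self, "profiles", prof)

    # -- lookups -----------------------------------------------------------
    @property
    def template_by_id(self) -> dict[str, TemplateRecord]:
        return {t.template_id: t for t in self.templates}

    @property
    def primer_by_id(self) -> dict[str, PrimerRecord]:
        return {p.primer_id: p for p in self.primers}

    @property
    def primer_by_core(self) -> dict[str, str]:
        return {p.core: p.primer_id for p in self.primers}

    @property
    def primer_by_triple(self) -> dict[tuple[str, ...], str]:
        d = {p.variant_triple: p.primer_id for p in self.primers}
        if len(d) != len(self.primers):
            raise DesignError("variant triples are not unique; triple lookup unavailable")
        return d

    @property
    def template_by_recognition(self) -> dict[str, str]:
        return {t.recognition_seq: t.template_id for t in self.templates}

    @property
    def recognition_offset(self) -> int:
        return self.templates[0].recognition_offset

    @property
    def recognition_length(self) -> int:
        return len(self.templates[0].recognition_seq)

    def pairs(self) -> list[tuple[str, str]]:
        return [(p.primer_id, t.template_id) for p in self.primers for t in self.templates]

    def n_mismatches(self, primer_id: str, template_id: str) -> int:
        return self.profiles[(primer_id, template_id)].n_mismatches

    def perfect_pairs(self) -> set[tuple[str, str]]:
        return {k for k, v in self.profiles.items() if v.is_perfect}

    # -- serialization -----------------------------------------------------
    def to_mapping_frame(self) -> pd.DataFrame:
        """Mapping table of all primer x recognition-sequence combinations."""
        rows = []
        tmap = self.template_by_id
        for p in self.primers:
            for t in self.templates:
                prof = self.profiles[(p.primer_id, t.template_id)]
                rows.append(
                    {
                        "primer_id": p.primer_id,
                        "template_id": t.template_id,
                        "primer_core": p.core,
                        "recognition_seq": tmap[t.template_id].recognition_seq,
                        "n_mismatches": prof.n_mismatches,
                        "mismatch_positions": ";".join(prof.positions),
                        "mismatch_pairs": ";".join(prof.pairings),
                    }
                )
        return pd.DataFrame(rows)

    def to_mapping_tsv(self, path) -> None:
        self.to_mapping_frame().to_csv(path, sep="\t", index=False)


def interaction_space(
    templates: Sequence[TemplateRecord],
    primers: Sequence[PrimerRecord],
    spec: VariantSpec = VariantSpec(),
) -> InteractionSpace:
    """Build the full |primers| x |templates| interaction space."""
    return InteractionSpace(tuple(templates), tuple(primers), spec)


# ---------------------------------------------------------------------------
# Pool registry (the experimental pools of templates and primers)
# ---------------------------------------------------------------------------

#: Template pools: A = single reference template; B = all ten equimolar;
#: C = reference template diluted to 10% relative concentration;
#: D/E = two-fold staircases over the 3'-variant (D) and M-variant (E) templates.
TEMPLATE_POOL_TABLE: dict[str, dict[str, float]] = {
    "A": {"ST0": 1.0},
    "B": {f"ST{i}": 1.0 for i in range(10)},
    "C": {"ST0": 0.1, **{f"ST{i}": 1.0 for i in range(1, 10)}},
    "D": {"ST0": 1.0, "ST7": 2.0, "ST9": 4.0, "ST8": 8.0},
    "E": {"ST0": 1.0, "ST5": 2.0, "ST4": 4.0, "ST6": 8.0},
}

#: Primer pools, all equimolar: 1 = the perfect-match primer only; 9 = the nine
#: single-mismatch primers; 10 = one perfect match per template; 27 = all double
#: mismatches (no perfect match with any template); 64 = every variant.
PRIMER_POOL_TABLE: dict[str, dict[str, float]] = {
    "1": {"V0": 1.0},
    "9": {f"V{i}": 1.0 for i in range(1, 10)},
    "10": {f"V{i}": 1.0 for i in range(10)},
    "27": {f"V{i}": 1.0 for i in range(10, 37)},
    "64": {f"V{i}": 1.0 for i in range(64)},
}


def make_pool(
    pool_id: str,
    registry: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> PoolSpec:
    """Look up a pool in the bundled registry (or a user-supplied one)."""
    if registry is None:
        registry = {**TEMPLATE_POOL_TABLE, **PRIMER_POOL_TABLE}
    key = str(pool_id)
    if key not in registry:
        raise DesignError(f"unknown pool id {pool_id!r}; known: {sorted(registry)}")
    return PoolSpec.from_mapping(key, registry[key])


# ---------------------------------------------------------------------------
# Default design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Design:
    templates: tuple[TemplateRecord, ...]
    primers: tuple[PrimerRecord, ...]
    space: InteractionSpace
    spec: VariantSpec

    @property
    def amplicon_length(self) -> int:
        return len(self.templates[0].sequence)


def default_base_sequence(
    seed: int = DEFAULT_DESIGN_SEED,
    amplicon_length: int = DEFAULT_AMPLICON_LENGTH,
) -> str:
    """Template backbone: ST0 forward site + seeded-random interior + constant reverse site.

    The interior carries no design information (the recognition window is
    stamped over part of it per template); it only has to be shared by all
    templates.  The amplicon length is chosen so a 2x153 read pair overlaps
    comfortably when merged.
    """
    rng = np.random.default_rng(seed)
    interior_len = amplicon_length - PRIMER_LENGTH
    interior = "".join(rng.choice(NUCLEOTIDES, size=interior_len))
    return ST0_FORWARD_SITE + interior


def default_design(
    seed: int = DEFAULT_DESIGN_SEED,
    n_templates: int = 10,
    spec: VariantSpec = VariantSpec(),
    recognition_length: int = RECOGNITION_LENGTH,
    recognition_offset: int = RECOGNITION_OFFSET,
    min_hamming: int = 4,
    amplicon_length: int = DEFAULT_AMPLICON_LENGTH,
) -> Design:
    """The study design: 10 templates x 64 primers = 640 interactions.

    Template STi carries the variant triple of primer Vi (so pool "10" holds
    exactly one perfect match per template), plus a unique recognition
    sequence with pairwise Hamming distance >= 4.
    """
    primers = canonical_primer_set(spec=spec)
    triples = [p.variant_triple for p in primers[:n_templates]]
    recs = generate_recognition_set(
        n_templates, recognition_length, min_hamming, seed=seed
    )
    base = default_base_sequence(seed=seed, amplicon_length=amplicon_length)
    templates = build_template_set(
        base, triples, recs, recognition_offset=recognition_offset, spec=spec
    )
    space = interaction_space(templates, primers, spec)
    return Design(tuple(templates), tuple(primers), space, spec)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def write_design_fasta(records: Iterable, path) -> None:
    """Write templates or primers as FASTA; descriptions carry the variant triple."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    out = []
    for r in records:
        if isinstance(r, TemplateRecord):
            desc = (
                f"triple={''.join(r.variant_triple)} "
                f"recognition={r.recognition_seq}@{r.recognition_offset}"
            )
            out.append(SeqRecord(Seq(r.sequence), id=r.template_id, description=desc))
        elif isinstance(r, PrimerRecord):
            desc = f"triple={''.join(r.variant_triple)}"
            if r.linker:
                desc += f" linker={r.linker}"
            out.append(SeqRecord(Seq(r.core), id=r.primer_id, description=desc))
        else:
            raise TypeError(f"cannot serialize {type(r).__name__} as design FASTA")
    seqio_write(out, path, "fasta")
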