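"""Synthetic hairpin bisulfite sequencing data.

Hairpin bisulfite libraries ligate a connector between the Watson and Crick
strands of a DNA duplex, so after bisulfite conversion and PCR a single
molecule yields two mates: a T-enriched read (the converted Watson strand,
where unmethylated C reads as T) and an A-enriched read (the PCR complement
of the converted Crick strand, where Watson G reads as A wherever the paired
Crick C was unmethylated).  This module generates reference genomes,
per-cytosine methylomes, duplex fragments, hairpin mate pairs and plain
single-end bisulfite reads, together with ground-truth sidecars recording
fragment origins, injected error positions and methylation states.

Default simulation conditions: CpG methylation 80%, CpH methylation 2%,
complete bisulfite conversion, read lengths 100/75/50 bp in proportions
0.634/0.2/0.166.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "WATSON",
    "CRICK",
    "revcomp",
    "ReferenceGenome",
    "Methylome",
    "PlantedRepeat",
    "HairpinFragment",
    "PairTruth",
    "HairpinReadPair",
    "SimulatedRead",
    "SimConfig",
    "generate_reference",
    "generate_methylome",
    "sample_fragments",
    "make_hairpin_pair",
    "simulate_hairpin_pairs",
    "simulate_bisulfite_reads",
    "inject_errors",
]

WATSON = "watson"
CRICK = "crick"

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Default read-length distribution: 63.4% of reads at full length (100 bp
#: stands in for the 100-101 bp mode of real hairpin libraries), remainder
#: split between 75 and 50 bp.
DEFAULT_LENGTH_DISTRIBUTION: dict[int, float] = {100: 0.634, 75: 0.2, 50: 0.166}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide sequence (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _rng_from(seed) -> np.random.Generator:
    """Accept an int seed or a SeedSequence."""
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceGenome:
    """Named nucleotide sequences over the strict uppercase {A,C,G,T} alphabet."""

    records: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("reference genome has no records")
        for name, seq in self.records.items():
            if not seq:
                raise ValueError(f"record {name!r} is empty")
            if set(seq) - set(_BASES):
                bad = sorted(set(seq) - set(_BASES))
                raise ValueError(f"record {name!r} contains non-ACGT characters: {bad}")

    def shortest(self) -> int:
        return min(len(s) for s in self.records.values())


@dataclass(frozen=True)
class Methylome:
    """Per-cytosine, per-strand methylation flags.

    Keys are ``(sequence_name, position, strand)`` with positions on the
    Watson coordinate system: a ``watson`` entry sits on a reference C, a
    ``crick`` entry sits on a reference G (the Crick-strand cytosine paired
    with it).  Values are True for methylated.
    """

    states: Mapping[tuple[str, int, str], bool]


@dataclass(frozen=True)
class PlantedRepeat:
    """A repeat family planted into a synthetic genome.

    ``collapse_after_conversion`` plants a second copy whose Cs are replaced
    by Ts: the copies are distinct as plain sequence but become identical
    after C->T bisulfite collapse, so converted reads from them map
    ambiguously while recovered (original) reads map uniquely.
    ``gc_fraction`` optionally gives the repeat block its own base
    composition (lower values yield low-entropy repeat families).
    """

    length: int
    copies: int = 2
    collapse_after_conversion: bool = False
    gc_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("repeat length must be positive")
        if self.copies < 2:
            raise ValueError("a repeat needs at least 2 copies")


@dataclass(frozen=True)
class HairpinFragment:
    """A double-stranded fragment: one duplex sequenced through the hairpin."""

    name: str
    start: int
    end: int
    watson_seq: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.watson_seq):
            raise ValueError("fragment interval does not match sequence length")

    @property
    def origin(self) -> tuple[str, int, int]:
        return (self.name, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PairTruth:
    """Ground truth for one simulated pair.

    ``meth_string`` has one character per fragment position (Watson
    orientation): ``M``/``u`` methylated/unmethylated Watson C, ``X``/``x``
    methylated/unmethylated Crick C (under a Watson G), ``.`` otherwise.
    ``t_error_positions`` are offsets in the T-read (Watson orientation);
    ``a_error_positions`` are offsets in the delivered (reverse-complemented)
    A-read.
    """

    name: str
    start: int
    end: int
    t_error_positions: tuple[int, ...] = ()
    a_error_positions: tuple[int, ...] = ()
    meth_string: str = ""
    strand: str = WATSON


@dataclass(frozen=True)
class HairpinReadPair:
    """T-enriched and A-enriched mates from one DNA duplex.

    ``t_read`` is in Watson orientation; ``a_read`` is stored in delivered
    orientation (reverse complement of its Watson-orientation form), matching
    how paired-end FASTQ files deliver the second mate.
    """

    pair_id: str
    t_read: str
    a_read: str
    truth: PairTruth | None = None

    def __post_init__(self) -> None:
        if not self.t_read or not self.a_read:
            raise ValueError("hairpin mates must be non-empty")
        if self.truth is not None:
            if any(p < 0 or p >= len(self.t_read) for p in self.truth.t_error_positions):
                raise ValueError("truth t_error_positions outside mate bounds")
            if any(p < 0 or p >= len(self.a_read) for p in self.truth.a_error_positions):
                raise ValueError("truth a_error_positions outside mate bounds")


@dataclass(frozen=True)
class SimulatedRead:
    """A single-end bisulfite read with its truth origin."""

    read_id: str
    sequence: str
    name: str
    start: int
    end: int
    strand: str  # template strand the read was converted from
    error_positions: tuple[int, ...] = ()


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults are the study conditions: CpG methylation 0.8, CpH 0.02,
    complete conversion, no sequencing error, lengths 100/75/50 at
    0.634/0.2/0.166.
    """

    p_cpg: float = 0.8
    p_cph: float = 0.02
    conversion_rate: float = 1.0
    error_rate: float = 0.0
    length_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )
    n_pairs: int = 1000
    rng_seed: int = 0
    hemimethylation_rate: float = 0.0

    def __post_init__(self) -> None:
        for nm in ("p_cpg", "p_cph", "conversion_rate", "error_rate", "hemimethylation_rate"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must be in [0,1], got {v}")
        total = sum(self.length_distribution.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"length_distribution proportions sum to {total}, not 1")
        if any(l < 1 for l in self.length_distribution):
            raise ValueError("lengths must be positive")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be non-negative")


# ---------------------------------------------------------------------------
# Reference genome generation
# ---------------------------------------------------------------------------


def generate_reference(
    length: int,
    gc_fraction: float = 0.42,
    repeat_spec: Sequence[PlantedRepeat] | None = None,
    seed: int = 0,
    name: str = "chr1",
) -> ReferenceGenome:
    """Generate one random reference record, optionally with planted repeats.

    Bases are drawn i.i.d. with P(G)=P(C)=gc_fraction/2.  Each
    :class:`PlantedRepeat` overwrites ``copies`` non-overlapping random
    windows with (near-)identical blocks so that ambiguous mappings occur.

    Raises ValueError for non-positive length, or a repeat_spec whose blocks
    cannot be placed without overlap (too long or too many copies).
    """
    if length < 1:
        raise ValueError("genome length must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0,1]")
    rng = _rng_from(seed)
    seq = _random_bases(rng, length, gc_fraction)

    if repeat_spec:
        occupied: list[tuple[int, int]] = []
        for rep in repeat_spec:
            if rep.length * rep.copies > length:
                raise ValueError(
                    f"repeat of length {rep.length} x {rep.copies} copies "
                    f"does not fit in a genome of length {length}"
                )
            block = _random_bases(
                rng, rep.length, rep.gc_fraction if rep.gc_fraction is not None else gc_fraction
            )
            collapsed = block.replace("C", "T")
            if rep.collapse_after_conversion and collapsed == block:
                # need at least one C for the collapse to be non-trivial
                block = "C" + block[1:]
                collapsed = block.replace("C", "T")
            for copy_i in range(rep.copies):
                start = _place_block(rng, length, rep.length, occupied)
                occupied.append((start, start + rep.length))
                text = block if (copy_i == 0 or not rep.collapse_after_conversion) else collapsed
                seq = seq[:start] + text + seq[start + rep.length :]
    return ReferenceGenome(records={name: seq})


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=n, p=probs)
    return "".join(_BASES[i] for i in idx)


def _place_block(
    rng: np.random.Generator, genome_len: int, block_len: int, occupied: list[tuple[int, int]]
) -> int:
    for _ in range(1000):
        start = int(rng.integers(0, genome_len - block_len + 1))
        if all(start + block_len <= s or start >= e for s, e in occupied):
            return start
    raise ValueError("could not place repeat copies without overlap")


# ---------------------------------------------------------------------------
# Methylome generation
# ---------------------------------------------------------------------------


def generate_methylome(
    ref: ReferenceGenome,
    p_cpg: float = 0.8,
    p_cph: float = 0.02,
    hemimethylation_rate: float = 0.0,
    seed: int = 0,
) -> Methylome:
    """Assign a methylation state to every cytosine on both strands.

    A Watson C at position i is in CpG context when position i+1 is G; a
    Crick C (under a Watson G at i) is in CpG context when position i-1 is C.
    CpG cytosines are methylated with probability ``p_cpg``, all other
    cytosines with ``p_cph``.  CpG methylation is symmetric across strands:
    the Crick partner copies the Watson call except with probability
    ``hemimethylation_rate``.
    """
    for nm, v in (("p_cpg", p_cpg), ("p_cph", p_cph), ("hemimethylation_rate", hemimethylation_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{nm} must be in [0,1]")
    rng = _rng_from(seed)
    states: dict[tuple[str, int, str], bool] = {}
    for name, seq in ref.records.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        next_g = np.zeros_like(is_c)
        next_g[:-1] = is_g[1:]
        prev_c = np.zeros_like(is_c)
        prev_c[1:] = is_c[:-1]
        watson_cpg = is_c & next_g
        crick_cpg = is_g & prev_c

        draws = rng.random(len(seq))
        for i in np.flatnonzero(is_c):
            p = p_cpg if watson_cpg[i] else p_cph
            states[(name, int(i), WATSON)] = bool(draws[i] < p)
        # Crick: CpG partners copy the Watson call (position i-1), with an
        # optional hemimethylation flip; non-CpG Crick Cs draw independently.
        draws2 = rng.random(len(seq))
        for i in np.flatnonzero(is_g):
            i = int(i)
            if crick_cpg[i]:
                partner = states[(name, i - 1, WATSON)]
                if hemimethylation_rate > 0 and draws2[i] < hemimethylation_rate:
                    partner = not partner
                states[(name, i, CRICK)] = partner
            else:
                states[(name, i, CRICK)] = bool(draws2[i] < p_cph)
    return Methylome(states=states)


# ---------------------------------------------------------------------------
# Fragment sampling
# ---------------------------------------------------------------------------


def sample_fragments(
    ref: ReferenceGenome,
    n: int,
    length_distribution: Mapping[int, float] | None = None,
    seed: int = 0,
) -> list[HairpinFragment]:
    """Sample n duplex fragments with lengths drawn from the distribution.

    Start positions are uniform over all valid starts across records.
    Raises ValueError when a requested length exceeds every record length.
    """
    dist = dict(length_distribution or DEFAULT_LENGTH_DISTRIBUTION)
    lengths = sorted(dist)
    probs = np.array([dist[l] for l in lengths], dtype=float)
    probs = probs / probs.sum()
    names = list(ref.records)
    for l in lengths:
        if all(len(ref.records[nm]) < l for nm in names):
            raise ValueError(f"requested length {l} exceeds every record length")
    rng = _rng_from(seed)
    chosen = rng.choice(len(lengths), size=n, p=probs)
    frags: list[HairpinFragment] = []
    for j in range(n):
        L = lengths[int(chosen[j])]
        # uniform over valid (record, start) slots
        slots = np.array([max(0, len(ref.records[nm]) - L + 1) for nm in names])
        total = int(slots.sum())
        flat = int(rng.integers(0, total))
        for nm, s in zip(names, slots):
            if flat < s:
                start = flat
                frags.append(
                    HairpinFragment(nm, start, start + L, ref.records[nm][start : start + L])
                )
                break
            flat -= int(s)
    return frags


# ---------------------------------------------------------------------------
# Hairpin pair construction
# ---------------------------------------------------------------------------


def inject_errors(
    seq: str, error_rate: float, rng: np.random.Generator
) -> tuple[str, tuple[int, ...]]:
    """Apply i.i.d. per-base substitution errors; each errored base becomes
    one of the 3 alternatives uniformly.  Returns (sequence, error offsets)."""
    if error_rate <= 0:
        return seq, ()
    out = list(seq)
    positions = []
    for i in range(len(out)):
        if rng.random() < error_rate:
            alternatives = [b for b in _BASES if b != out[i]]
            out[i] = alternatives[int(rng.integers(0, 3))]
            positions.append(i)
    return "".join(out), tuple(positions)


def make_hairpin_pair(
    frag: HairpinFragment,
    meth: Methylome,
    cfg: SimConfig,
    seed,
    pair_id: str | None = None,
) -> HairpinReadPair:
    """Simulate one hairpin mate pair from a duplex fragment.

    The T-read is the Watson strand with each unmethylated C converted to T
    with probability ``cfg.conversion_rate``.  The A-read is the PCR
    complement of the converted Crick strand rendered in Watson coordinates
    (Watson G -> A wherever the paired Crick C converted), then stored
    reverse-complemented (delivered orientation).  Substitution errors at
    ``cfg.error_rate`` are applied independently to each mate afterwards.

    Conversion and error injection use separate child RNG streams of
    ``seed``, so the same seed yields the same conversion layer at any error
    rate.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    conv_rng, err_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    t = list(frag.watson_seq)
    a_watson = list(frag.watson_seq)
    meth_chars = []
    for i, base in enumerate(frag.watson_seq):
        pos = frag.start + i
        if base == "C":
            key = (frag.name, pos, WATSON)
            if key not in meth.states:
                raise ValueError(f"methylome does not cover Watson C at {key}")
            methylated = meth.states[key]
            meth_chars.append("M" if methylated else "u")
            if not methylated and conv_rng.random() < cfg.conversion_rate:
                t[i] = "T"
        elif base == "G":
            key = (frag.name, pos, CRICK)
            if key not in meth.states:
                raise ValueError(f"methylome does not cover Crick C at {key}")
            methylated = meth.states[key]
            meth_chars.append("X" if methylated else "x")
            if not methylated and conv_rng.random() < cfg.conversion_rate:
                a_watson[i] = "A"
        else:
            meth_chars.append(".")

    t_read, t_errors = inject_errors("".join(t), cfg.error_rate, err_rng)
    a_delivered, a_errors = inject_errors(revcomp("".join(a_watson)), cfg.error_rate, err_rng)
    truth = PairTruth(
        name=frag.name,
        start=frag.start,
        end=frag.end,
        t_error_positions=t_errors,
        a_error_positions=a_errors,
        meth_string="".join(meth_chars),
    )
    return HairpinReadPair(
        pair_id=pair_id if pair_id is not None else f"{frag.name}:{frag.start}-{frag.end}",
        t_read=t_read,
        a_read=a_delivered,
        truth=truth,
    )


def simulate_hairpin_pairs(
    ref: ReferenceGenome, meth: Methylome, cfg: SimConfig
) -> list[HairpinReadPair]:
    """Simulate ``cfg.n_pairs`` hairpin pairs; fully determined by cfg.rng_seed."""
    root = np.random.SeedSequence(cfg.rng_seed)
    frag_ss, pairs_ss = root.spawn(2)
    frags = sample_fragments(ref, cfg.n_pairs, cfg.length_distribution, seed=frag_ss)
    children = pairs_ss.spawn(len(frags))
    return [
        make_hairpin_pair(frag, meth, cfg, child, pair_id=f"pair{j:06d}")
        for j, (frag, child) in enumerate(zip(frags, children))
    ]


# ---------------------------------------------------------------------------
# Single-end bisulfite reads (non-directional)
# ---------------------------------------------------------------------------


def simulate_bisulfite_reads(
    ref: ReferenceGenome, meth: Methylome, cfg: SimConfig
) -> list[SimulatedRead]:
    """Simulate single-end bisulfite reads drawn from either strand.

    Watson-template reads are the fragment with unmethylated Watson Cs
    converted; Crick-template reads are the reverse complement with
    unmethylated Crick Cs converted, delivered in Crick orientation.
    Substitution errors follow ``cfg.error_rate``.
    """
    root = np.random.SeedSequence(cfg.rng_seed)
    frag_ss, strand_ss, conv_ss, err_ss = root.spawn(4)
    frags = sample_fragments(ref, cfg.n_pairs, cfg.length_distribution, seed=frag_ss)
    strand_rng = np.random.default_rng(strand_ss)
    conv_rng = np.random.default_rng(conv_ss)
    err_rng = np.random.default_rng(err_ss)
    reads: list[SimulatedRead] = []
    for j, frag in enumerate(frags):
        strand = WATSON if strand_rng.random() < 0.5 else CRICK
        if strand == WATSON:
            out = list(frag.watson_seq)
            for i, base in enumerate(out):
                if base == "C":
                    key = (frag.name, frag.start + i, WATSON)
                    if not meth.states[key] and conv_rng.random() < cfg.conversion_rate:
                        out[i] = "T"
            seq = "".join(out)
        else:
            crick = revcomp(frag.watson_seq)
            out = list(crick)
            for i, base in enumerate(out):
                if base == "C":
                    # crick offset i sits over watson position end-1-i (a G)
                    key = (frag.name, frag.end - 1 - i, CRICK)
                    if not meth.states[key] and conv_rng.random() < cfg.conversion_rate:
                        out[i] = "T"
            seq = "".join(out)
        seq, errors = inject_errors(seq, cfg.error_rate, err_rng)
        reads.append(
            SimulatedRead(
                read_id=f"read{j:06d}",
                sequence=seq,
                name=frag.name,
                start=frag.start,
                end=frag.end,
                strand=strand,
                error_positions=errors,
            )
        )
    return reads
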