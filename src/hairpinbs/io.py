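"""File formats, run configuration and the end-to-end pipeline.

Coordinates are 0-based half-open in every file.  Tabular outputs are
headered, tab-separated UTF-8 with a leading ``#`` comment line carrying the
configuration hash so a report can be traced to the run that made it.
All randomness flows from the single configured seed.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from . import recovery as rec
from . import stats as st
from .mapper import MappingResult, build_index, map_batch
from .simulate import (
    HairpinReadPair,
    PairTruth,
    PlantedRepeat,
    ReferenceGenome,
    SimConfig,
    generate_methylome,
    generate_reference,
    simulate_hairpin_pairs,
)

logger = logging.getLogger("hairpinbs")

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "read_truth",
    "write_truth",
    "write_mapping_tsv",
    "read_mapping_tsv",
    "write_sam",
    "RunConfig",
    "RunManifest",
    "run_pipeline",
]

_FASTA_ALPHABET = set("ACGTN")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> ReferenceGenome:
    """Read a (wrapped or unwrapped) FASTA file into a ReferenceGenome.

    Sequences are upper-cased; characters outside A/C/G/T/N and duplicate or
    empty records are rejected with the offending record named.
    """
    records: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if record.id in records:
            raise ValueError(f"duplicate FASTA record name {record.id!r}")
        if not seq:
            raise ValueError(f"FASTA record {record.id!r} is empty")
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            raise ValueError(
                f"FASTA record {record.id!r} contains illegal characters: {sorted(bad)}"
            )
        records[record.id] = seq
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return ReferenceGenome(records=records)


def write_fasta(ref: ReferenceGenome, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in ref.records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Paired FASTQ
# ---------------------------------------------------------------------------


def _strip_mate_suffix(read_id: str) -> str:
    if read_id.endswith("/1") or read_id.endswith("/2"):
        return read_id[:-2]
    return read_id


def read_fastq_pairs(r1_path, r2_path) -> list[HairpinReadPair]:
    """Read lockstep paired FASTQ files (R1 = T-enriched, R2 = A-enriched).

    Pairs by file position; ids must agree after stripping /1 /2 or
    whitespace suffixes.  Ragged files or an id mismatch raise ValueError
    naming the position.
    """
    it1 = SeqIO.parse(str(r1_path), "fastq")
    it2 = SeqIO.parse(str(r2_path), "fastq")
    pairs: list[HairpinReadPair] = []
    pos = 0
    while True:
        rec1 = next(it1, None)
        rec2 = next(it2, None)
        if rec1 is None and rec2 is None:
            break
        if rec1 is None or rec2 is None:
            short = r1_path if rec1 is None else r2_path
            raise ValueError(f"{short} ends early at record {pos}")
        id1, id2 = _strip_mate_suffix(rec1.id), _strip_mate_suffix(rec2.id)
        if id1 != id2:
            raise ValueError(f"mate id mismatch at record {pos}: {rec1.id!r} vs {rec2.id!r}")
        pairs.append(
            HairpinReadPair(pair_id=id1, t_read=str(rec1.seq).upper(), a_read=str(rec2.seq).upper())
        )
        pos += 1
    return pairs


def write_fastq_pairs(pairs: Iterable[HairpinReadPair], r1_path, r2_path) -> None:
    """Write mates to two FASTQ files with constant high quality (no quality
    model is simulated)."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}/1\n{p.t_read}\n+\n{'I' * len(p.t_read)}\n")
            f2.write(f"@{p.pair_id}/2\n{p.a_read}\n+\n{'I' * len(p.a_read)}\n")


# ---------------------------------------------------------------------------
# Truth sidecar
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = [
    "pair_id",
    "seq_name",
    "start",
    "end",
    "strand",
    "t_error_positions",
    "a_error_positions",
    "methylation",
]


def write_truth(pairs: Iterable[HairpinReadPair], path, config_hash: str = "") -> None:
    """TSV sidecar of fragment origins, injected errors and methylation.

    Coordinates are 0-based half-open; error positions are semicolon-
    separated 0-based offsets within each delivered mate.
    """
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for p in pairs:
            t = p.truth
            if t is None:
                continue
            fh.write(
                "\t".join(
                    [
                        p.pair_id,
                        t.name,
                        str(t.start),
                        str(t.end),
                        t.strand,
                        ";".join(map(str, t.t_error_positions)),
                        ";".join(map(str, t.a_error_positions)),
                        t.meth_string,
                    ]
                )
                + "\n"
            )


def read_truth(path) -> dict[str, PairTruth]:
    out: dict[str, PairTruth] = {}
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = fields
                if header != _TRUTH_COLUMNS:
                    raise ValueError(f"unexpected truth columns: {header}")
                continue
            row = dict(zip(header, fields))
            parse = lambda s: tuple(int(x) for x in s.split(";") if s) if s else ()
            out[row["pair_id"]] = PairTruth(
                name=row["seq_name"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                t_error_positions=parse(row["t_error_positions"]),
                a_error_positions=parse(row["a_error_positions"]),
                meth_string=row["methylation"],
            )
    return out


# ---------------------------------------------------------------------------
# Mapping results
# ---------------------------------------------------------------------------

_MAP_COLUMNS = ["read_id", "category", "seq_name", "position", "strand", "conversion", "score", "n_best"]


def write_mapping_tsv(results: Iterable[MappingResult], path, config_hash: str = "") -> None:
    """Headered TSV, one row per read; best location only (ties in n_best)."""
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        fh.write("\t".join(_MAP_COLUMNS) + "\n")
        for r in results:
            loc = r.best_locations[0] if r.best_locations else None
            fh.write(
                "\t".join(
                    [
                        r.read_id,
                        r.category,
                        loc.name if loc else ".",
                        str(loc.pos) if loc else ".",
                        loc.strand if loc else ".",
                        loc.conversion if loc else ".",
                        str(r.best_score) if r.best_score is not None else ".",
                        str(r.n_best),
                    ]
                )
                + "\n"
            )


def read_mapping_tsv(path) -> list[MappingResult]:
    from .mapper import Location

    out: list[MappingResult] = []
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = fields
                if header != _MAP_COLUMNS:
                    raise ValueError(f"unexpected mapping columns: {header}")
                continue
            row = dict(zip(header, fields))
            locs = ()
            if row["seq_name"] != ".":
                locs = (
                    Location(row["seq_name"], int(row["position"]), row["strand"], row["conversion"]),
                )
            out.append(
                MappingResult(
                    read_id=row["read_id"],
                    category=row["category"],
                    best_score=int(row["score"]) if row["score"] != "." else None,
                    best_locations=locs,
                    n_best=int(row["n_best"]),
                )
            )
    return out


def write_sam(
    results: Iterable[MappingResult], reads: Mapping[str, str], ref: ReferenceGenome, path
) -> None:
    """Minimal SAM of the mapped reads only: flags 0/16, NM tag = score."""
    from .simulate import revcomp

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, seq in ref.records.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for r in results:
            if not r.best_locations:
                continue
            loc = r.best_locations[0]
            seq = reads[r.read_id]
            flag = 0 if loc.strand == "watson" else 16
            if flag == 16:
                seq = revcomp(seq)
            fh.write(
                f"{r.read_id}\t{flag}\t{loc.name}\t{loc.pos + 1}\t255\t{len(seq)}M\t*\t0\t0\t"
                f"{seq}\t*\tNM:i:{r.best_score}\n"
            )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a full pipeline run (plain-text serializable)."""

    seed: int = 0
    log_level: str = "INFO"
    # simulate
    genome_length: int = 100_000
    gc_fraction: float = 0.42
    n_pairs: int = 10_000
    p_cpg: float = 0.8
    p_cph: float = 0.02
    conversion_rate: float = 1.0
    error_rate: float = 0.0
    length_distribution: Mapping[int, float] = field(
        default_factory=lambda: {100: 0.634, 75: 0.2, 50: 0.166}
    )
    repeats: tuple[PlantedRepeat, ...] = ()
    # map
    k: int = 16
    max_mismatch_fraction: float = 0.1
    # analyze
    bootstrap_b: int = 50
    replicate_size: int | None = None
    boundary: int = 25

    _SECTIONS = {
        "global": ("seed", "log_level"),
        "simulate": (
            "genome_length",
            "gc_fraction",
            "n_pairs",
            "p_cpg",
            "p_cph",
            "conversion_rate",
            "error_rate",
            "length_distribution",
            "repeats",
        ),
        "map": ("k", "max_mismatch_fraction"),
        "analyze": ("bootstrap_b", "replicate_size", "boundary"),
    }

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        kwargs = {}
        for section in cp.sections():
            if section not in cls._SECTIONS:
                raise ValueError(f"unknown config section [{section}]")
            for key, value in cp.items(section):
                if key not in cls._SECTIONS[section]:
                    raise ValueError(f"unknown config key {key!r} in section [{section}]")
                kwargs[key] = _parse_config_value(key, value)
        return cls(**kwargs)

    def to_file(self, path) -> None:
        cp = configparser.ConfigParser()
        for section, keys in self._SECTIONS.items():
            cp[section] = {}
            for key in keys:
                value = getattr(self, key)
                if key == "length_distribution":
                    value = ",".join(f"{l}:{p}" for l, p in sorted(value.items()))
                elif key == "repeats":
                    value = ",".join(
                        f"{r.length}x{r.copies}{'c' if r.collapse_after_conversion else ''}"
                        + (f"@{r.gc_fraction}" if r.gc_fraction is not None else "")
                        for r in value
                    )
                elif value is None:
                    value = ""
                cp[section][key] = str(value)
        with open(path, "w") as fh:
            cp.write(fh)

    def hash(self) -> str:
        payload = asdict(self)  # nested dataclasses become dicts
        payload["length_distribution"] = sorted(self.length_distribution.items())
        payload["repeats"] = list(payload["repeats"])
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _parse_config_value(key: str, value: str):
    value = value.strip()
    if key == "length_distribution":
        out = {}
        for part in value.split(","):
            l, p = part.split(":")
            out[int(l)] = float(p)
        return out
    if key == "repeats":
        if not value:
            return ()
        reps = []
        for part in value.split(","):
            gc = None
            if "@" in part:
                part, gc_s = part.split("@")
                gc = float(gc_s)
            collapse = part.endswith("c")
            if collapse:
                part = part[:-1]
            length, copies = part.split("x")
            reps.append(
                PlantedRepeat(
                    length=int(length),
                    copies=int(copies),
                    collapse_after_conversion=collapse,
                    gc_fraction=gc,
                )
            )
        return tuple(reps)
    if key == "replicate_size":
        return None if value in ("", "None") else int(value)
    if key in ("seed", "genome_length", "n_pairs", "k", "bootstrap_b", "boundary"):
        return int(value)
    if key == "log_level":
        return value
    return float(value)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    version: str
    config_hash: str
    checksums: dict[str, str]
    counts: dict[str, int]
    started: str
    finished: str

    def write(self, path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        tmp.replace(path)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> RunManifest:
    """simulate -> recover -> map (T/A bisulfite, recovered plain) -> analyze.

    Identical config + seed gives byte-identical stage outputs; the manifest
    records per-file checksums and record counts.
    """
    from . import __version__

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    counts: dict[str, int] = {}

    # --- simulate
    logger.info("simulating genome (%d bp) and %d hairpin pairs", config.genome_length, config.n_pairs)
    root = np.random.SeedSequence(config.seed)
    g_seed, m_seed, p_seed = (int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3))
    ref = generate_reference(
        config.genome_length, config.gc_fraction, repeat_spec=config.repeats or None, seed=g_seed
    )
    meth = generate_methylome(ref, config.p_cpg, config.p_cph, seed=m_seed)
    sim_cfg = SimConfig(
        p_cpg=config.p_cpg,
        p_cph=config.p_cph,
        conversion_rate=config.conversion_rate,
        error_rate=config.error_rate,
        length_distribution=config.length_distribution,
        n_pairs=config.n_pairs,
        rng_seed=p_seed,
    )
    pairs = simulate_hairpin_pairs(ref, meth, sim_cfg)
    write_fasta(ref, outdir / "genome.fasta")
    write_fastq_pairs(pairs, outdir / "pairs_R1.fastq", outdir / "pairs_R2.fastq")
    write_truth(pairs, outdir / "truth.tsv", config_hash=chash)
    counts["pairs"] = len(pairs)

    # --- recover
    logger.info("recovering original sequences")
    recovered = [rec.recover(p) for p in pairs]
    with open(outdir / "recovered.fasta", "w") as fh:
        for r in recovered:
            fh.write(f">{r.pair_id}\n{r.sequence}\n")
    with open(outdir / "recovery.tsv", "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        fh.write("pair_id\toffset\tstrand\tstatus\n")
        for r in recovered:
            for c in r.meth_calls:
                fh.write(
                    f"{r.pair_id}\t{c.offset}\t{c.strand}\t"
                    f"{'methylated' if c.methylated else 'unmethylated'}\n"
                )
    counts["recovered"] = len(recovered)

    # --- map
    logger.info("mapping T/A mates (bisulfite mode) and recovered reads (plain mode)")
    bis = build_index(ref, k=config.k, mode="bisulfite")
    plain = build_index(ref, k=config.k, mode="plain")
    kw = dict(max_mismatch_fraction=config.max_mismatch_fraction)
    res_t, _ = map_batch(bis, [(p.pair_id, p.t_read) for p in pairs], **kw)
    res_a, _ = map_batch(bis, [(p.pair_id, p.a_read) for p in pairs], **kw)
    res_r, _ = map_batch(plain, [(r.pair_id, r.sequence) for r in recovered], **kw)
    write_mapping_tsv(res_t, outdir / "map_t.tsv", config_hash=chash)
    write_mapping_tsv(res_a, outdir / "map_a.tsv", config_hash=chash)
    write_mapping_tsv(res_r, outdir / "map_recovered.tsv", config_hash=chash)
    counts["mapped_t"] = len(res_t)

    # --- analyze
    logger.info("running analyses")
    t_reads = {p.pair_id: p.t_read for p in pairs}
    dist = st.entropy_by_category(t_reads, res_t)
    with open(outdir / "entropy.tsv", "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        fh.write("category\tn\tmean_entropy\t" + "\t".join(f"b{i}" for i in range(21)) + "\n")
        for cat, ce in dist.categories.items():
            fh.write(
                f"{cat}\t{ce.n}\t{ce.mean:.6f}\t" + "\t".join(f"{b:.6f}" for b in ce.buckets) + "\n"
            )
    st.categories_by_length(t_reads, res_t).to_csv(outdir / "lengths.tsv", sep="\t", index=False)
    mloc = st.mismatch_location_effect(
        pairs, bis, boundary=config.boundary, max_mismatch_fraction=config.max_mismatch_fraction
    )
    mloc.to_csv(outdir / "mismatch_location.tsv", sep="\t", index=False)
    a_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
    boot = st.bootstrap_improvement(
        pairs,
        ref,
        B=config.bootstrap_b,
        replicate_size=config.replicate_size,
        k=config.k,
        max_mismatch_fraction=config.max_mismatch_fraction,
        seed=a_seed,
    )
    rescue = st.cross_strand_rescue(res_t, res_a)
    est = st.estimate_methylation(recovered)
    summary = {
        "config_hash": chash,
        "bootstrap": {
            "B": boot.B,
            "mean_improvement": boot.mean_improvement,
            "variance": boot.variance,
            "p_value": boot.p_value,
        },
        "cross_strand_rescue": asdict(rescue),
        "ks_max_differences": st.max_category_differences(dist)
        if all(ce.n for ce in dist.categories.values())
        else {},
        "methylation": {
            "cpg_rate": est.cpg_rate,
            "cph_rate": est.cph_rate,
            "n_cpg": est.n_cpg,
            "n_cph": est.n_cph,
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    checksums = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name not in ("manifest.json",)
    }
    manifest = RunManifest(
        version=__version__,
        config_hash=chash,
        checksums=checksums,
        counts=counts,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(outdir / "manifest.json")
    return manifest
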