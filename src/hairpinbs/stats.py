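"""Mapping-failure statistics for bisulfite sequencing experiments.

Covers the analyses that link sequence entropy to mapping category, quantify
what original-sequence recovery buys in unique-mapping efficiency
(bootstrap over read pairs), and stratify mapping outcomes by read length
and by the position/count of inter-mate mismatches.

Sequence entropy here is the base-2 Shannon entropy of a read's base
composition, Ent(s) = -sum_b f_b log2 f_b over b in {A,C,G,T}: 0 for a
homopolymer, 2 for a uniform base mix.  Bisulfite conversion depletes C,
skewing compositions and lowering entropy, which is the proposed mechanism
behind poor bisulfite-read mapping.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

# the package re-exports the recover() *function* under the same name as the
# module, so bind the submodule explicitly
from . import recovery as rec
from .mapper import (
    AMBIGUOUS,
    UNIQUE,
    UNMAPPED,
    MapperIndex,
    MappingResult,
    build_index,
    map_read,
    summarize_categories,
)
from .simulate import CRICK, WATSON, HairpinReadPair, ReferenceGenome

__all__ = [
    "entropy",
    "EntropyDistribution",
    "CategoryEntropy",
    "entropy_by_category",
    "entropy_bucket",
    "ks_two_sample",
    "max_category_differences",
    "categories_by_length",
    "mismatch_location_effect",
    "BootstrapSummary",
    "bootstrap_improvement",
    "CrossStrandRescue",
    "cross_strand_rescue",
    "MapperUnion",
    "mapper_union",
    "MethylationEstimate",
    "estimate_methylation",
]

CATEGORIES = (UNIQUE, AMBIGUOUS, UNMAPPED)


# ---------------------------------------------------------------------------
# Entropy
# ---------------------------------------------------------------------------


def entropy(seq: str) -> float:
    """Base-2 Shannon entropy of the base composition of ``seq``.

    N bases (recovery errors) are excluded from the frequencies.  Raises
    ValueError on an empty sequence or one with no A/C/G/T at all.
    """
    counts = Counter(seq)
    total = sum(counts[b] for b in "ACGT")
    if total == 0:
        raise ValueError("entropy undefined: sequence has no A/C/G/T bases")
    h = 0.0
    for b in "ACGT":
        c = counts[b]
        if c:
            f = c / total
            h -= f * math.log2(f)
    return h


def entropy_bucket(value: float) -> int:
    """Histogram bucket index: 0 for entropy exactly 0, else x in 1..20 where
    bucket x covers ((x-1)/10, x/10]."""
    if value < 0 or value > 2 + 1e-9:
        raise ValueError("entropy out of [0,2]")
    if value == 0:
        return 0
    return min(20, math.ceil(round(value * 10, 9)))


@dataclass(frozen=True)
class CategoryEntropy:
    n: int
    mean: float  # nan when n == 0
    buckets: tuple[float, ...]  # 21 proportions: exact-0 bucket + 20 bins


@dataclass(frozen=True)
class EntropyDistribution:
    categories: Mapping[str, CategoryEntropy]
    samples: Mapping[str, tuple[float, ...]]  # raw entropy values per category


def entropy_by_category(
    reads: Mapping[str, str], results: Sequence[MappingResult]
) -> EntropyDistribution:
    """Entropy histogram (0.1-wide buckets) and mean per mapping category."""
    values: dict[str, list[float]] = {c: [] for c in CATEGORIES}
    for r in results:
        if r.read_id not in reads:
            raise KeyError(f"mapping result for unknown read id {r.read_id!r}")
        values[r.category].append(entropy(reads[r.read_id]))
    cats = {}
    for c in CATEGORIES:
        vals = values[c]
        buckets = [0.0] * 21
        for v in vals:
            buckets[entropy_bucket(v)] += 1
        n = len(vals)
        if n:
            buckets = [b / n for b in buckets]
        cats[c] = CategoryEntropy(
            n=n, mean=float(np.mean(vals)) if n else float("nan"), buckets=tuple(buckets)
        )
    return EntropyDistribution(
        categories=cats, samples={c: tuple(v) for c, v in values.items()}
    )


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns (D, p) where D is the supremum difference between the empirical
    CDFs and p comes from the asymptotic two-sample approximation.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("KS test needs non-empty samples")
    res = sps.ks_2samp(np.asarray(a, float), np.asarray(b, float), method="asymp")
    return float(res.statistic), float(res.pvalue)


def max_category_differences(dist: EntropyDistribution) -> dict[str, float]:
    """Pairwise KS statistics D between the per-category entropy samples.

    Pairs involving an empty category are omitted (with a warning via the
    returned dict simply lacking that key).
    """
    import warnings

    out: dict[str, float] = {}
    pairs = [
        ("unmapped-ambiguous", UNMAPPED, AMBIGUOUS),
        ("unmapped-unique", UNMAPPED, UNIQUE),
        ("unique-ambiguous", UNIQUE, AMBIGUOUS),
    ]
    for label, c1, c2 in pairs:
        a, b = dist.samples[c1], dist.samples[c2]
        if not a or not b:
            warnings.warn(f"category pair {label} has an empty sample; omitted")
            continue
        out[label] = ks_two_sample(a, b)[0]
    return out


# ---------------------------------------------------------------------------
# Length stratification
# ---------------------------------------------------------------------------


def categories_by_length(
    reads: Mapping[str, str], results: Sequence[MappingResult], min_n: int = 20
) -> pd.DataFrame:
    """Percent unique/ambiguous/unmapped per read length.

    Lengths supported by fewer than ``min_n`` reads are flagged low_support.
    """
    rows = []
    by_len: dict[int, list[MappingResult]] = {}
    for r in results:
        by_len.setdefault(len(reads[r.read_id]), []).append(r)
    for L in sorted(by_len):
        s = summarize_categories(by_len[L])
        rows.append(
            {
                "length": L,
                "n": s["n"],
                "unique_pct": s["unique_pct"],
                "ambiguous_pct": s["ambiguous_pct"],
                "unmapped_pct": s["unmapped_pct"],
                "low_support": s["n"] < min_n,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mismatch-location effect
# ---------------------------------------------------------------------------


def mismatch_location_effect(
    pairs: Sequence[HairpinReadPair],
    index: MapperIndex,
    k_values: Sequence[int] = (1, 2, 3),
    boundary: int = 25,
    max_mismatch_fraction: float = 0.1,
    seed_span: int | None = 25,
) -> pd.DataFrame:
    """Unique-mapping rate of T-reads whose inter-mate errors are confined to
    the 5' side (< boundary) vs the 3' side of the read, per error count k.

    Mapping uses bisulfite mode with seeds restricted to the first
    ``seed_span`` bases by default, modelling mappers that anchor on a 5'
    seed region (the mechanism by which 5' mismatches disrupt candidate
    discovery).  Pass ``seed_span=None`` for full-read seeding.
    """
    rows = []
    for k in k_values:
        left, right = rec.mismatch_window_split(pairs, k, boundary=boundary)
        for side, subset in (("left", left), ("right", right)):
            if subset:
                results = [
                    map_read(
                        index,
                        p.t_read,
                        max_mismatch_fraction=max_mismatch_fraction,
                        read_id=p.pair_id,
                        seed_span=seed_span,
                    )
                    for p in subset
                ]
                s = summarize_categories(results)
            else:
                s = summarize_categories([])
            rows.append({"k": k, "side": side, "n": s["n"], "unique_pct": s["unique_pct"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bootstrap comparison of converted vs recovered mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BootstrapSummary:
    B: int
    replicate_size: int
    improvements: tuple[float, ...]  # percentage points, one per replicate
    mean_improvement: float
    variance: float
    p_value: float
    n_missing: int = 0  # replicates with no exactly-aligned pairs


def bootstrap_improvement(
    pairs: Sequence[HairpinReadPair],
    ref: ReferenceGenome,
    B: int = 50,
    replicate_size: int | None = None,
    k: int = 16,
    max_mismatch_fraction: float = 0.1,
    seed: int = 0,
    tie_cap: int = 100,
) -> BootstrapSummary:
    """Bootstrap the unique-mapping gain of recovered over converted reads.

    Each of B replicates samples ``replicate_size`` pairs with replacement
    (default: the input size), keeps the exactly-aligned pairs, maps the
    T- and A-reads in bisulfite mode and the recovered original sequence in
    plain mode with identical thresholds, and records
    improvement = unique%(recovered) - (unique%(T) + unique%(A)) / 2.
    The p-value is the one-sided fraction of replicates with improvement
    <= 0; the variance is the sample variance over replicates (0 when B=1).

    Pair categories are deterministic, so each pair is mapped once and the
    bootstrap resamples the cached categories.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not pairs:
        raise ValueError("no pairs supplied")
    n = len(pairs)
    replicate_size = n if replicate_size is None else replicate_size
    bis = build_index(ref, k=k, mode="bisulfite")
    plain = build_index(ref, k=k, mode="plain")

    is_exact = np.zeros(n, dtype=bool)
    uniq_t = np.zeros(n, dtype=bool)
    uniq_a = np.zeros(n, dtype=bool)
    uniq_r = np.zeros(n, dtype=bool)
    for i, p in enumerate(pairs):
        if rec.error_offsets(p):
            continue
        is_exact[i] = True
        kw = dict(max_mismatch_fraction=max_mismatch_fraction, tie_cap=tie_cap)
        uniq_t[i] = map_read(bis, p.t_read, read_id=p.pair_id, **kw).category == UNIQUE
        uniq_a[i] = map_read(bis, p.a_read, read_id=p.pair_id, **kw).category == UNIQUE
        rcvd = rec.recover(p)
        uniq_r[i] = map_read(plain, rcvd.sequence, read_id=p.pair_id, **kw).category == UNIQUE

    rng = np.random.default_rng(seed)
    improvements: list[float] = []
    n_missing = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=replicate_size)
        sel = idx[is_exact[idx]]
        if len(sel) == 0:
            n_missing += 1
            continue
        u_t = 100.0 * uniq_t[sel].mean()
        u_a = 100.0 * uniq_a[sel].mean()
        u_r = 100.0 * uniq_r[sel].mean()
        improvements.append(u_r - (u_t + u_a) / 2.0)
    if not improvements:
        raise ValueError("every bootstrap replicate was empty of exact pairs")
    arr = np.array(improvements)
    return BootstrapSummary(
        B=B,
        replicate_size=replicate_size,
        improvements=tuple(float(x) for x in arr),
        mean_improvement=float(arr.mean()),
        variance=float(arr.var(ddof=1)) if len(arr) > 1 else 0.0,
        p_value=float((arr <= 0).mean()),
        n_missing=n_missing,
    )


# ---------------------------------------------------------------------------
# Cross-strand rescue and mapper union
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossStrandRescue:
    #: % of uniquely mapped T-reads whose A-mate did not map uniquely
    t_unique_partner_not_pct: float
    #: % of uniquely mapped A-reads whose T-mate did not map uniquely
    a_unique_partner_not_pct: float
    #: unique% when a unique mate's position is transferred to its partner
    combined_unique_pct: float
    n: int


def cross_strand_rescue(
    results_t: Sequence[MappingResult], results_a: Sequence[MappingResult]
) -> CrossStrandRescue:
    """How often one hairpin mate rescues the other's mapping."""
    by_t = {r.read_id: r for r in results_t}
    by_a = {r.read_id: r for r in results_a}
    if set(by_t) != set(by_a):
        raise ValueError("T and A mapping results carry different read ids")
    ids = list(by_t)
    t_u = [i for i in ids if by_t[i].category == UNIQUE]
    a_u = [i for i in ids if by_a[i].category == UNIQUE]
    either = {i for i in ids if by_t[i].category == UNIQUE or by_a[i].category == UNIQUE}
    return CrossStrandRescue(
        t_unique_partner_not_pct=(
            100.0 * sum(by_a[i].category != UNIQUE for i in t_u) / len(t_u) if t_u else 0.0
        ),
        a_unique_partner_not_pct=(
            100.0 * sum(by_t[i].category != UNIQUE for i in a_u) / len(a_u) if a_u else 0.0
        ),
        combined_unique_pct=100.0 * len(either) / len(ids) if ids else 0.0,
        n=len(ids),
    )


@dataclass(frozen=True)
class MapperUnion:
    union_unique_pct: float
    unique_pct_1: float
    unique_pct_2: float
    increment_over_1: float
    increment_over_2: float
    n: int


def mapper_union(
    results_1: Sequence[MappingResult], results_2: Sequence[MappingResult]
) -> MapperUnion:
    """OR-combination of two mappers' unique calls over the same reads."""
    by_1 = {r.read_id: r for r in results_1}
    by_2 = {r.read_id: r for r in results_2}
    if set(by_1) != set(by_2):
        raise ValueError("the two result sets carry different read ids")
    ids = list(by_1)
    n = len(ids)
    u1 = sum(by_1[i].category == UNIQUE for i in ids)
    u2 = sum(by_2[i].category == UNIQUE for i in ids)
    both = sum(by_1[i].category == UNIQUE or by_2[i].category == UNIQUE for i in ids)
    pct = lambda c: 100.0 * c / n if n else 0.0
    return MapperUnion(
        union_unique_pct=pct(both),
        unique_pct_1=pct(u1),
        unique_pct_2=pct(u2),
        increment_over_1=pct(both) - pct(u1),
        increment_over_2=pct(both) - pct(u2),
        n=n,
    )


# ---------------------------------------------------------------------------
# Methylation-rate estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MethylationEstimate:
    cpg_rate: float
    cpg_ci: tuple[float, float]
    n_cpg: int
    cph_rate: float
    cph_ci: tuple[float, float]
    n_cph: int


def estimate_methylation(
    reads: Iterable[rec.RecoveredRead],
    confidence: float = 0.99,
    collapse_symmetric_cpg: bool = False,
) -> MethylationEstimate:
    """CpG and CpH methylation rates from recovered reads' methylation calls.

    Context comes from the recovered sequence itself: a Watson call at
    offset i is CpG when position i+1 reads G; a Crick call at i is CpG when
    position i-1 reads C.  Calls whose context position falls outside the
    read (or on an error N) are skipped.  Wilson score intervals at the
    requested confidence.

    With ``collapse_symmetric_cpg`` the Watson call at offset i and the
    Crick call at i+1 of the same CpG dyad in the same read are merged into
    one site-level observation (they read the same epigenetic state twice,
    so counting both would overstate the evidence); dyads whose two calls
    disagree are skipped as ambiguous.  Use this when the interval is meant
    to be calibrated against a per-site methylation probability.
    """
    meth = {"cpg": 0, "cph": 0}
    total = {"cpg": 0, "cph": 0}
    for r in reads:
        seq = r.sequence
        by_offset = {(c.offset, c.strand): c.methylated for c in r.meth_calls}
        for call in r.meth_calls:
            i = call.offset
            if call.strand == WATSON:
                if i + 1 >= len(seq) or seq[i + 1] == "N":
                    continue
                ctx = "cpg" if seq[i + 1] == "G" else "cph"
            else:
                if i - 1 < 0 or seq[i - 1] == "N":
                    continue
                ctx = "cpg" if seq[i - 1] == "C" else "cph"
            if collapse_symmetric_cpg and ctx == "cpg":
                if call.strand == CRICK and (i - 1, WATSON) in by_offset:
                    continue  # counted with its Watson partner
                partner = by_offset.get((i + 1, CRICK)) if call.strand == WATSON else None
                if partner is not None and partner != call.methylated:
                    continue  # discordant dyad: ambiguous, skip
            total[ctx] += 1
            meth[ctx] += call.methylated
    if total["cpg"] == 0 and total["cph"] == 0:
        raise ValueError("no methylation calls with usable context")
    alpha = 1.0 - confidence

    def _one(ctx):
        if total[ctx] == 0:
            return float("nan"), (float("nan"), float("nan"))
        lo, hi = proportion_confint(meth[ctx], total[ctx], alpha=alpha, method="wilson")
        return meth[ctx] / total[ctx], (float(lo), float(hi))

    cpg_rate, cpg_ci = _one("cpg")
    cph_rate, cph_ci = _one("cph")
    return MethylationEstimate(
        cpg_rate=cpg_rate,
        cpg_ci=cpg_ci,
        n_cpg=total["cpg"],
        cph_rate=cph_rate,
        cph_ci=cph_ci,
        n_cph=total["cph"],
    )
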