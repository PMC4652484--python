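"""Shared fixtures: the synthetic study conditions used across the suite.

The study genome plants two kinds of repeat families into otherwise random
sequence:

* conversion-collapse repeats — two copies that differ only at C/T
  positions, so they are distinct as plain sequence but identical after
  C->T bisulfite collapse (converted reads from them map ambiguously,
  recovered reads uniquely);
* low-GC repeat families — identical low-entropy copies that are ambiguous
  in any mode, giving the ambiguous category its low-entropy character.

Low-entropy *off-genome* pairs ("junk") model unmappable low-complexity
sequence and populate the unmapped category.
"""

from __future__ import annotations

import numpy as np
import pytest

import hairpinbs as h
from hairpinbs import recovery as rec

STUDY_REPEATS = tuple(
    [h.PlantedRepeat(130, 2, collapse_after_conversion=True) for _ in range(12)]
    + [h.PlantedRepeat(130, 3, gc_fraction=0.1) for _ in range(8)]
)


def make_study_data(seed: int = 11, n_pairs: int = 4000, n_junk: int = 300, error_rate: float = 0.005):
    """Study-condition dataset: repeat/CpG-rich genome + low-entropy junk pairs."""
    ref = h.generate_reference(60_000, 0.42, repeat_spec=STUDY_REPEATS, seed=seed)
    meth = h.generate_methylome(ref, seed=seed + 1)
    pairs = h.simulate_hairpin_pairs(
        ref, meth, h.SimConfig(n_pairs=n_pairs, rng_seed=seed + 2, error_rate=error_rate)
    )
    junk_ref = h.generate_reference(20_000, 0.05, seed=seed + 3)
    junk_meth = h.generate_methylome(junk_ref, seed=seed + 4)
    junk = [
        h.HairpinReadPair("junk_" + p.pair_id, p.t_read, p.a_read, p.truth)
        for p in h.simulate_hairpin_pairs(
            junk_ref, junk_meth, h.SimConfig(n_pairs=n_junk, rng_seed=seed + 5, error_rate=error_rate)
        )
    ]
    return {"ref": ref, "meth": meth, "pairs": pairs, "junk": junk}


def inject_t_errors(pair: h.HairpinReadPair, offsets, rng) -> h.HairpinReadPair:
    """Substitute t_read bases so each offset gets an inter-mate ERROR label
    (never a silent rule-table cell)."""
    t = list(pair.t_read)
    _, a_oriented = rec.orient_pair(pair)
    for i in offsets:
        choices = [
            b
            for b in "ACGT"
            if b != t[i] and rec.classify_base_pair(b, a_oriented[i]) == rec.ERROR
        ]
        t[i] = choices[int(rng.integers(0, len(choices)))]
    return h.HairpinReadPair(pair.pair_id, "".join(t), pair.a_read, None)


@pytest.fixture(scope="session")
def study_data():
    return make_study_data()


@pytest.fixture(scope="session")
def study_mapped_t(study_data):
    """Bisulfite-mode mapping of every T-read (genome + junk pairs)."""
    allpairs = study_data["pairs"] + study_data["junk"]
    index = h.build_index(study_data["ref"], k=16, mode="bisulfite")
    results, summary = h.map_batch(index, [(p.pair_id, p.t_read) for p in allpairs])
    t_reads = {p.pair_id: p.t_read for p in allpairs}
    return {"results": results, "summary": summary, "t_reads": t_reads, "index": index}


@pytest.fixture(scope="session")
def error_strata_pairs(study_data):
    """Exact length-100 pairs with 1-3 forced t-read errors confined to one
    side of the 25 bp boundary; 200 pairs per (k, side) stratum."""
    ref, meth = study_data["ref"], study_data["meth"]
    base = h.simulate_hairpin_pairs(
        ref,
        meth,
        h.SimConfig(n_pairs=1200, rng_seed=77, error_rate=0.0, length_distribution={100: 1.0}),
    )
    rng = np.random.default_rng(78)
    out = []
    for j, p in enumerate(base):
        k = (j % 3) + 1
        lo, hi = (0, 25) if j % 2 == 0 else (25, 100)
        offsets = rng.choice(np.arange(lo, hi), size=k, replace=False)
        out.append(inject_t_errors(p, offsets, rng))
    return out


@pytest.fixture()
def tiny_ref():
    return h.ReferenceGenome(records={"chr1": "ATGC"})


@pytest.fixture()
def tiny_unmethylated(tiny_ref):
    return h.generate_methylome(tiny_ref, p_cpg=0.0, p_cph=0.0, seed=0)
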