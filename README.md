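# hairpinbs

A self-contained toolkit for studying **why bisulfite-converted short reads
map so poorly**, built around hairpin bisulfite sequencing. It simulates
hairpin read pairs with ground truth, recovers the original unconverted
sequence from the two mates, maps reads with a minimal bisulfite-aware
seed-and-extend mapper (with an exhaustive brute-force oracle), and runs the
statistics that connect sequence entropy, read length, mismatch position and
original-sequence recovery to unique-mapping efficiency.

It is aimed at methods developers and teaching settings: every stage is a
plain Python function over explicit domain types, every simulation carries a
truth sidecar, and the mapper ships with its own oracle so its behaviour is
testable to the read.

## The science in brief

Bisulfite treatment converts unmethylated cytosine to uracil (read as T
after PCR), so bisulfite reads are C-depleted. Hairpin libraries ligate a
connector between the Watson and Crick strands of one duplex, yielding two
mates per molecule: a **T-enriched** read (converted Watson strand) and an
**A-enriched** read (PCR complement of the converted Crick strand). Placing
both in Watson orientation, the original sequence is recovered position by
position:

| (T-read, A-read) | recovered | meaning |
|---|---|---|
| equal bases | that base | no visible conversion |
| (T, C) | C | unmethylated Watson C |
| (G, A) | G | unmethylated Crick C |
| anything else | error (N) | PCR/sequencing error |

Matching (C,C) and (G,G) positions additionally call methylated cytosines,
so recovery doubles as a double-strand methylation caller.

Mapping uses **three-letter** comparison: C→T (and, for complement strands,
G→A) collapse in both read and reference removes conversion mismatches;
candidates come from exact k-mer seeds (k = 16 by default) and are scored by
Hamming mismatches with threshold ⌊0.1·L⌋. A read is *unique* (one best
location), *ambiguous* (tied best), or *unmapped*.

The linking statistic is base-composition Shannon entropy,
`Ent(s) = −Σ_b f_b log₂ f_b` over b ∈ {A,C,G,T} — 0 for a homopolymer, 2
for a uniform mix. Conversion depletes C, lowers entropy, and makes distinct
loci collide after three-letter collapse; recovering the original sequence
restores entropy and unique mappability, quantified by a 50-replicate
bootstrap of `unique%(recovered) − ½(unique%(T) + unique%(A))`.

## Worked example

```python
import hairpinbs as h
from hairpinbs import stats as st

# a 30-kb genome with repeat families that collapse only after C->T conversion
repeats = [h.PlantedRepeat(130, 2, collapse_after_conversion=True) for _ in range(6)]
ref  = h.generate_reference(30_000, gc_fraction=0.42, repeat_spec=repeats, seed=1)
meth = h.generate_methylome(ref, p_cpg=0.8, p_cph=0.02, seed=2)
pairs = h.simulate_hairpin_pairs(ref, meth, h.SimConfig(n_pairs=1000, rng_seed=3))

rec0 = h.recover(pairs[0])
print(pairs[0].t_read[:40])   # TGAGGTTTTCGATGTAAATTTTTTGAGAAAAAGGTAAGTC
print(rec0.sequence[:40])     # TGAGGTTTTCGATGTAAATTCTTTGAGAAAAAGGTAAGTC

bis, plain = h.build_index(ref, mode="bisulfite"), h.build_index(ref, mode="plain")
_, s_t = h.map_batch(bis,   [(p.pair_id, p.t_read) for p in pairs])
_, s_r = h.map_batch(plain, [(p.pair_id, h.recover(p).sequence) for p in pairs])
boot = st.bootstrap_improvement(pairs, ref, B=50, seed=4)
est  = st.estimate_methylation((h.recover(p) for p in pairs), collapse_symmetric_cpg=True)
```

Output of the full script:

```
entropy(t_read)    = 1.818
entropy(recovered) = 1.973
unique% converted (bisulfite mode): 98.0
unique% recovered (plain mode)   : 100.0
bootstrap mean improvement = 1.03 points, p = 0.00, variance = 0.0647
CpG methylation = 0.799 (99% CI 0.782-0.815, n=3884)
CpH methylation = 0.0210 (99% CI 0.0189-0.0233, n=28099)
```

Reading it: recovery restores the C at position 20 that conversion had
turned into T, raising the read's entropy from 1.82 to 1.97. Converted reads
from the collapse-repeat regions map ambiguously (98.0% unique), recovered
reads map uniquely (100%); across 50 bootstrap replicates the recovery gain
is +1.03 percentage points with no replicate at or below zero (p = 0). The
methylation caller recovers the simulated CpG (80%) and CpH (2%) rates
within their 99% Wilson intervals.

A command-line interface mirrors the stages
(`hairpinbs simulate|recover|map|analyze|run`); `hairpinbs run --out DIR`
executes the whole pipeline from one config file and writes a manifest with
per-file checksums.

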