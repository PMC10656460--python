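# chainsim

Co-linear anchor chaining with a bounded-lookback dynamic program, linear
runtime predictors for hardware/software execution, and a discrete-event
simulator of prediction-based accelerator offloading.

The package models the software side of a heterogeneous (CPU + accelerator)
long-read mapping pipeline at desk scale:

- **`chainsim.anchors`** — anchors (reference/query end positions + span),
  chaining tasks, a seeded generator that plants colinear chains in noise,
  and a TSV dialect for anchor tables.
- **`chainsim.seeding`** — canonical minimizer sampling and shared-minimizer
  anchor extraction from FASTA reference/read pairs.
- **`chainsim.chaining`** — the chaining DP: exact (unbounded lookback),
  bounded-lookback with a maximum inner-loop trip count `H`, and a
  sub-partitioned variant that processes the candidate range in slices of
  `P` predecessors while reproducing the bounded results exactly (the form
  a fixed-trip-count hardware pipeline executes). Plus chain backtracking
  and a quadratic brute-force oracle.
- **`chainsim.perfmodel`** — per-task features (`n`, total sub-partitions,
  summed trip counts), the affine time predictors
  `T_hw = K1·n + II·T_clock·total_subparts + C1` and
  `T_sw = K2·Σ trip_count + C2`, and their least-squares training.
- **`chainsim.scheduler`** — event-driven simulation of `Y` software threads
  sharing `N` accelerator kernels with per-kernel FIFO queues: each chaining
  task runs in software if `T_sw ≤ T_hw`, otherwise on the qualifying kernel
  with the least predicted wait (`T_wait + T_hw < T_sw`), else software.
- **`chainsim.concordance`** — chain-level agreement between bounded-`H`
  and exact chaining (score ratios, top-chain identity), per task and
  aggregated.

## CLI

The `chainsim` entry point exposes the full pipeline:

```sh
# generate synthetic tasks (config is a JSON GeneratorConfig)
chainsim generate --config cfg.json --seed 1 --out anchors.tsv

# or extract anchors from FASTA via shared minimizers
chainsim seed --ref ref.fa --reads reads.fa -k 15 -w 10 --out anchors.tsv

# chain (engines: exact | bounded | subpart), TSV or PAF output
chainsim chain --anchors anchors.tsv --engine bounded -H 512 --out chains.tsv
chainsim chain --anchors anchors.tsv --format paf --out chains.paf

# fit the time predictors from a timing table
chainsim fit --timings timings.tsv --which both --out coeffs.tsv

# simulate prediction-based placement (Y threads, N kernels)
chainsim simulate --anchors anchors.tsv --coeffs coeffs.tsv \
    --threads 8 --kernels 1 --truth noisy:0.1 --seed 1 --report report.tsv

# bounded-H vs exact concordance sweep
chainsim compare --anchors anchors.tsv -H 64,512,1024 --out concordance.tsv
```

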