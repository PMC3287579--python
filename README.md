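# bnss

Stochastic simulation and state-space analysis of Boolean regulatory
networks.

`bnss` simulates logical models under a hybrid update scheme —
deterministic Boolean rules for most nodes, a fresh random Boolean state
per update for *free* nodes, and *clamped* nodes held fixed (the hormone
input held True, knockout "mutants" held False) — and analyses the
resulting trajectories:

- **State census**: distinct visited states (Hamming-distance-0 identity
  over all nodes) with visit times and counts; per-run cardinality mean
  and sample SD (the visited state space is bounded by Ω = 2^N).
- **Frozen/variable classification**: a node is *frozen* iff it holds one
  constant value at every recorded update in every run of an ensemble.
- **Synchrony groups**: maximal sets of variable nodes with exactly equal
  (optionally exactly complementary) value sequences.
- **Joint pair census**: 2×2 counts for a node pair with a
  synchronized-equal / synchronized-opposite / unsynchronized verdict.
- **Efficiency curves**: per-update fraction of runs with a designated
  output node True.
- **Mutant comparison**: wild network vs single-node False-clamp mutants,
  including the intersection of their variable sets.
- **Exact oracle**: brute-force enumeration of the full 2^N transition
  structure for small networks (functional map when deterministic,
  row-stochastic matrix with uniform branching over free-node draws
  otherwise), recurrent classes, and exact stationary distributions —
  ground truth for every sampling-based statistic.

## Rule files

Line-oriented, one Boolean rule per node; declaration order defines node
order and the sequential update order:

```text
# toy network
GCR1 = RANDOM              # free node: Bernoulli(1/2) each update
GPA1 = S1P AND NOT GCR1
S1P  = GPA1 OR S1P
clamp S1P = False          # hold a node fixed (precedes rule and RANDOM)
```

Operators `AND`/`OR`/`NOT` (case-insensitive; precedence `NOT > AND >
OR`, parentheses allowed), constants `True`/`False`, `#` comments.
Identifiers may contain letters, digits, `_`, `+`, `-` (e.g. `Ca2+_c`).
A BoolNet-style `targets, factors` dialect (`&`, `|`, `!`) and a JSON
serialization are also supported.

Two update modes: `synchronous` (default; every rule reads the old state)
and `sequential` (nodes updated in declaration order, rules reading the
partially updated state). Run `i` of an ensemble uses an RNG stream
derived from `(seed, i)`, so results are bit-reproducible and independent
of execution order.

## CLI

```sh
bnss simulate network.txt --updates 20 --runs 300 --seed 1 \
     --clamp ABA=TRUE -o out/            # ensemble TSV + manifest
bnss analyze network.txt --census --classify --pair AnionEm,closure \
     --efficiency closure --burnin 4 --runs 300 --updates 20 -o out/
bnss mutants network.txt --mutate S1P,PA,ABI1,pHc,NOS \
     --clamp ABA=TRUE --output-node closure --runs 30 --updates 100 -o out/
bnss oracle toy.txt -o out/              # exact dynamics JSON
bnss generate -n 8 -k 2 --free-fraction 0.2 --seed 7 -o out/
```

Every command writes a `manifest.json` (resolved configuration, input
hash, tool version) sufficient to reproduce its outputs byte-for-byte.
Exit codes: 0 success, 2 usage error, 3 parse/validation error. A YAML
config file may replace flags (`--config`); explicit flags win.

## The ABA stomatal-closure model

The 43-node guard-cell ABA signaling network this tool was designed
around is **not bundled**: its rule table lives in the published source
model and must be transcribed by the user. A labelled template with
format instructions ships at `src/bnss/data/aba_template.txt`; a
completed transcription placed at `src/bnss/data/aba_rules.txt` (or
pointed to by `BNSS_ABA_RULES` / `--network`) unlocks the external-model
acceptance targets.

## Tests and acceptance report

```sh
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The suite validates the engine and analyses against the exact oracle
(empirical visit frequencies vs stationary distributions, exhaustive
trajectory equality for deterministic networks, frozen-set and
synchrony-verdict agreement) plus structural invariants and CLI
round-trips. One acceptance test and all five acceptance targets depend
on the external ABA transcription above; without it the test fails with
an explanatory message and the report omits the targets (empty JSON).

## Practical notes

- Default burn-in is 0 everywhere; for transient-sensitive analyses
  (classification, joint censuses) a burn-in of ~4 updates is
  recommended, since these networks settle after about 3–4 updates.
- Census statistics include the initial state by default
  (`record_initial=True`): t_m updates record t_m + 1 states.
- The exact oracle is capped at 16 nodes (12 with free nodes).
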