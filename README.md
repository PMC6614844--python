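# signalflip

Predict which signalling molecules, when activated or inhibited, drive a cell
from an initial to a desired gene-expression state.

The method couples three layers:

1. **Boolean transition GRN** — expression of the two cell states is
   Booleanized (Gaussian + uniform "barcode" mixture, or detection-call
   p-values); transcription factors whose state differs form a Boolean
   network, pruned so both states are point attractors under synchronous
   majority logic.
2. **Interface-TF perturbation screen** — TFs that regulate the GRN, are
   expressed initially and reachable from signalling-pathway sources through
   expressed paths are exhaustively clamped (combinations up to 4); the
   best-performing combinations (top-3 flipping scores with ties, synergy
   filtered) yield a probability distribution **Q** over TF states.
3. **Signed path scoring + JSD ranking** — for every signalling molecule the
   most-probably-expressed path (MPP) to each interface TF is computed under
   two variants (correlation-boosted and length-penalized), giving a signed
   distribution **P** per molecule and direction; molecules are ranked by
   Jensen–Shannon divergence of P from Q, aggregated across variants by the
   minimum rank, and candidates selected below a fraction (default 6%) of the
   maximum rank.

## CLI

Generate a fully synthetic, ground-truthed case and run the pipeline on it:

```bash
signalflip generate --seed 1 --out case/
signalflip run \
  --signalling case/signalling.tsv --regulatory case/regulatory.tsv \
  --expr-initial case/expr_initial.tsv --expr-final case/expr_final.tsv \
  --barcode case/barcode.tsv --correlations case/correlations.tsv \
  --targets case/targets.tsv --max-combination-size 3 --out results/
```

Outputs: `ranking.tsv` (molecule, direction, per-variant JSD and rank, R,
candidate flag), `bpcs.json` (combinations + Q), `grn.tsv`/`grn.json`
(pruned network, states, pruning log), `provenance.json` (config hash,
flags, evaluation).

Other subcommands: `evaluate` (check known targets against a written
ranking), `predict-state` (GRN state expected after one perturbation).

### Input formats

* networks: 4-column TSV `source<TAB>effect<TAB>mechanism<TAB>target`,
  effects in {Activation, Inhibition, Unspecified}, `#` comments;
* expression: TSV with gene ids in the first column, replicates after;
* barcode parameters: `gene<TAB>mu<TAB>sigma` (non-expressed Gaussian);
* correlations: `gene_a<TAB>gene_b<TAB>pearson_r`;
* targets: `molecule[<TAB>direction]` per line.

## Package layout

| module | responsibility |
|---|---|
| `network` | signed-network parsing, filtering, merging, topology queries |
| `expression` | Booleanization routes and the transition object |
| `grn` | majority-logic dynamics, attractor-consistent pruning |
| `perturb` | interface TFs, clamped simulation, BPCs, Q |
| `paths` | MPP search (both variants), per-molecule distributions P |
| `ranking` | JSD, competition ranks, aggregation, candidates, success |
| `evaluation` | phospho-enrichment of MPPs, topological distance test |
| `fixtures` | synthetic ground-truthed case generator |
| `pipeline` | orchestration, file I/O, provenance; `cli` exposes it |
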