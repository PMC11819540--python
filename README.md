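# neomer

Analysis toolkit for **closed-sequence-space aptamer selections** — library
designs in which a small number of random nucleotides are interspersed among
non-hybridizing fixed sequences, so that the entire sequence space is
enumerable and a *single* round of selection can be evaluated (and repeated)
statistically.

## The problem and the method

Classical SELEX libraries carry a contiguous random region of 25–80 nt; a
40-nt region spans 4⁴⁰ ≈ 1.2 × 10²⁴ sequences, of which a synthesized pool of
10¹⁵ molecules covers only ~8.3 × 10⁻¹⁰ — roughly one copy per unique
sequence, so selections are irreproducible and need many amplification
rounds. A closed design with **16 random nucleotides** spans exactly
4¹⁶ = 4,294,967,296 sequences; a pool of 4.29 × 10¹² molecules then carries
~1000 copies of *every* possible sequence, enabling reproducible single-round
selection and in-silico specificity screening against counter-targets (an
analogue of immune tolerance).

Because one NGS lane (~10⁹ reads) cannot count 4.3 × 10⁹ sequences directly,
the template carries a central KasI site (`CCATCGGCGCC`): digestion yields two
**modules** of 8 random nucleotides each, whose 4⁸ = 65,536-sequence spaces
are counted exhaustively (≥5 × 10⁶ reads ≈ 76 copies per module sequence).
The analysis core is:

- per-module frequency: `f = count / total reads`;
- full-sequence frequency reconstructed as the **outer product** of the two
  module marginals, `f(a,b) = f_A[a] · f_B[b]`, streamed row-by-row (never
  materialized);
- replicate **z-score** per sequence,
  `z = (X̄_target − X̄_control) / max(½(s_target + s_control), ε)`,
  ranked by an exact bounded-memory top-k (default k = 10,000);
- **fold** specificity per counter-target,
  `fold = X̄_target / max(X̄_counter, pseudo)`, with threshold filtering of the
  retained candidates.

A ground-truth selection simulator (Dirichlet pool → planted-binder
enrichment → multinomial sequencing → module amplicon reads) makes the whole
pipeline testable end to end, and structure tools (constrained base-pair
maximization folding, loop-element annotation, positional Shannon diversity)
reproduce the library structural-diversity analysis.

## Worked example

```sh
$ printf 'TGTGTATAAGTCNNGAGGNNNGAATNNNAACCATCGGCGCCAACANNNCATTCNNNCAGANNTCTACTAGTCAC\n' > template.txt
$ neomer validate template.txt
template_length	74
n_random	16
block_lengths	2,3,3,3,3,2
module_widths	8,8
fixed_gc_percent	46.55
gc_bounds	40,60
gc_pass	True
restriction_site_count	1
site_pass	True
fixed_fixed_pairs	0-72;1-71;2-44;3-43;4-42;56-69;57-67;58-66
passed	True
```

The production template parses to 74 characters with 16 random positions in
the symmetric 2:3:3 block layout, eight per module; the fixed scaffold's GC
content (46.55% over the 58 fixed positions) sits inside the 40–60% design
band, and the self-hybridization screen lists the few predicted fixed–fixed
base pairs (report-only) under the maximum-pairing fold of the N→A proxy.

Simulate a selection, then screen it:

```sh
$ cat sim.yaml
w_a: 3
w_b: 3
replicates: 3
reads_per_sample: 30000
counter_conditions: [resin]
binders:
  - {fill_a: AAA, fill_b: CCC, factor: 60.0}
  - {fill_a: GGG, fill_b: TTT, factor: 60.0}
  - {fill_a: CAT, fill_b: TAC, factor: 40.0, binds: resin}
$ neomer simulate --config sim.yaml --seed 9 -o sim/
$ neomer screen --manifest sim/manifest.yaml -k 4096 --threshold resin=1.0 -o screen/
$ head -5 screen/ranked.tsv
rank	fill_a	fill_b	z	mean_target	mean_control
1	AAA	TTT	18.57112282328368	0.0008537415298214904	0.00023439442882820438
2	AAA	CCC	18.395112148624474	0.0008612375065419816	0.0002477603630160695
3	GGG	CCC	17.429601395858217	0.0008375683523424766	0.00025629100047126703
4	GGG	TTT	14.678933291263114	0.0008321373780479824	0.0002426133702688342
```

The two planted target binders (`AAA/CCC`, `GGG/TTT`) and their two
module-sharing cross terms (`AAA/TTT`, `GGG/CCC`) top the z ranking — the
expected signature of outer-product reconstruction, which spreads a joint
enrichment across all sequences sharing either enriched module.  In
`screened.tsv` the planted resin binder appears with `fold_resin 0.37` and
`kept False`: removed by the specificity screen at threshold 1.

Profile structural diversity of the template ensemble:

```sh
$ neomer structure --template template.txt -n 1000 --seed 4 -o struct/
```

writes the 6-element × 74-position abundance matrix, per-position Shannon
diversity (bits), and per-element motif summaries.

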