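# regutarget

Rank transcriptional regulators (TRs) as overexpression or downregulation
targets for overproducing a chosen metabolite, from three inputs:

1. a **genome-scale metabolic model** (SBML, with flux bounds and
   gene-protein-reaction rules),
2. a **signed transcriptional regulatory network** (TRN: regulator → target
   edges marked activator `+`, repressor `-` or dual `+-`; RegulonDB- and
   Abasy-style exports are read directly), and
3. a **two-condition expression table** contrasting a producer with a
   non-producer phenotype.

Enzyme-centric engineering often under-delivers because metabolism is
wrapped in layers of transcriptional regulation; manipulating a regulator
moves a whole regulon at once. `regutarget` scores each regulator's global
effect on the product flux, accounting for two things simpler regulon
scores miss: the **hierarchy** of TR→TR regulation (a target's effect can
be amplified or cancelled by the regulators above it) and **competing
reactions** — fluxes negatively correlated with the product are scored too,
yielding downregulation candidates, not only overexpression ones.

## Method

For every gene-associated reaction *r*, flux variability analysis under a
growth requirement (v_biomass ≥ 0.5·v_biomass^max) gives the feasible range
[v_min, v_max]. Fixing v_r = v_min + k·(v_max − v_min) for k = 0, 0.1, …, 1
and maximising the product flux at each point, the least-squares slope of
max v_target versus k is the reaction's score

> **nRAP_r** — positive for product-favouring reactions, negative for
> competing ones, 0 for irrelevant ones.

GPR rules distribute the reaction score over its genes: a subunit factor
GPRf_j is assigned by walking the boolean tree (OR passes the factor
through, AND with c children multiplies it by c), and

> **nGAP_jr = nRAP_r / GPRf_j.**

From expression intensities in the producer (prod) and non-producer
(n-prod) conditions, each regulatory edge i→j gets a normalised regulatory
strength

> **nRS_ij = ((Gene_j,prod − Gene_j,n-prod) / (TR_i,prod − TR_i,n-prod)) ·
> (TR_i,n-prod / Gene_j,n-prod)**,

with edges whose empirical sign contradicts their curated effect removed.
A regulator's local effect is the regulon-weighted sum

> **TRE_i = Σ_{j,r} nRS_ij · nGAP_jr**,

screened against chance by redrawing all reaction scores uniformly within
their observed range (1000 draws; a TR is kept when fewer than 5% of random
draws land within ±10% of its actual TRE). Finally the TR→TR graph — with
self-loops and feedback-loop edges excluded, since a negative loop cancels
and a positive one diverges — is layered by longest path, and effects
propagate bottom-up:

> **gTRE(i) = TRE(i) + Σ_{i→c} nRS_ic · gTRE(c).**

TRs sorted by gTRE give the report: high positive → overexpress, high
negative → downregulate.

## Worked example

The package ships a fully self-contained toy instance — a 9-reaction model
(uptake, a 3-step product pathway, a 2-step biomass pathway, a competing
drain), a 7-regulator TRN with a planted cascade, feedback loop and
self-loop, and consistent integer expression values:

```sh
regutarget fixtures --out toy_inputs --seed 1
regutarget run --model toy_inputs/toy_model.xml --trn toy_inputs/toy_trn.tsv \
  --expression toy_inputs/toy_expression.tsv --out results \
  --biomass-id BIOMASS --target-id EX_P --seed 7
```

`results/ranked_targets.tsv` (values rounded here for readability):

```
tr_id    level  tre    q      significant  gtre   rank  direction
t_act    2      20.0   0.002  True         20.0   1     upregulate
t_mid    2      0.0    1.000  False        11.0   2     upregulate
t_top    1      0.0    1.000  False        5.1    3     upregulate
t_rep    1      -5.0   0.054  False        0.0    4     neutral
t_c1     1      2.0    0.054  False        0.0    5     neutral
t_c2     1      0.0    1.000  False        0.0    6     neutral
t_drain  3      -11.0  0.008  True         -11.0  7     downregulate
```

Reading it: `t_act`, the activator of the product-pathway genes, is the top
overexpression candidate (TRE = 2·5 + 1.5·5 + 1·2.5 = 20, summing its three
regulon genes' nRS·nGAP terms; the third gene sits in a two-subunit complex,
halving its slope of 5). `t_drain`, which activates the drain and a
biomass-pathway gene (slopes −5), is the downregulation candidate
(TRE = 1.2·(−5) + 1·(−5) = −11). `t_mid` and `t_top` have no metabolic
targets of their own (TRE 0) but inherit effects through the hierarchy:
`t_mid` represses `t_drain` with nRS −1, so gTRE(t_mid) = 0 + (−1)·(−11) =
+11 — repressing the drain's activator helps the product. The feedback pair
`t_c1`/`t_c2` keeps its nodes but loses its loop edges, and `t_rep`'s TRE
fails the randomisation screen (q = 0.054 ≥ 0.05), so its own effect is
zeroed. Intermediate tables (`fva.tsv`, `nrap.tsv`, `ngap.tsv`, `nrs.tsv`,
`tre.tsv`, `hierarchy_edges.tsv`, `exclusions.tsv`) and a `manifest.yaml`
are written alongside.

The same pipeline runs on genome-scale inputs (an SBML reconstruction plus
a RegulonDB or Abasy TRN export and a producer/non-producer expression
contrast) via the same flags, with `--trn-dialect regulondb|abasy`.

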