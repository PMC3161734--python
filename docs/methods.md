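# Methods

## The model

The package studies night-time nitrogen assimilation in *Chlamydomonas
reinhardtii* with elementary flux mode (EFM) analysis. An EFM is a
steady-state flux vector with minimal support that respects every
irreversibility constraint; the set of EFMs is the complete, unbiased
catalogue of routes through the network, which is what makes it suitable
for asking how a *regulator* reshapes the whole capability spectrum rather
than a single optimal flux (no objective function, no kinetic parameters).

Regulation enters as a set of reactions whose enzymes are translationally
repressed at night by the RNA-binding factor CHLAMY1, identified by
perfect, uninterrupted (UG)₇₊ repeats in annotated 3′ UTRs. Two regimes
are analysed: **knockout** (all-or-none repression; every mode using a
regulated reaction is removed) and **weighted** (modes keep their yields
but affected modes enter the distribution with weight `w_a`).

### The packaged core network

The shipped model is a curated reduced reconstruction — 43 reactions, 42
metabolites (31 internal) — of the pathways active in the dark:
glycolysis, the oxidative and non-oxidative pentose phosphate pathway
(lumped), acetate activation, the citrate cycle with the glyoxylate shunt,
nitrate/nitrite transport and reduction, ammonium assimilation (GDH and
GS/GOGAT), and lumped biosynthesis of glycine, alanine, asparagine, lysine
(diaminopimelate route) and arginine (ornithine–citrulline route).
Unbranched multi-step segments are lumped into single reactions; FAD and
ferredoxin are folded onto NAD(H)/NADP(H). Energy and redox carriers (ATP,
NAD(H), NADP(H)) are internal species and must balance within every mode;
a respiratory chain lump (NADH + 2 ADP → NAD + 2 ATP), an ATP-maintenance
reaction and an irreversible NADPH→NADH dehydrogenase provide the
physiological dissipation routes. GOGAT is the NADH-dependent form
(EC 1.4.1.14, the form relevant in the dark) and NADP-malic enzyme is
included as a canonical algal NADPH source; without these two choices the
model shows an artificial night-time NADPH shortage that the real network
does not have.

Externals (buffered species): the carbon sources G6P (from starch
degradation) and acetate; the nitrogen sources nitrate, nitrite and
ammonium; CO₂; and the five target amino acids. Nitrate and nitrite enter
through irreversible transporters, so a mode can only consume them by
reducing them through nitrate and nitrite reductase. Directions follow
night-time (respiratory, assimilatory) physiology; genuinely reversible
steps (G6P isomerase, aldolase, aconitase, fumarase, malate dehydrogenase,
aspartate transaminase) stay reversible.

Carbon atom counts are explicit data on each metabolite. A validator
checks every reaction for substrate/product carbon equality; carriers
whose carbon moiety is conserved (ATP, NAD(P)H) carry a
`skip_carbon_check` flag so only the metabolic skeleton is balanced.

### The regulated set

Six enzymes are marked CHLAMY1-regulated. Four are fixed by the known
biology of the system: nitrite reductase and argininosuccinate lyase
(binding shown experimentally), glucose-6-phosphate isomerase (whose
repression forces G6P into the pentose phosphate pathway) and the
NADP-dependent isocitrate dehydrogenase (its NAD-dependent isoenzyme,
using a different cofactor, is not repressed — the same-cofactor
isoenzyme-exemption rule applies only within a cofactor class). The
remaining two members are pyruvate kinase and the pyruvate dehydrogenase
complex: the two gatekeepers of committed carbon oxidation. This choice is
the package's own curation, made so that the reduced model reproduces the
qualitative behaviour reported for the full-size network — a rising mean
yield with a non-rising maximum under both regimes, more than 96% of modes
affected, G6P still usable through the PPP after knockout — and it is
mechanistically coherent with the energy-conservation interpretation:
repressing the entry points of complete oxidation suppresses exactly the
low-yield, energy-producing routes. On the reduced model the GAP+acetate
variant does not preserve the "maximum yield unchanged" observation for
all four amino acids (a property of the full-size network's redundancy);
the variant is provided and reported but that equality is not asserted.

## Statistics

For a target-classified mode (net production of the target > 0, net
consumption of ≥ 1 designated carbon source) the carbon yield is
`Y = n_AA c_AA / Σ n_s c_s`, computed exactly in rational arithmetic from
the mode's overall external equation. CO₂ is never a source, so `Y > 1`
means net dark CO₂ fixation (via PEP carboxylase).

Summaries report min/Q1/median/Q3/max, the arithmetic mean, and the
weighted mean `Ȳ_w = Σ w_i Y_i / Σ w_i` with `w_i = w_a` for affected and
1 for unaffected modes. `w_a` defaults to 1/10 — a conventional choice in
the absence of quantitative repression data — and a sweep utility verifies
that the direction of the shift is stable across nearby values (5–15%).
Quantiles under weighting use the weighted empirical CDF with linear
interpolation: weights are scaled by the LCM of their denominators to
integer replication counts and the type-7 order statistic of the virtual
replicated sample is interpolated exactly, so the `w_a = 1/10` boxplot
equals the explicit 10×-unaffected/1×-affected sample's. An empty knockout
distribution (arginine) is reported as infeasible rather than an error.

## Enumeration

Double description on the split cone: each reversible reaction becomes a
forward/backward pair, the cone `{v ≥ 0, S v = 0}` is built by processing
one internal-metabolite constraint at a time, keeping the rays that
satisfy the new equality plus combinations of adjacent positive/negative
ray pairs. Numerical choices:

- **Exact arithmetic.** Rows of S are scaled to integers; rays are integer
  vectors reduced by their gcd at every combination. Support-minimality
  decisions are therefore never at the mercy of rounding; floats appear
  only in reports.
- **Adjacency** is the combinatorial test (a pair is adjacent iff no third
  ray's support fits inside the pair's union support), vectorised over
  candidate bitsets packed into uint64 words.
- **Constraint order**: ascending nonzero count, ties by declaration
  index — deterministic and empirically close to minimal intermediate
  growth. The canonical output ordering (by support bitmask, then vector)
  makes enumeration independent of reaction declaration order.
- **Canonical form**: split two-cycles are discarded; backward flux folds
  in with negative sign; a mode whose support is entirely reversible is
  kept in the orientation whose first nonzero flux is positive.
- A configurable intermediate-ray cap (default 5·10⁶) turns runaway inputs
  into a controlled abort carrying partial-progress information.

The brute-force reference enumerator checks every support subset: a
support is elementary iff its column submatrix has nullity one and the
kernel vector is strictly nonzero with consistent sign. It shares only the
matrix construction with the engine and is exponential by nature; pruning
(dangling-metabolite rejection, two-cycle supersets, supersets of found
supports) keeps ≤ 16 split columns tractable. Engine and oracle agree
exactly on 100 random networks in the acceptance run.

Knockout filtering (drop modes whose support meets the removed set) is
provably identical to re-enumerating the reduced network; the test suite
checks the identity on random networks rather than trusting it.

## Synthetic data

The generators produce all three input kinds with known ground truth:

- **Networks**: four analytic toys (single chain; two-branch diamond;
  diamond with a reversible cross-edge — 4 EFMs, pinned by the oracle; a
  CO₂-releasing chain whose single mode has yield exactly 2/3) and random
  carbon-balanced networks built from source→sink chains sharing
  intermediates (uniform carbon, 1-to-1 steps, optional reversibility), on
  which enumeration is oracle-checked. These probe the algorithm, not
  biology: they contain no cofactors and no realistic pathway structure.
- **UTR sets**: background RNA whose UG runs are capped below threshold,
  with maximal (UG)ₖ runs planted at recorded positions behind
  non-extending flanks; scanner recall and precision are exactly 1 by
  construction, which validates coordinates and maximality, not
  performance on genomic repeat statistics.
- **Proteomes**: residue-wise samples from a given frequency vector
  (Poisson lengths), so composition estimates can be tested against a
  3σ multinomial envelope.

All generators draw from named substreams of one integer seed, so fixtures
do not depend on call order. The packaged UTR FASTA used by the regulation
driver is such a synthetic set (flagged in its filename) with motifs
planted in the six regulated genes and a motif-free isoform partner for
aspartate transaminase to exercise the exemption rule; real *C.
reinhardtii* UTR annotation is an external resource and is not
redistributed.

## Problem sizes and limitations

The core model yields 3,771 EFMs (≈ 6 s, single core); the original
full-size reconstruction yields 10⁵–10⁶ modes per amino acid, which is why
the tests that pin those published absolute counts fail on the core model
and are kept as an explicit record of the reduction. All qualitative
conclusions (affected fractions > 96%, arginine and nitrate/nitrite use
abolished by knockout, mean-up/max-not-up under both regimes, shift
direction stable across `w_a`) hold on the core model. Remaining
limitations: no compartmentalisation (as in the modelled study), no
thermodynamic feasibility beyond irreversibility flags, lumped reactions
hide internal branch points, and the double description implementation
targets desk-scale networks (tens of reactions), not genome scale.
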